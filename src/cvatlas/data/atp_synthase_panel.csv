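human_symbol,mouse_ortholog,complex_part,annotation
MT-ATP6,Mt-Atp6,Core subunit (F0),Encodes ATP synthase subunit a
MT-ATP8,Mt-Atp8,Core subunit (F0),Encodes ATP synthase subunit A6L
ATP5F1A,Atp5f1a,F1 subunit,"Alpha subunit, catalytic core"
ATP5F1B,Atp5f1b,F1 subunit,"Beta subunit, catalytic core"
ATP5F1C,Atp5f1c,F1 subunit,"Gamma subunit, catalytic core"
ATP5F1D,Atp5f1d,F1 subunit,"Delta subunit, catalytic core"
ATP5F1E,Atp5f1e,F1 subunit,"Epsilon subunit, catalytic core"
ATP5MC1,Atp5mc1,F0 subunit,"Membrane subunit c, isoform 1"
ATP5MC2,Atp5mc2,F0 subunit,"Membrane subunit c, isoform 2"
ATP5MC3,Atp5mc3,F0 subunit,"Membrane subunit c, isoform 3"
ATP5ME,Atp5me,F0 subunit,Epsilon subunit of F0
ATP5MF,Atp5mf,F0 subunit,Subunit f of F0
ATP5MG,Atp5mg,F0 subunit,Subunit g of F0
ATP5PB,Atp5pb,F0 subunit,Subunit b of F0
ATP5PD,Atp5pd,F0 subunit,Subunit d of F0
ATP5PO,Atp5po,F0 subunit,Oligomycin sensitivity
ATPAF1,Atpaf1,Assembly factor,Essential for F1 complex assembly
ATPAF2,Atpaf2,Assembly factor,Essential for F1 complex assembly
TMEM70,Tmem70,Assembly factor,Involved in F0-F1 assembly
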