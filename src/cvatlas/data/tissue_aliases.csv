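expression_label,activity_tissue
Spleen,Spleen
BAT,BAT
gWAT,gWAT
SubQ/iWAT,iWAT
iWAT,iWAT
Duodenum,Duodenum
Pancreas,Pancreas
Skin,Skin
Lung,Lung
Liver,Liver
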