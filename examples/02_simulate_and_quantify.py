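"""Simulate a small plate experiment and recover per-sample activity.

Generates kinetic traces and MTDR fluorescence for 3 tissues x 4 groups x
4 animals with mild noise, quantifies well activity, pools triplicates and
normalizes by net MTDR signal (mitochondrial content proxy).
"""

from cvatlas import (
    AtlasDesign, default_ground_truth, gen_mtdr, gen_plate,
    normalize_table, quantify_plate,
)
from cvatlas.mito import normalized_to_frame

design = AtlasDesign(tissues=("Liver", "Heart atrium", "Tongue"), n_per_group=4)
truth = default_ground_truth(design, seed=0, noise_cv_ar=0.10, noise_sd_fluor=20.0)

traces, _ = gen_plate(design, truth)
print(f"simulated {len(traces)} wells "
      f"({design.replicates_per_sample} technical replicates per sample)")

records = quantify_plate(traces, design.schedule)
normalized = normalize_table(records, gen_mtdr(design, truth))
df = normalized_to_frame(normalized)
print(df.head(8).to_string(index=False))

liver_ym = df[(df.tissue == "Liver") & (df.sex == "male") & (df.age_group == "young")]
print(f"\nLiver young-male mean normalized activity: "
      f"{liver_ym.activity_norm.mean():.3e} (truth {truth.activity('Liver', 'YM'):.3e})")
print("activity_norm is mpH/min per MTDR fluorescence unit; with 10% noise "
      "the group mean lands close to the generator's ground truth.")
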