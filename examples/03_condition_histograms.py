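"""Tube-vs-cyst condition separation through weighted radius histograms.

A reduced phantom study: a control condition of pure ~1 µm tubes and a
"knockdown" condition where 20 % of objects are 7–9 µm cysts.  Object
histograms are combined with the volume-proxy weights w = A^(3/2), averaged
image-then-experiment, and summarised as the percentage of lumen mass with
radius above 6 µm — the statistic that separates tubular from cystic
phenotypes.
"""

from lumenmorph import (
    DatasetDesign, PipelineConfig, analyze_dataset, make_dataset,
)

design = DatasetDesign(
    conditions={"control": {"tube": 1.0},
                "knockdown": {"tube": 0.8, "cyst": 0.2}},
    n_experiments=2, images_per_condition=2, master_seed=4,
)
dataset = make_dataset(design)
print(f"{len(dataset.images)} images "
      f"({design.n_experiments} experiments x "
      f"{design.images_per_condition} images x 2 conditions)")

bundle = analyze_dataset(dataset, PipelineConfig())
mass = bundle.threshold_stats.query("mode == 'mass'")
for _, row in mass.iterrows():
    print(f"{row.condition:9s}: {row.mean_pct:6.2f} % ± {row.sem_pct:.2f} % "
          f"of lumen mass above {row.threshold_um:g} µm")
# Control stays near zero (tubes never reach 6 µm radius); the knockdown's
# cysts, upweighted by their volume proxy, dominate its histogram mass.
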