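"""Quantify droplets in synthetic fluorescence micrographs.

Generates two 'conditions' of three replicate micrographs each — one
with large droplets, one with small — runs the segmentation/filtering/
measurement pipeline (Otsu threshold, 4-70 px diameter, eccentricity
<= 0.6, median intensity 0.1-1, 0.010645 um^2 per pixel) and compares
the per-measurement median droplet areas with an unpaired two-sided
t-test, exactly as a plate-level phase-separation assay is analysed.
"""

import numpy as np
import pandas as pd

import ctdphase as cp

rng = np.random.default_rng(0)
records = []
for condition, base_radius in [("wild-type", 11.0), ("variant", 6.0)]:
    for m in range(3):
        specs = []
        for k in range(12):
            specs.append(cp.DropletSpec(
                center=(float(rng.uniform(60, 452)), float(rng.uniform(60, 452))),
                radius=float(base_radius * rng.uniform(0.8, 1.2)),
                peak_intensity=0.85))
        mg, _ = cp.generate_micrograph(
            specs, shape=(512, 512), background=0.02, noise_sd=0.02,
            seed=int(rng.integers(2**31)), condition=condition,
            measurement=f"m{m + 1}")
        records.append(cp.quantify_micrograph(mg))
records = pd.concat(records, ignore_index=True)

summary = cp.summarize_assay(records, value="area_um2")
print("median droplet area per measurement (um^2):")
print(summary.medians.to_string(index=False))
print("\nmean +/- SD of the three medians per condition:")
print(summary.conditions.round(3).to_string(index=False))
t = summary.tests.iloc[0]
print(f"\nunpaired two-sided t-test on the medians: "
      f"t = {t['t']:.2f}, p = {t['p']:.2g} ({t['significance']})")
print("the variant's smaller median area mirrors a reduced "
      "phase-separation propensity")
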