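"""Exclude failed wells and doublets, then compare against the ground truth.

A well fails when neither marker lipid (PC 34:1, PC 36:2) is detected — the
extraction missed the cell. A well is a doublet when >= 80% of its detected
lipids sit more than 2.5 SD above the per-plate mean — two cells inflate all
signals together.
"""

import pandas as pd

from sclipid import SimulationConfig, classify_samples, match_all, simulate_experiment

cfg = SimulationConfig(seed=2)
spectra, samples, truth = simulate_experiment(cfg)
matches, raw = match_all(spectra, list(cfg.lipid_panel))

report = classify_samples(matches, raw, samples)
merged = report.merge(truth.labels.rename("truth"), left_on="sample_id", right_index=True)
print(pd.crosstab(merged["status"], merged["truth"]))

doublets = merged[merged["truth"] == "doublet"]
clean = merged[merged["truth"] == "clean"]
sens = (doublets["status"] == "excluded_doublet").mean()
spec = (clean["status"] == "pass").mean()
print(f"doublet sensitivity {sens:.3f}, specificity {spec:.3f}")
print(
    "-> rows are assigned statuses, columns the simulated truth; the cascade\n"
    "   removes failed wells and doublets while keeping genuine single cells"
)
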