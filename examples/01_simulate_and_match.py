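"""Simulate one plate-based single-cell experiment and match the lipid panel.

Builds seven 96-well plates of synthetic spectra (single cells, extraction
blanks, pooled QCs), finds the closest peak to each target m/z within 10 ppm,
and contrasts the mass accuracy of real cells against blanks.
"""

from sclipid import SimulationConfig, blank_assessment, match_all, simulate_experiment

cfg = SimulationConfig(seed=1)
spectra, samples, truth = simulate_experiment(cfg)
print(f"simulated {len(spectra)} wells: {truth.labels.value_counts().to_dict()}")

matches, raw = match_all(spectra, list(cfg.lipid_panel))
clean_ids = set(truth.labels[truth.labels == "clean"].index)
det = matches[
    matches["detected"] & (matches["lipid_name"] == "PC 34:1")
    & matches["sample_id"].isin(clean_ids)
]
print(
    f"PC 34:1 in single cells: mean deviation {det['deviation_ppm'].mean():.2f} ppm, "
    f"max {det['deviation_ppm'].max():.2f} ppm, detected in {len(det)}/{len(clean_ids)} cells"
)

blanks = [s for s in spectra if truth.labels[s.sample_id] == "blank"]
marker = next(t for t in cfg.lipid_panel if t.name == "PC 34:1")
blank = blank_assessment(blanks, [marker]).iloc[0]
print(
    f"PC 34:1 in blanks: closest signal {blank['mean_closest_deviation_ppm']:.0f} ppm away "
    f"on average; {blank['n_within_ppm_max']}/{blank['n_blanks']} blanks within 10 ppm"
)
print(
    "-> a clear cell signal sits a few ppm from the target mass; in blanks the\n"
    "   nearest background peak is orders of magnitude further away"
)
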