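"""Total-signal normalization removes multiplicative plate batch effects.

Pooled-QC wells repeated on every plate act as the monitor: before
normalization their raw PC 34:1 abundance differs significantly between
plates; after dividing each well by its total detected signal the difference
disappears. The same division controls for cell size in single-cell wells.
"""

from sclipid import (
    SimulationConfig,
    injection_order_check,
    match_all,
    plate_batch_check,
    simulate_experiment,
    total_signal_normalize,
)

cfg = SimulationConfig(plate_batch_effect_sd=0.3, seed=3)
spectra, samples, _ = simulate_experiment(cfg)
_, raw = match_all(spectra, list(cfg.lipid_panel))
keep = raw.values.notna().any(axis=1)
raw = raw.subset(list(raw.values.index[keep]))
norm = total_signal_normalize(raw)

report = plate_batch_check(raw, norm, samples).set_index("lipid_name")
row = report.loc["PC 34:1"]
print(f"PC 34:1 between-plate ANOVA: raw p = {row['p_raw']:.2e}, "
      f"normalized p = {row['p_normalized']:.3f}")
print(f"lipids with a batch effect removed: {int(report['batch_effect_removed'].sum())}"
      f"/{len(report)}")

cells = samples.loc[samples["sample_type"] == "single_cell", "sample_id"]
order = injection_order_check(
    norm.subset([s for s in norm.sample_ids if s in set(cells)]), samples, seed=3
)
print(order.to_string(index=False))
print(
    "-> the raw plate effect is strongly significant and vanishes after\n"
    "   normalization; the injection-order correlations of the ordination\n"
    "   coordinates stay small (|rho| < 0.1)"
)
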