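"""Failed-well and doublet exclusion rules."""

import numpy as np
import pandas as pd
import pytest

from sclipid import QCThresholds, classify_samples, detect_doublets, detect_failed
from sclipid.sample_qc import STATUS_DOUBLET, STATUS_FAILED, STATUS_NOT_EVALUABLE, STATUS_PASS
from tests.conftest import cell_table, make_matrix


def marker_matches(verdicts):
    """Build a matches frame with given {sample: {marker: detected}}."""
    rows = []
    for sid, flags in verdicts.items():
        for lipid, det in flags.items():
            rows.append(
                {"sample_id": sid, "lipid_name": lipid, "measured_mz": 760.0,
                 "deviation_ppm": 1.0, "intensity": 100.0, "snr": 5.0, "detected": det}
            )
    return pd.DataFrame(rows)


def test_one_marker_detection_suffices():
    samples = cell_table(["a", "b", "c"])
    matches = marker_matches(
        {
            "a": {"PC 34:1": True, "PC 36:2": False},
            "b": {"PC 34:1": False, "PC 36:2": False},
            "c": {"PC 34:1": False, "PC 36:2": True},
        }
    )
    report = detect_failed(matches, samples).set_index("sample_id")
    assert report.loc["a", "status"] == STATUS_PASS
    assert report.loc["b", "status"] == STATUS_FAILED
    assert report.loc["c", "status"] == STATUS_PASS


def test_sample_without_any_peaks_fails():
    samples = cell_table(["a"])
    matches = marker_matches({"a": {"PC 34:1": False, "PC 36:2": False}})
    matches.loc[:, ["measured_mz", "intensity", "snr"]] = np.nan
    report = detect_failed(matches, samples)
    assert report["status"].iloc[0] == STATUS_FAILED


def test_missing_marker_in_panel_is_configuration_error():
    samples = cell_table(["a"])
    matches = marker_matches({"a": {"PC 34:1": True}})
    with pytest.raises(ValueError, match="PC 36:2"):
        detect_failed(matches, samples)


def test_non_cell_wells_never_classified():
    samples = cell_table(["a", "qc1"])
    samples.loc[samples["sample_id"] == "qc1", "sample_type"] = "qc_pool"
    matches = marker_matches(
        {"a": {"PC 34:1": True, "PC 36:2": True}, "qc1": {"PC 34:1": False, "PC 36:2": False}}
    )
    report = detect_failed(matches, samples)
    assert list(report["sample_id"]) == ["a"]


def _doublet_setup(n=12, n_lipids=5, outlier_factor=None, seed=0):
    rng = np.random.default_rng(seed)
    base = np.outer(np.ones(n), np.linspace(1000, 100, n_lipids))
    vals = base * rng.lognormal(0, 0.05, size=(n, n_lipids))
    if outlier_factor is not None:
        vals[0] = base[0] * outlier_factor
    m = make_matrix(vals)
    samples = cell_table(m.sample_ids)
    return m, samples


def test_extreme_outlier_sample_is_doublet():
    m, samples = _doublet_setup(outlier_factor=10.0)
    report = detect_doublets(m, samples, m.sample_ids).set_index("sample_id")
    assert report.loc["s0", "status"] == STATUS_DOUBLET
    assert report.loc["s0", "doublet_fraction_high"] == 1.0


def test_sample_at_population_mean_passes():
    m, samples = _doublet_setup()
    report = detect_doublets(m, samples, m.sample_ids)
    assert (report["status"] == STATUS_PASS).all()


def test_fewer_than_three_wells_not_evaluable():
    m, samples = _doublet_setup(n=2)
    report = detect_doublets(m, samples, m.sample_ids)
    assert (report["status"] == STATUS_NOT_EVALUABLE).all()


def test_normalized_matrix_rejected():
    m, samples = _doublet_setup()
    norm = make_matrix(
        m.values.div(m.values.sum(axis=1), axis=0).to_numpy(), normalized=True
    )
    with pytest.raises(ValueError, match="raw"):
        detect_doublets(norm, samples, m.sample_ids)


def test_doublet_flags_invariant_to_global_rescaling():
    m, samples = _doublet_setup(outlier_factor=4.0, seed=3)
    scaled = make_matrix(m.values.to_numpy() * 7.5)
    a = detect_doublets(m, samples, m.sample_ids)
    b = detect_doublets(scaled, samples, m.sample_ids)
    pd.testing.assert_frame_equal(a, b)


def test_exclusions_monotone_in_sd_multiplier():
    rng = np.random.default_rng(11)
    for _ in range(60):
        n = int(rng.integers(8, 30))
        vals = rng.lognormal(0, 0.3, size=(n, 6)) * 1000
        if rng.random() < 0.5:  # sprinkle doublet-like wells
            vals[rng.integers(0, n)] *= 2.0
        m = make_matrix(vals)
        samples = cell_table(m.sample_ids)
        flagged = []
        for k in (1.5, 2.5, 4.0):
            rep = detect_doublets(m, samples, m.sample_ids, QCThresholds(doublet_sd_multiplier=k))
            flagged.append(set(rep.loc[rep["status"] == STATUS_DOUBLET, "sample_id"]))
        assert flagged[0] >= flagged[1] >= flagged[2]


def test_failed_fraction_recovered_from_simulation():
    from sclipid import SimulationConfig, match_all, simulate_experiment

    cfg = SimulationConfig(
        n_plates=6, wells_per_plate=96, qc_per_plate=0, blank_fraction=0.0,
        failed_fraction=0.2, doublet_fraction=0.0, seed=91,
    )
    spectra, samples, truth = simulate_experiment(cfg)
    matches, raw = match_all(spectra, list(cfg.lipid_panel))
    report = classify_samples(matches, raw, samples)
    n = len(report)
    assert n >= 500
    rate = (report["status"] == STATUS_FAILED).mean()
    assert abs(rate - 0.2) < 4 * np.sqrt(0.2 * 0.8 / n)
    # near-perfect agreement with ground truth; an occasional background peak
    # within 10 ppm of a marker can rescue a failed well, as in real blanks
    m = report.merge(truth.labels.rename("truth"), left_on="sample_id", right_index=True)
    failed = m[m["truth"] == "failed"]
    ok = m[m["truth"] == "clean"]
    assert (failed["status"] == STATUS_FAILED).mean() > 0.95
    assert (ok["status"] != STATUS_FAILED).mean() > 0.95


def test_doublet_recovery_from_simulation(default_sim, matched):
    cfg, spectra, samples, truth = default_sim
    matches, raw = matched
    report = classify_samples(matches, raw, samples)
    m = report.merge(truth.labels.rename("truth"), left_on="sample_id", right_index=True)
    doublets = m[m["truth"] == "doublet"]
    clean = m[m["truth"] == "clean"]
    sens = (doublets["status"] == STATUS_DOUBLET).mean()
    spec = (clean["status"] == STATUS_PASS).mean()
    assert sens > 0.9
    assert spec > 0.9


def test_cascade_order_failed_then_doublet():
    # a well with no markers must be failed, not evaluated for doubling
    vals = np.ones((6, 4)) * 100.0
    vals[0] *= 10
    m = make_matrix(vals, lipids=["PC 34:1", "PC 36:2", "PE 34:1", "SM 34:1"])
    samples = cell_table(m.sample_ids)
    verdicts = {sid: {"PC 34:1": True, "PC 36:2": True} for sid in m.sample_ids}
    verdicts["s0"] = {"PC 34:1": False, "PC 36:2": False}
    report = classify_samples(marker_matches(verdicts), m, samples).set_index("sample_id")
    assert report.loc["s0", "status"] == STATUS_FAILED
    assert np.isnan(report.loc["s0", "doublet_fraction_high"])
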