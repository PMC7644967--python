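"""Total-signal normalization and batch/order diagnostics."""

import numpy as np
import pandas as pd
import pytest

from sclipid import (
    SimulationConfig,
    injection_order_check,
    match_all,
    plate_batch_check,
    simulate_experiment,
    total_signal_normalize,
)
from tests.conftest import make_matrix


def test_unit_sum_and_simple_arithmetic():
    m = make_matrix([[2.0, 3.0, 5.0]])
    norm = total_signal_normalize(m)
    assert norm.normalized
    np.testing.assert_allclose(norm.values.iloc[0], [0.2, 0.3, 0.5])


def test_missing_values_excluded_from_denominator():
    m = make_matrix([[2.0, np.nan, 8.0]])
    norm = total_signal_normalize(m)
    row = norm.values.iloc[0]
    assert row.iloc[0] == pytest.approx(0.2)
    assert np.isnan(row.iloc[1])
    assert row.iloc[2] == pytest.approx(0.8)


def test_sample_without_signal_is_an_error():
    m = make_matrix([[1.0, 2.0], [np.nan, np.nan]], sample_ids=["good", "dead"])
    with pytest.raises(ValueError, match="dead"):
        total_signal_normalize(m)


def test_idempotence_and_scale_invariance():
    rng = np.random.default_rng(4)
    vals = rng.lognormal(0, 1, size=(20, 8))
    vals[rng.random(vals.shape) < 0.2] = np.nan
    vals[:, 0] = 1.0  # keep every row with at least one value
    m = make_matrix(vals)
    once = total_signal_normalize(m)
    twice = total_signal_normalize(once)
    pd.testing.assert_frame_equal(twice.values, once.values, atol=1e-12, rtol=0)
    # per-sample rescaling commutes away
    scales = rng.uniform(0.5, 20, size=20)
    scaled = make_matrix(vals * scales[:, None])
    pd.testing.assert_frame_equal(
        total_signal_normalize(scaled).values, once.values, atol=1e-12, rtol=0
    )
    sums = once.values.sum(axis=1, skipna=True)
    np.testing.assert_allclose(sums, 1.0, atol=1e-9)


def test_doublet_profile_indistinguishable_after_normalization(default_sim, matched):
    # total-signal normalization is the cell-size control: a doubled well has
    # the same composition as a single cell
    cfg, spectra, samples, truth = default_sim
    _, raw = matched
    cells = truth.labels[truth.labels.isin(["clean", "doublet"])].index
    norm = total_signal_normalize(raw.subset([s for s in raw.sample_ids if s in set(cells)]))
    wt = samples.set_index("sample_id").loc[norm.sample_ids, "genotype"] == "WT"
    vals = norm.values.loc[wt[wt].index, "PC 34:1"]
    labels = truth.labels[vals.index]
    clean, doublet = vals[labels == "clean"], vals[labels == "doublet"]
    delta = abs(doublet.mean() - clean.mean())
    se = np.sqrt(clean.var(ddof=1) / len(clean) + doublet.var(ddof=1) / len(doublet))
    assert delta < 4 * se


def _qc_run(seed, batch_sd):
    cfg = SimulationConfig(
        n_plates=7, wells_per_plate=10, qc_per_plate=6,
        blank_fraction=0.0, failed_fraction=0.0, doublet_fraction=0.0,
        plate_batch_effect_sd=batch_sd, seed=seed,
    )
    spectra, samples, truth = simulate_experiment(cfg)
    _, raw = match_all(spectra, list(cfg.lipid_panel))
    norm = total_signal_normalize(raw)
    return plate_batch_check(raw, norm, samples), samples


def test_batch_effect_detected_then_removed():
    report, _ = _qc_run(seed=21, batch_sd=0.3)
    row = report.set_index("lipid_name").loc["PC 34:1"]
    assert row["p_raw"] < 0.05
    assert row["p_normalized"] >= 0.05
    assert row["batch_effect_removed"]


def test_no_batch_effect_keeps_type_one_error_near_nominal():
    # with zero plate effect the raw ANOVA should reject ~5% of the time
    rng = np.random.default_rng(17)
    rejections = 0
    n_rep, n_lipid = 150, 4
    for _ in range(n_rep):
        vals = rng.lognormal(np.log(1000), 0.1, size=(14, n_lipid))
        m = make_matrix(vals, sample_ids=[f"q{i}" for i in range(14)])
        samples = pd.DataFrame(
            {
                "sample_id": m.sample_ids,
                "sample_type": "qc_pool",
                "plate": np.repeat(np.arange(7), 2),
                "well": "W01",
                "injection_order": range(14),
                "genotype": "",
                "replicate": "",
                "experiment_id": "exp1",
                "n_cells": np.nan,
            }
        )
        norm = total_signal_normalize(m)
        rep = plate_batch_check(m, norm, samples)
        rejections += (rep["p_raw"] < 0.05).sum()
    rate = rejections / (n_rep * n_lipid)
    assert 0.02 < rate < 0.09


def test_identical_qc_values_give_p_one():
    m = make_matrix(np.ones((8, 2)) * 5.0, sample_ids=[f"q{i}" for i in range(8)])
    samples = pd.DataFrame(
        {
            "sample_id": m.sample_ids,
            "sample_type": "qc_pool",
            "plate": np.repeat([1, 2, 3, 4], 2),
            "well": "W01",
            "injection_order": range(8),
            "genotype": "",
            "replicate": "",
            "experiment_id": "exp1",
            "n_cells": np.nan,
        }
    )
    report = plate_batch_check(m, total_signal_normalize(m), samples)
    assert (report["p_raw"] == 1.0).all()
    assert (report["p_normalized"] == 1.0).all()


def test_plate_with_single_qc_dropped_with_warning():
    m = make_matrix(np.random.default_rng(0).lognormal(0, 0.1, (5, 2)),
                    sample_ids=[f"q{i}" for i in range(5)])
    samples = pd.DataFrame(
        {
            "sample_id": m.sample_ids,
            "sample_type": "qc_pool",
            "plate": [1, 1, 2, 2, 3],
            "well": "W01",
            "injection_order": range(5),
            "genotype": "",
            "replicate": "",
            "experiment_id": "exp1",
            "n_cells": np.nan,
        }
    )
    with pytest.warns(UserWarning, match="dropping plates"):
        plate_batch_check(m, total_signal_normalize(m), samples)


def test_injection_order_null_and_power():
    rng = np.random.default_rng(33)
    n = 40
    vals = rng.lognormal(np.log(1000), 0.1, size=(n, 6))
    ids = [f"s{i}" for i in range(n)]
    samples = pd.DataFrame(
        {
            "sample_id": ids, "sample_type": "single_cell", "plate": 1, "well": "W01",
            "injection_order": range(1, n + 1), "genotype": "WT", "replicate": "r1",
            "experiment_id": "exp1", "n_cells": np.nan,
        }
    )
    null = total_signal_normalize(make_matrix(vals, sample_ids=ids))
    report = injection_order_check(null, samples, seed=1)
    assert report["evaluable"].all()
    assert (report["p_value"] > 0.001).all()  # no spurious strong trend

    # inject a strong drift in half the panel and expect a significant rho
    drift = vals.copy()
    drift[:, :3] *= np.exp(np.linspace(0, 1.5, n))[:, None]
    drifted = total_signal_normalize(make_matrix(drift, sample_ids=ids))
    report = injection_order_check(drifted, samples, seed=1)
    assert (report["p_value"] < 0.01).any()


def test_injection_order_not_evaluable_for_two_samples():
    m = total_signal_normalize(make_matrix([[1.0, 1.0], [2.0, 1.0]]))
    samples = pd.DataFrame(
        {
            "sample_id": m.sample_ids, "sample_type": "single_cell", "plate": 1,
            "well": "W01", "injection_order": [1, 2], "genotype": "WT",
            "replicate": "r1", "experiment_id": "exp1", "n_cells": np.nan,
        }
    )
    report = injection_order_check(m, samples)
    assert not report["evaluable"].any()
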