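"""Lipid-level QC filters and cross-experiment confidence tiering.

Within one experiment a lipid must pass four filters to be reported:

1. mass accuracy — median unsigned deviation of its detected matches
   <= ``ppm_max`` (10 ppm);
2. signal-to-noise — median S/N of detected matches > ``snr_min`` (1.5);
3. standard-curve linearity — Pearson r between intensity and cell count in
   the multi-cell "standard" wells > ``curve_r_min`` (0.5);
4. presence — detected in at least ``presence_min_frac`` (5%, inclusive) of
   passing single-cell samples.

Across experiments, lipids are graded by how many independent experiments
they passed: level 1 = all, level 3 = exactly one, level 2 = in between
(with three experiments: exactly two).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import AbundanceMatrix, QCThresholds, parse_lipid_name

__all__ = [
    "presence_fraction",
    "curve_linearity",
    "apply_filters",
    "assign_tiers",
    "tiers_from_presence",
]


def presence_fraction(matrix: AbundanceMatrix, passing_cells) -> pd.Series:
    """Fraction of passing single-cell samples in which each lipid is detected."""
    ids = list(passing_cells)
    if not ids:
        raise ValueError("passing_cells must be non-empty")
    sub = matrix.values.loc[ids]
    return sub.notna().mean(axis=0)


def curve_linearity(curve_matrix: AbundanceMatrix, cell_counts: pd.Series) -> pd.Series:
    """Per-lipid Pearson r between intensity and cell count in curve wells.

    Missing intensities are pairwise-dropped. NaN marks a not-evaluable
    lipid (< 3 paired points or a constant intensity vector); not-evaluable
    fails the linearity filter. Requires >= 3 distinct cell-count levels.
    """
    counts = cell_counts.loc[curve_matrix.values.index].astype(float)
    if counts.nunique() < 3:
        raise ValueError("curve_linearity needs >= 3 distinct cell-count levels")
    out = {}
    for lipid in curve_matrix.lipid_names:
        y = curve_matrix.values[lipid]
        mask = y.notna()
        if mask.sum() < 3 or counts[mask].nunique() < 2:
            out[lipid] = np.nan
            continue
        yv = y[mask].to_numpy()
        xv = counts[mask].to_numpy()
        if np.ptp(yv) == 0 or np.ptp(xv) == 0:
            out[lipid] = np.nan
            continue
        out[lipid] = float(sps.pearsonr(xv, yv).statistic)
    return pd.Series(out, name="curve_r")


def apply_filters(
    matches: pd.DataFrame,
    raw: AbundanceMatrix,
    passing_cells,
    curve_matrix: AbundanceMatrix | None,
    curve_counts: pd.Series | None,
    thresholds: QCThresholds = QCThresholds(),
    experiment_id: str = "exp1",
    aggregate: str = "median",
) -> pd.DataFrame:
    """Apply the four lipid-level filters for one experiment.

    ``aggregate`` chooses how per-match deviation and S/N are summarized per
    lipid ("median", robust default, or "mean"). With no curve data the
    linearity filter is not-evaluable and fails. Returns one report row per
    lipid with the component verdicts and the conjunction ``passes``.
    """
    if aggregate not in ("median", "mean"):
        raise ValueError("aggregate must be 'median' or 'mean'")
    agg = np.nanmedian if aggregate == "median" else np.nanmean
    cell_ids = list(passing_cells)
    presence = presence_fraction(raw, cell_ids)
    if curve_matrix is not None and curve_counts is not None:
        curve_r = curve_linearity(curve_matrix, curve_counts)
    else:
        curve_r = pd.Series(np.nan, index=raw.values.columns)
    det = matches[matches["detected"] & matches["sample_id"].isin(cell_ids)]
    rows = []
    for lipid in raw.lipid_names:
        sub = det[det["lipid_name"] == lipid]
        if len(sub):
            med_dev = float(agg(sub["deviation_ppm"].to_numpy()))
            finite_snr = sub["snr"].replace(np.inf, np.nan).to_numpy()
            med_snr = (
                float(agg(finite_snr)) if np.isfinite(finite_snr).any() else np.inf
            )
        else:
            med_dev, med_snr = np.nan, np.nan
        within_ppm = bool(len(sub)) and med_dev <= thresholds.ppm_max
        snr_pass = bool(len(sub)) and med_snr > thresholds.snr_min
        r = curve_r.get(lipid, np.nan)
        curve_pass = bool(np.isfinite(r)) and r > thresholds.curve_r_min
        pres = float(presence.get(lipid, 0.0))
        presence_pass = pres >= thresholds.presence_min_frac
        rows.append(
            {
                "lipid_name": lipid,
                "experiment_id": experiment_id,
                "median_deviation_ppm": med_dev,
                "within_ppm": within_ppm,
                "median_snr": med_snr,
                "snr_pass": snr_pass,
                "curve_r": r,
                "curve_pass": curve_pass,
                "presence_frac": pres,
                "presence_pass": presence_pass,
                "passes": within_ppm and snr_pass and curve_pass and presence_pass,
            }
        )
    return pd.DataFrame(rows)


def assign_tiers(reports: pd.DataFrame) -> pd.DataFrame:
    """Grade lipids by the number of experiments in which they passed all filters.

    ``reports`` concatenates per-experiment filter reports (columns
    ``lipid_name``, ``experiment_id``, ``passes``). Level 1 = passed every
    experiment, level 3 = exactly one, level 2 = anything in between. Lipids
    passing zero experiments are dropped; their count is in the DataFrame's
    ``attrs["n_dropped"]``.
    """
    if reports.empty:
        raise ValueError("assign_tiers needs at least one experiment report")
    n_exp = reports["experiment_id"].nunique()
    passed = (
        reports[reports["passes"]]
        .groupby("lipid_name")["experiment_id"]
        .nunique()
        .rename("n_experiments_passed")
    )
    n_dropped = reports["lipid_name"].nunique() - len(passed)

    def level(k: int) -> int:
        if k == n_exp:
            return 1
        if k == 1:
            return 3
        return 2

    out = passed.reset_index()
    out["level"] = out["n_experiments_passed"].map(level)
    out["lipid_class"] = [parse_lipid_name(n)[0] for n in out["lipid_name"]]
    out = out.sort_values(["level", "lipid_name"]).reset_index(drop=True)
    out.attrs["n_dropped"] = int(n_dropped)
    out.attrs["n_experiments"] = int(n_exp)
    return out


def tiers_from_presence(
    presence_pct: pd.DataFrame, min_frac: float = QCThresholds().presence_min_frac
) -> pd.DataFrame:
    """Tier assignment from a lipids x experiments detection-percentage table.

    Convenience path for published summary tables where only presence
    percentages are available: a lipid "passes" an experiment when its
    percentage is at least ``min_frac * 100`` (inclusive).
    """
    long = presence_pct.stack().rename("pct").reset_index()
    long.columns = ["lipid_name", "experiment_id", "pct"]
    long["passes"] = long["pct"] >= min_frac * 100.0
    return assign_tiers(long)
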