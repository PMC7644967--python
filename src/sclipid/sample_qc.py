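"""Well-level quality control: failed analyses and doublet wells.

Two exclusion rules, applied in order to single-cell wells only:

1. *Failed analysis* — the extraction spot missed the cell. A well fails
   when **neither** marker lipid (by default PC 34:1 and PC 36:2, the two
   most abundant species) is detected; detecting either one suffices.
2. *Doublet* — two cells dispensed into one well, which inflates all raw
   lipid signals together. Among the wells that survive rule 1, a well is
   excluded when at least 80% of its detected lipids lie more than 2.5
   standard deviations above the per-lipid mean of the reference population.

Doublet statistics are computed on raw (pre-normalization) intensities —
total-signal normalization would erase the doubling signature — and, by
default, over passing single-cell wells of the same plate, so that plate
batch effects do not inflate the reference SD. Blanks, pooled QCs and curve
wells never enter the reference statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import AbundanceMatrix, QCThresholds

__all__ = ["detect_failed", "detect_doublets", "classify_samples"]

STATUS_PASS = "pass"
STATUS_FAILED = "failed_no_marker"
STATUS_DOUBLET = "excluded_doublet"
STATUS_NOT_EVALUABLE = "not_evaluable"


def detect_failed(
    matches: pd.DataFrame,
    samples: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
) -> pd.DataFrame:
    """Per-single-cell marker verdicts: fail iff no marker lipid is detected.

    Returns one row per single-cell sample with a ``detected_<marker>``
    column per marker and ``status`` in {pass, failed_no_marker}. Blanks,
    QC pools and curve wells are never classified as failed cells.
    """
    present = set(matches["lipid_name"].unique())
    missing = [m for m in thresholds.marker_lipids if m not in present]
    if missing:
        raise ValueError(f"marker lipids absent from the matched panel: {missing}")
    cells = samples.loc[samples["sample_type"] == "single_cell", "sample_id"]
    marker_rows = matches[matches["lipid_name"].isin(thresholds.marker_lipids)]
    det = marker_rows.pivot_table(
        index="sample_id", columns="lipid_name", values="detected", aggfunc="any"
    ).astype(bool)
    rows = []
    for sid in cells:
        flags = {
            f"detected_{m}": bool(det.loc[sid, m]) if sid in det.index else False
            for m in thresholds.marker_lipids
        }
        status = STATUS_PASS if any(flags.values()) else STATUS_FAILED
        rows.append({"sample_id": sid, **flags, "status": status})
    return pd.DataFrame(rows)


def _doublet_fractions(sub: pd.DataFrame, ref_ids: list, multiplier: float) -> pd.Series:
    """Fraction of each well's detected lipids above mean + multiplier x SD of the reference."""
    ref = sub.loc[ref_ids]
    cutoff = ref.mean(axis=0, skipna=True) + multiplier * ref.std(axis=0, ddof=1, skipna=True)
    usable = sub.notna() & cutoff.notna().to_numpy()
    n_det = usable.sum(axis=1)
    n_over = (sub.gt(cutoff, axis=1) & usable).sum(axis=1)
    frac = (n_over / n_det).where(n_det > 0, 0.0)
    return frac.astype(float)


def detect_doublets(
    raw: AbundanceMatrix,
    samples: pd.DataFrame,
    passing_ids: pd.Series | list[str],
    thresholds: QCThresholds = QCThresholds(),
    reference: str = "plate",
    refine_reference: bool = True,
    max_iter: int = 10,
) -> pd.DataFrame:
    """Flag doublet wells among the passing single-cell samples.

    ``passing_ids`` are the single-cell wells that survived failed-well
    detection; the per-lipid mean/SD reference is computed over the passing
    wells, per plate (``reference="plate"``, default) or pooled
    (``"global"``). A well is a doublet when the fraction of its *detected*
    lipids with abundance above mean + ``doublet_sd_multiplier`` x SD is at
    least ``doublet_lipid_frac``.

    With ``refine_reference`` (default) the passing set is made
    self-consistent: wells flagged as doublets are removed from the
    reference and the statistics recomputed until the flagged set is stable.
    Without refinement the doublets themselves inflate the reference mean
    and SD, and plates that happen to receive several doublets miss most of
    them. Groups with fewer than 3 evaluable wells are reported
    ``not_evaluable`` rather than silently passed.
    """
    if raw.normalized:
        raise ValueError("doublet detection must run on the raw (un-normalized) matrix")
    if reference not in ("plate", "global"):
        raise ValueError(f"reference must be 'plate' or 'global', got {reference!r}")
    passing = list(passing_ids)
    meta = samples.set_index("sample_id")
    vals = raw.values.loc[passing]
    if reference == "plate":
        # a physical plate is one experiment's plate number
        groups = (
            meta.loc[passing, "experiment_id"].astype(str)
            + "/"
            + meta.loc[passing, "plate"].astype(str)
        )
    else:
        groups = pd.Series(0, index=pd.Index(passing, name="sample_id"))
    rows = []
    for _, ids in groups.groupby(groups).groups.items():
        ids = list(ids)
        sub = vals.loc[ids]
        if len(ids) < 3:
            for sid in ids:
                rows.append(
                    {
                        "sample_id": sid,
                        "doublet_fraction_high": np.nan,
                        "status": STATUS_NOT_EVALUABLE,
                    }
                )
            continue
        flagged: set = set()
        frac = _doublet_fractions(sub, ids, thresholds.doublet_sd_multiplier)
        for _ in range(max_iter if refine_reference else 1):
            frac = _doublet_fractions(
                sub,
                [i for i in ids if i not in flagged] if flagged else ids,
                thresholds.doublet_sd_multiplier,
            )
            new_flagged = set(frac.index[frac >= thresholds.doublet_lipid_frac])
            if new_flagged == flagged or len(ids) - len(new_flagged) < 3:
                break
            flagged = new_flagged
        for sid in ids:
            status = (
                STATUS_DOUBLET
                if frac[sid] >= thresholds.doublet_lipid_frac
                else STATUS_PASS
            )
            rows.append(
                {"sample_id": sid, "doublet_fraction_high": float(frac[sid]), "status": status}
            )
    return pd.DataFrame(rows)


def classify_samples(
    matches: pd.DataFrame,
    raw: AbundanceMatrix,
    samples: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
    reference: str = "plate",
) -> pd.DataFrame:
    """Full sample-QC cascade: failed-well detection, then doublet exclusion.

    Returns one row per single-cell sample with columns mirroring the
    sample QC report: ``status`` in {pass, failed_no_marker,
    excluded_doublet, not_evaluable}, per-marker detection flags, and
    ``doublet_fraction_high``.
    """
    failed = detect_failed(matches, samples, thresholds)
    passing = failed.loc[failed["status"] == STATUS_PASS, "sample_id"]
    report = failed.set_index("sample_id")
    report["doublet_fraction_high"] = np.nan
    if len(passing) > 0:
        doublets = detect_doublets(raw, samples, passing, thresholds, reference).set_index(
            "sample_id"
        )
        report.loc[doublets.index, "doublet_fraction_high"] = doublets[
            "doublet_fraction_high"
        ]
        overridden = doublets.index[doublets["status"] != STATUS_PASS]
        report.loc[overridden, "status"] = doublets.loc[overridden, "status"]
    return report.reset_index()
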