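"""Closest-peak matching of target lipids with ppm deviation and S/N estimation.

A lipid is "detected" in a well when the closest peak within the ppm search
window deviates by at most ``ppm_max`` from the target mass AND its
signal-to-noise ratio strictly exceeds ``snr_min``. Deviation is reported
unsigned (magnitude only). The S/N estimate is the peak intensity over the
median intensity of the other peaks within +-1 Da (falling back to the 5th
percentile of the remaining peak intensities when the local window is empty,
and to +infinity when there are no other peaks or the estimate is zero) — a
robust, deterministic choice that needs no profile-mode data.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .core import AbundanceMatrix, LipidTarget, QCThresholds, Spectrum

__all__ = ["closest_peak", "estimate_snr", "match_all", "blank_assessment", "MATCH_COLUMNS"]

MATCH_COLUMNS = (
    "sample_id",
    "lipid_name",
    "measured_mz",
    "deviation_ppm",
    "intensity",
    "snr",
    "detected",
)


def _closest_index(spectrum: Spectrum, target_mz: float, window_ppm: float) -> int | None:
    """Index of the closest peak within the ppm window, or None.

    Ties on |delta m/z| are broken toward higher intensity, then lower m/z.
    ``window_ppm = inf`` searches the whole spectrum.
    """
    mz = spectrum.mz
    if mz.size == 0:
        return None
    if math.isinf(window_ppm):
        lo_i, hi_i = 0, mz.size
    else:
        tol = target_mz * window_ppm * 1e-6
        lo_i = int(np.searchsorted(mz, target_mz - tol, side="left"))
        hi_i = int(np.searchsorted(mz, target_mz + tol, side="right"))
        if hi_i <= lo_i:
            return None
    dev = np.abs(mz[lo_i:hi_i] - target_mz)
    # lexicographic: smallest deviation, then largest intensity, then lowest m/z
    order = np.lexsort((mz[lo_i:hi_i], -spectrum.intensity[lo_i:hi_i], dev))
    return lo_i + int(order[0])


def closest_peak(
    spectrum: Spectrum, target_mz: float, window_ppm: float
) -> tuple[float, float] | None:
    """Return the (mz, intensity) of the closest peak within ``window_ppm``, or None."""
    if not (window_ppm > 0):
        raise ValueError("window_ppm must be > 0")
    idx = _closest_index(spectrum, target_mz, window_ppm)
    if idx is None:
        return None
    return float(spectrum.mz[idx]), float(spectrum.intensity[idx])


def estimate_snr(
    spectrum: Spectrum, peak: tuple[float, float], noise_window_da: float = 1.0
) -> float:
    """Signal-to-noise of a peak against the local spectral background.

    Noise is the median intensity of *other* peaks within
    ``+-noise_window_da`` of the peak m/z; with no such neighbours it falls
    back to the 5th percentile of the remaining peak intensities, and with no
    other peaks at all (or a zero noise estimate) the S/N is +infinity.
    """
    if not (noise_window_da > 0):
        raise ValueError("noise_window_da must be > 0")
    mz0, int0 = peak
    candidates = np.flatnonzero((spectrum.mz == mz0) & (spectrum.intensity == int0))
    if candidates.size == 0:
        raise ValueError(f"peak ({mz0}, {int0}) not found in spectrum {spectrum.sample_id!r}")
    idx = int(candidates[0])
    lo = int(np.searchsorted(spectrum.mz, mz0 - noise_window_da, side="left"))
    hi = int(np.searchsorted(spectrum.mz, mz0 + noise_window_da, side="right"))
    neighbour_idx = [i for i in range(lo, hi) if i != idx]
    if neighbour_idx:
        noise = float(np.median(spectrum.intensity[neighbour_idx]))
    else:
        others = np.delete(spectrum.intensity, idx)
        noise = float(np.percentile(others, 5)) if others.size else 0.0
    if noise == 0:
        return math.inf
    return int0 / noise


def match_all(
    spectra: Sequence[Spectrum],
    targets: Sequence[LipidTarget],
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[pd.DataFrame, AbundanceMatrix]:
    """Match every target in every spectrum.

    Returns one row per (sample, lipid) with measured m/z, unsigned ppm
    deviation (+inf when no peak lies in the search window), intensity, S/N
    and the detected flag, plus the raw abundance matrix holding intensity
    where detected and missing (NaN) otherwise.
    """
    if not targets:
        raise ValueError("targets must be non-empty")
    rows = []
    names = [t.name for t in targets]
    grid = np.full((len(spectra), len(names)), np.nan)
    for si, spec in enumerate(spectra):
        for li, t in enumerate(targets):
            idx = _closest_index(spec, t.target_mz, thresholds.ppm_max)
            if idx is None:
                rows.append(
                    (spec.sample_id, t.name, np.nan, math.inf, np.nan, np.nan, False)
                )
                continue
            mz = float(spec.mz[idx])
            inten = float(spec.intensity[idx])
            dev = abs(mz - t.target_mz) / t.target_mz * 1e6
            snr = estimate_snr(spec, (mz, inten), thresholds.snr_window_da)
            detected = dev <= thresholds.ppm_max and snr > thresholds.snr_min
            if detected:
                grid[si, li] = inten
            rows.append((spec.sample_id, t.name, mz, dev, inten, snr, detected))
    matches = pd.DataFrame(rows, columns=list(MATCH_COLUMNS))
    raw = AbundanceMatrix(
        pd.DataFrame(grid, index=[s.sample_id for s in spectra], columns=names),
        normalized=False,
    )
    return matches, raw


def blank_assessment(
    blank_spectra: Sequence[Spectrum],
    targets: Sequence[LipidTarget],
    thresholds: QCThresholds = QCThresholds(),
) -> pd.DataFrame:
    """Closest-signal deviation statistics of extraction blanks, per target.

    The search is global (no ppm window): the question is how far the nearest
    background signal sits from each target mass in wells with no cell.
    Blanks with no peaks at all are excluded from the deviation statistics and
    counted as non-evaluable. Returns one row per target with the mean and
    minimum closest deviation (ppm), the count of blanks with a signal within
    ``ppm_max``, and the blank counts.
    """
    if len(blank_spectra) == 0:
        raise ValueError("blank_assessment requires at least one blank spectrum")
    rows = []
    for t in targets:
        devs = []
        n_empty = 0
        for spec in blank_spectra:
            idx = _closest_index(spec, t.target_mz, math.inf)
            if idx is None:
                n_empty += 1
                continue
            devs.append(abs(float(spec.mz[idx]) - t.target_mz) / t.target_mz * 1e6)
        devs_arr = np.array(devs)
        rows.append(
            {
                "lipid_name": t.name,
                "mean_closest_deviation_ppm": float(devs_arr.mean()) if devs_arr.size else np.nan,
                "min_deviation_ppm": float(devs_arr.min()) if devs_arr.size else np.nan,
                "n_within_ppm_max": int((devs_arr <= thresholds.ppm_max).sum()),
                "n_blanks": len(blank_spectra),
                "n_non_evaluable": n_empty,
            }
        )
    return pd.DataFrame(rows)
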