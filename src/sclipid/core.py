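"""Core domain types for the single-cell lipid profiling pipeline.

The pipeline operates on four kinds of objects: annotated lipid targets
(sum-composition species with a target m/z), per-well centroid spectra,
a sample metadata table, and samples x lipids abundance matrices in which
a missing cell means "below the lower limit of detection", never zero.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LIPID_CLASSES",
    "SAMPLE_TYPES",
    "LipidTarget",
    "Spectrum",
    "QCThresholds",
    "AbundanceMatrix",
    "parse_lipid_name",
    "format_lipid_name",
    "validate_samples",
    "SAMPLE_COLUMNS",
]

#: Head-group classes the annotation grammar accepts.
LIPID_CLASSES = ("PC", "PE", "SM", "Cer", "DG", "PS", "TG")

SAMPLE_TYPES = ("single_cell", "blank", "qc_pool", "curve_standard")

#: Canonical column order of a sample metadata table.
SAMPLE_COLUMNS = (
    "sample_id",
    "sample_type",
    "plate",
    "well",
    "injection_order",
    "genotype",
    "replicate",
    "experiment_id",
    "n_cells",
)

_NAME_RE = re.compile(r"^(?P<cls>[A-Za-z]+) (?P<c>\d+):(?P<d>\d+)$")


def parse_lipid_name(name: str) -> tuple[str, int, int]:
    """Split a sum-composition name like ``"PC 34:1"`` into (class, carbons, double bonds)."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"lipid name {name!r} does not match '<CLASS> <carbons>:<double_bonds>'")
    cls = m.group("cls")
    if cls not in LIPID_CLASSES:
        raise ValueError(f"unknown lipid class {cls!r} in {name!r}; expected one of {LIPID_CLASSES}")
    return cls, int(m.group("c")), int(m.group("d"))


def format_lipid_name(lipid_class: str, carbons: int, double_bonds: int) -> str:
    return f"{lipid_class} {carbons}:{double_bonds}"


@dataclass(frozen=True)
class LipidTarget:
    """One annotated lipid species (sum composition) and its target m/z.

    Annotation is at the level of head group plus total acyl carbons and
    double bonds (e.g. PC 34:1); fatty-acid chain composition is not resolved.
    """

    name: str
    lipid_class: str
    carbons: int
    double_bonds: int
    adduct: str
    target_mz: float

    def __post_init__(self) -> None:
        if self.lipid_class not in LIPID_CLASSES:
            raise ValueError(f"unknown lipid class {self.lipid_class!r}")
        if self.carbons < 10:
            raise ValueError(f"{self.name}: carbons must be >= 10, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError(f"{self.name}: double_bonds must be >= 0")
        if not (self.target_mz > 0):
            raise ValueError(f"{self.name}: target_mz must be > 0, got {self.target_mz}")
        expected = format_lipid_name(self.lipid_class, self.carbons, self.double_bonds)
        if self.name != expected:
            raise ValueError(f"name {self.name!r} inconsistent with composition {expected!r}")


class Spectrum:
    """A centroided peak list for one well, sorted ascending by m/z.

    Parameters
    ----------
    sample_id : str
        Identifier linking the spectrum to a sample-metadata row.
    mz, intensity : array-like
        Peak positions (Da, strictly positive) and heights (>= 0).
        Peaks are sorted on construction; duplicate m/z values are allowed.
    """

    __slots__ = ("sample_id", "mz", "intensity")

    def __init__(self, sample_id: str, mz: Iterable[float], intensity: Iterable[float]):
        mz_arr = np.asarray(list(mz) if not isinstance(mz, np.ndarray) else mz, dtype=float)
        int_arr = np.asarray(
            list(intensity) if not isinstance(intensity, np.ndarray) else intensity, dtype=float
        )
        if mz_arr.shape != int_arr.shape or mz_arr.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz_arr.size and not np.all(mz_arr > 0):
            raise ValueError(f"spectrum {sample_id!r}: all m/z values must be > 0")
        if int_arr.size and not np.all(int_arr >= 0):
            raise ValueError(f"spectrum {sample_id!r}: intensities must be >= 0")
        order = np.argsort(mz_arr, kind="stable")
        self.sample_id = sample_id
        self.mz = mz_arr[order]
        self.intensity = int_arr[order]

    def __len__(self) -> int:
        return self.mz.size

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and np.array_equal(self.mz, other.mz)
            and np.array_equal(self.intensity, other.intensity)
        )

    def __repr__(self) -> str:
        return f"Spectrum(sample_id={self.sample_id!r}, n_peaks={len(self)})"


@dataclass(frozen=True)
class QCThresholds:
    """Full parameter set of the QC filter cascade.

    Defaults implement the four lipid-level filters (<= 10 ppm mass deviation,
    S/N > 1.5, standard-curve Pearson r > 0.5, presence in >= 5% of single
    cells) and the sample-level exclusion rules (failed well: neither marker
    lipid detected; doublet: >= 80% of a well's detected lipids more than
    2.5 SD above the reference mean).
    """

    ppm_max: float = 10.0
    snr_min: float = 1.5
    curve_r_min: float = 0.5
    presence_min_frac: float = 0.05
    doublet_sd_multiplier: float = 2.5
    doublet_lipid_frac: float = 0.8
    marker_lipids: tuple[str, ...] = ("PC 34:1", "PC 36:2")
    #: half-width (Da) of the local window used for the S/N noise estimate
    snr_window_da: float = 1.0

    def __post_init__(self) -> None:
        for attr in ("ppm_max", "snr_min", "curve_r_min", "doublet_sd_multiplier", "snr_window_da"):
            if not (getattr(self, attr) > 0):
                raise ValueError(f"{attr} must be positive")
        for attr in ("presence_min_frac", "doublet_lipid_frac"):
            v = getattr(self, attr)
            if not (0 < v <= 1):
                raise ValueError(f"{attr} must be in (0, 1], got {v}")
        if not self.marker_lipids:
            raise ValueError("marker_lipids must be non-empty")
        object.__setattr__(self, "marker_lipids", tuple(self.marker_lipids))

    def replace(self, **kwargs) -> "QCThresholds":
        return replace(self, **kwargs)


class AbundanceMatrix:
    """Samples x lipids intensity table; NaN encodes "missing" (below LLOD).

    A zero is a valid measurement and distinct from missing. When
    ``normalized`` is True every sample's non-missing values sum to 1.
    """

    def __init__(self, values: pd.DataFrame, normalized: bool = False):
        if values.index.has_duplicates:
            raise ValueError("duplicate sample_ids in abundance matrix")
        if values.columns.has_duplicates:
            raise ValueError("duplicate lipid names in abundance matrix")
        vals = values.astype(float)
        if np.nanmin(vals.to_numpy(), initial=0.0) < 0:
            raise ValueError("abundances must be non-negative")
        if normalized:
            sums = vals.sum(axis=1, skipna=True).to_numpy()
            if vals.shape[1] and not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("normalized matrix rows must sum to 1 within 1e-9")
        self.values = vals
        self.normalized = bool(normalized)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def lipid_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, sample_ids: Sequence[str]) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.loc[list(sample_ids)], normalized=self.normalized)

    def equals(self, other: "AbundanceMatrix") -> bool:
        return self.normalized == other.normalized and self.values.equals(other.values)

    def __repr__(self) -> str:
        n, p = self.shape
        return f"AbundanceMatrix({n} samples x {p} lipids, normalized={self.normalized})"


def validate_samples(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample metadata table and return it with canonical dtypes.

    Raises on duplicate sample ids, unknown sample types, or an ``n_cells``
    entry that is present without / absent with ``curve_standard`` type.
    """
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    out = df.copy()
    if out["sample_id"].duplicated().any():
        dups = out.loc[out["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id values: {dups[:5]}")
    bad = set(out["sample_type"]) - set(SAMPLE_TYPES)
    if bad:
        raise ValueError(f"unknown sample_type values: {sorted(bad)}")
    out["plate"] = out["plate"].astype(int)
    out["injection_order"] = out["injection_order"].astype(int)
    out["n_cells"] = pd.to_numeric(out["n_cells"], errors="coerce")
    is_curve = out["sample_type"] == "curve_standard"
    if out.loc[is_curve, "n_cells"].isna().any():
        raise ValueError("curve_standard samples must have n_cells")
    if out.loc[~is_curve, "n_cells"].notna().any():
        raise ValueError("n_cells is only valid for curve_standard samples")
    extra = [c for c in out.columns if c not in SAMPLE_COLUMNS]
    return out[list(SAMPLE_COLUMNS) + extra]
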