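"""Synthetic spectrum generator for plate-based single-cell lipid profiling.

Emulates the statistical structure the pipeline assumes from FACS-dispensed
well plates analysed by direct-infusion MS: single-cell wells whose lipid
signals share a common per-cell size factor, extraction blanks carrying only
chemical noise, pooled-QC wells repeated on every plate, multiplicative
plate batch effects, failed wells in which the extraction spot missed the
cell (no marker-lipid signal), and doublet wells in which two cells were
dispensed (all signals roughly doubled). A separate generator produces
multi-cell "standard curve" wells whose signal scales linearly with cell
count before noise.

All randomness flows from the single config seed; a fixed seed reproduces
output bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import LipidTarget, Spectrum, validate_samples
from .panel import default_panel

__all__ = ["SimulationConfig", "TruthTable", "simulate_experiment", "simulate_standard_curve"]

#: truth labels a well can carry
TRUTH_LABELS = ("clean", "blank", "failed", "doublet", "qc")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the generator.

    Defaults emulate one experiment of the study design the pipeline is
    built for: 7 plates of 96 wells, two genotypes of single cells across
    4 biological replicates, pooled QCs on every plate, ~10% extraction
    blanks, a tightly gated cell-size distribution (CV 8%), ~2 ppm mass
    jitter, and a multiplicative plate batch effect that total-signal
    normalization must remove. The
    second genotype carries a bimodal deficit of PC 36:2: a configurable
    fraction of its cells is drawn from a low-abundance mode.
    """

    n_plates: int = 7
    wells_per_plate: int = 96
    n_experiments: int = 1
    lipid_panel: tuple[LipidTarget, ...] = field(default_factory=lambda: tuple(default_panel()))
    base_abundance: Mapping[str, float] | None = None
    #: non-linear (log-like) spread of base abundances across the ranked panel:
    #: the least abundant lipid sits 10**(2*shape) below the most abundant.
    abundance_distribution_shape: float = 1.0
    #: CV of the per-cell size factor; tight FACS gating on one defined cell
    #: type keeps this small, which is what the 2.5-SD doublet rule presumes
    cell_size_cv: float = 0.08
    #: log-scale SD of per-signal technical (measurement) noise
    abundance_noise_sd: float = 0.04
    ppm_jitter_sd: float = 2.0
    #: chemical-background peaks per Da of m/z range
    noise_peak_density: float = 2.0
    noise_intensity_scale: float = 50.0
    blank_fraction: float = 0.10
    failed_fraction: float = 0.08
    doublet_fraction: float = 0.05
    qc_per_plate: int = 6
    plate_batch_effect_sd: float = 0.30
    genotypes: tuple[str, str] = ("WT", "MU")
    n_replicates: int = 4
    genotype_effect: Mapping[str, float] = field(
        default_factory=lambda: {"PC 36:2": 0.40}
    )
    #: fraction of second-genotype cells drawn from the low mode of the mixture
    bimodality_fraction: float = 0.60
    #: peak intensity scale of the most abundant panel lipid
    max_base_abundance: float = 1.0e4
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lipid_panel:
            raise ValueError("lipid_panel must be non-empty")
        if self.wells_per_plate <= 0 or self.n_plates <= 0 or self.n_experiments <= 0:
            raise ValueError("plate/well/experiment counts must be positive")
        for attr in ("blank_fraction", "failed_fraction", "doublet_fraction", "bimodality_fraction"):
            v = getattr(self, attr)
            if not (0 <= v <= 1):
                raise ValueError(f"{attr} must be in [0, 1], got {v}")
        if self.failed_fraction + self.doublet_fraction > 1:
            raise ValueError("failed_fraction + doublet_fraction must be <= 1")
        if self.qc_per_plate < 0 or self.qc_per_plate >= self.wells_per_plate:
            raise ValueError("qc_per_plate must be in [0, wells_per_plate)")
        if self.base_abundance is not None:
            if set(self.base_abundance) != {t.name for t in self.lipid_panel}:
                raise ValueError("base_abundance keys must match the lipid panel")
            if any(v <= 0 for v in self.base_abundance.values()):
                raise ValueError("base abundances must be strictly positive")
        if self.max_base_abundance <= 0:
            raise ValueError("max_base_abundance must be positive")

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def resolved_base_abundance(self) -> dict[str, float]:
        """Per-lipid base intensity; defaults to a log-spaced ranked spread."""
        if self.base_abundance is not None:
            return dict(self.base_abundance)
        n = len(self.lipid_panel)
        if n == 1:
            return {self.lipid_panel[0].name: self.max_base_abundance}
        exps = -2.0 * self.abundance_distribution_shape * np.arange(n) / (n - 1)
        return {
            t.name: self.max_base_abundance * 10.0 ** e
            for t, e in zip(self.lipid_panel, exps)
        }


@dataclass
class TruthTable:
    """Ground truth of a simulated run: per-well label and realized signal intensities."""

    labels: pd.Series  # index sample_id, values in TRUTH_LABELS
    abundances: pd.DataFrame  # samples x lipids realized signal intensity (0 = no signal)
    size_factors: pd.Series  # per-well cell-size factor (NaN for non-cell wells)
    low_mode: pd.Series  # True for second-genotype cells drawn from the low mixture mode


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv * cv))


def _make_spectrum(
    sample_id: str,
    signal: dict[str, float],
    targets: Sequence[LipidTarget],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    mz_lo: float,
    mz_hi: float,
) -> Spectrum:
    mzs: list[float] = []
    intens: list[float] = []
    for t in targets:
        value = signal.get(t.name, 0.0)
        if value > 0:
            jitter = rng.normal(0.0, cfg.ppm_jitter_sd) if cfg.ppm_jitter_sd > 0 else 0.0
            mzs.append(t.target_mz * (1.0 + jitter * 1e-6))
            intens.append(value)
    n_noise = rng.poisson(cfg.noise_peak_density * (mz_hi - mz_lo)) if cfg.noise_peak_density > 0 else 0
    if n_noise:
        mzs.extend(rng.uniform(mz_lo, mz_hi, size=n_noise).tolist())
        intens.extend(rng.exponential(cfg.noise_intensity_scale, size=n_noise).tolist())
    return Spectrum(sample_id, np.array(mzs), np.array(intens))


def _mz_bounds(targets: Sequence[LipidTarget]) -> tuple[float, float]:
    lo = min(t.target_mz for t in targets) - 60.0
    hi = max(t.target_mz for t in targets) + 60.0
    return max(lo, 50.0), hi


def simulate_experiment(config: SimulationConfig):
    """Generate per-well spectra, sample metadata and the ground-truth table.

    Each single-cell well's lipid signal is
    ``base_abundance x size_factor x plate_factor x genotype_factor x
    exp(N(0, abundance_noise_sd))``; the peak lands at the target m/z
    perturbed by ``N(0, ppm_jitter_sd)`` ppm. Blanks carry noise peaks only;
    failed wells omit both marker lipids; doublets draw their size factor
    from twice the single-cell size distribution.

    Returns ``(spectra, metadata, truth)``.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    targets = list(cfg.lipid_panel)
    base = cfg.resolved_base_abundance()
    mz_lo, mz_hi = _mz_bounds(targets)
    size_sigma = _lognormal_sigma(cfg.cell_size_cv) if cfg.cell_size_cv > 0 else 0.0
    size_mu = -0.5 * size_sigma * size_sigma  # mean size factor = 1
    effect_lipids = dict(cfg.genotype_effect)
    marker_like = ("PC 34:1", "PC 36:2")  # failed wells omit these if present in panel
    markers_in_panel = [t.name for t in targets if t.name in marker_like]

    spectra: list[Spectrum] = []
    meta_rows: list[dict] = []
    labels: dict[str, str] = {}
    truth_rows: dict[str, dict[str, float]] = {}
    sizes: dict[str, float] = {}
    low_modes: dict[str, bool] = {}

    for e in range(cfg.n_experiments):
        exp_id = f"exp{e + 1}"
        order = 0
        for p in range(1, cfg.n_plates + 1):
            plate_factor = (
                math.exp(rng.normal(0.0, cfg.plate_batch_effect_sd))
                if cfg.plate_batch_effect_sd > 0
                else 1.0
            )
            for w in range(1, cfg.wells_per_plate + 1):
                order += 1
                sid = f"{exp_id}_P{p}_W{w:02d}"
                well = f"W{w:02d}"
                is_qc = w <= cfg.qc_per_plate
                row = {
                    "sample_id": sid,
                    "plate": p,
                    "well": well,
                    "injection_order": order,
                    "genotype": "",
                    "replicate": "",
                    "experiment_id": exp_id,
                    "n_cells": np.nan,
                }
                signal: dict[str, float] = {}
                if is_qc:
                    label = "qc"
                    row["sample_type"] = "qc_pool"
                    for name, b in base.items():
                        signal[name] = b * plate_factor * math.exp(
                            rng.normal(0.0, cfg.abundance_noise_sd)
                        )
                    sizes[sid] = np.nan
                elif rng.random() < cfg.blank_fraction:
                    label = "blank"
                    row["sample_type"] = "blank"
                    sizes[sid] = np.nan
                else:
                    row["sample_type"] = "single_cell"
                    u = rng.random()
                    if u < cfg.failed_fraction:
                        label = "failed"
                    elif u < cfg.failed_fraction + cfg.doublet_fraction:
                        label = "doublet"
                    else:
                        label = "clean"
                    genotype = cfg.genotypes[int(rng.random() < 0.5)]
                    replicate = f"r{rng.integers(1, cfg.n_replicates + 1)}"
                    row["genotype"] = genotype
                    row["replicate"] = replicate
                    size = math.exp(rng.normal(size_mu, size_sigma)) if size_sigma > 0 else 1.0
                    if label == "doublet":
                        size *= 2.0
                    sizes[sid] = size
                    low_mode = (
                        genotype == cfg.genotypes[1]
                        and rng.random() < cfg.bimodality_fraction
                    )
                    low_modes[sid] = low_mode
                    for name, b in base.items():
                        g = effect_lipids.get(name, 1.0) if low_mode else 1.0
                        v = b * size * plate_factor * g * math.exp(
                            rng.normal(0.0, cfg.abundance_noise_sd)
                        )
                        if label == "failed" and name in markers_in_panel:
                            v = 0.0
                        signal[name] = v
                labels[sid] = label
                truth_rows[sid] = {t.name: signal.get(t.name, 0.0) for t in targets}
                meta_rows.append(row)
                spectra.append(_make_spectrum(sid, signal, targets, cfg, rng, mz_lo, mz_hi))

    metadata = validate_samples(pd.DataFrame(meta_rows))
    truth = TruthTable(
        labels=pd.Series(labels, name="label"),
        abundances=pd.DataFrame.from_dict(truth_rows, orient="index")[
            [t.name for t in targets]
        ],
        size_factors=pd.Series(sizes, name="size_factor"),
        low_mode=pd.Series(low_modes, name="low_mode", dtype=bool),
    )
    return spectra, metadata, truth


def simulate_standard_curve(config: SimulationConfig, cell_counts: Sequence[int]):
    """Generate multi-cell "standard curve" wells; signal is linear in cell count.

    One well is generated per entry of ``cell_counts`` (repeat a count for
    replicate wells). Before noise, each lipid's intensity is
    ``base_abundance x n_cells``. Returns ``(spectra, metadata)``.
    """
    if len(cell_counts) == 0:
        raise ValueError("cell_counts must be non-empty")
    if any(int(c) < 1 for c in cell_counts):
        raise ValueError("each cell count must be >= 1")
    cfg = config
    # separate child seed so curve wells do not perturb the main experiment draw
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    targets = list(cfg.lipid_panel)
    base = cfg.resolved_base_abundance()
    mz_lo, mz_hi = _mz_bounds(targets)

    spectra: list[Spectrum] = []
    rows: list[dict] = []
    for i, count in enumerate(int(c) for c in cell_counts):
        sid = f"curve_{i + 1:02d}_n{count}"
        signal = {
            name: b * count * math.exp(rng.normal(0.0, cfg.abundance_noise_sd))
            for name, b in base.items()
        }
        spectra.append(_make_spectrum(sid, signal, targets, cfg, rng, mz_lo, mz_hi))
        rows.append(
            {
                "sample_id": sid,
                "sample_type": "curve_standard",
                "plate": 1,
                "well": f"C{i + 1:02d}",
                "injection_order": i + 1,
                "genotype": "",
                "replicate": "",
                "experiment_id": "curve",
                "n_cells": count,
            }
        )
    return spectra, validate_samples(pd.DataFrame(rows))
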