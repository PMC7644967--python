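"""End-to-end orchestration: match -> sample QC -> normalize -> lipid QC -> tiers -> stats.

Every stage reads and writes plain CSV in the run directory, so a run can be
resumed or driven stage-by-stage from the CLI; a ``manifest.json`` records
thresholds, seed, package version and per-stage sample/lipid counts. Stage
outputs are pure functions of their inputs and the config: re-running with
the same config and seed reproduces the manifest byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import AbundanceMatrix, QCThresholds
from .io import (
    read_matrix,
    read_samples,
    read_spectra,
    read_targets,
    write_matrix,
    write_samples,
    write_spectra_table,
    write_targets,
)
from .lipid_qc import apply_filters, assign_tiers
from .matching import blank_assessment, match_all
from .normalization import injection_order_check, plate_batch_check, total_signal_normalize
from .sample_qc import STATUS_PASS, classify_samples
from .stats import genotype_test, population_profiles, stratified_tests, stratify_by_lipid
from .synthetic import SimulationConfig, simulate_experiment, simulate_standard_curve

__all__ = ["STAGES", "RunConfig", "DependencyError", "run_pipeline"]

STAGES = ("simulate", "match", "sample-qc", "normalize", "lipid-qc", "tiers", "stats")


class DependencyError(RuntimeError):
    """A stage was requested whose upstream outputs are absent."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``simulation`` is set (stage ``simulate`` generates the inputs) or
    ``spectra_path``/``targets_path``/``samples_path`` point at existing
    files. ``stages`` must be a contiguous suffix-extension of the dependency
    chain starting from the first requested stage.
    """

    outdir: Path
    simulation: SimulationConfig | None = None
    curve_cell_counts: tuple[int, ...] = (1, 2, 5, 10, 20, 1, 2, 5, 10, 20)
    spectra_path: Path | None = None
    targets_path: Path | None = None
    samples_path: Path | None = None
    curve_spectra_path: Path | None = None
    curve_samples_path: Path | None = None
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    stages: tuple[str, ...] = STAGES
    stratify_lipid: str = "PC 36:2"
    seed: int | None = None

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")
        idx = [STAGES.index(s) for s in self.stages]
        if idx != sorted(idx) or (idx and idx != list(range(idx[0], idx[0] + len(idx)))):
            raise ValueError("stages must be a contiguous, ordered slice of the chain")


def _require(outdir: Path, stage: str, *names: str) -> list[Path]:
    paths = [outdir / n for n in names]
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise DependencyError(
            f"stage {stage!r} needs outputs from an earlier stage; missing: {missing}"
        )
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested stages; returns the manifest (also written as JSON)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    manifest: dict = {
        "version": __version__,
        "stages": list(config.stages),
        "thresholds": dataclasses.asdict(thr),
        "seed": None,
        "counts": {},
    }

    if "simulate" in config.stages:
        sim = config.simulation or SimulationConfig()
        if config.seed is not None:
            sim = sim.replace(seed=config.seed)
        manifest["seed"] = sim.seed
        spectra, samples, truth = simulate_experiment(sim)
        curve_spectra, curve_samples = simulate_standard_curve(sim, config.curve_cell_counts)
        write_spectra_table(spectra, out / "spectra.csv")
        write_samples(samples, out / "samples.csv")
        write_spectra_table(curve_spectra, out / "curve_spectra.csv")
        write_samples(curve_samples, out / "curve_samples.csv")
        write_targets(sim.lipid_panel, out / "targets.csv")
        truth.labels.rename_axis("sample_id").to_csv(out / "truth_labels.csv")
        truth.abundances.rename_axis("sample_id").to_csv(
            out / "truth_abundance.csv", float_format=lambda v: repr(float(v))
        )
        manifest["counts"]["simulate"] = {
            "wells": len(spectra),
            "labels": truth.labels.value_counts().to_dict(),
            "curve_wells": len(curve_spectra),
        }
    elif config.spectra_path is not None:
        # stage inputs supplied externally: stage files into the run directory
        spectra = read_spectra(config.spectra_path)
        write_spectra_table(spectra, out / "spectra.csv")
        write_samples(read_samples(config.samples_path), out / "samples.csv")
        write_targets(read_targets(config.targets_path), out / "targets.csv")
        if config.curve_spectra_path is not None:
            write_spectra_table(read_spectra(config.curve_spectra_path), out / "curve_spectra.csv")
            write_samples(read_samples(config.curve_samples_path), out / "curve_samples.csv")

    if "match" in config.stages:
        _require(out, "match", "spectra.csv", "targets.csv", "samples.csv")
        spectra = read_spectra(out / "spectra.csv")
        targets = read_targets(out / "targets.csv")
        samples = read_samples(out / "samples.csv")
        matches, raw = match_all(spectra, targets, thr)
        matches.to_csv(out / "matches.csv", index=False, float_format=lambda v: repr(float(v)))
        write_matrix(raw, out / "raw_matrix.csv")
        blank_ids = set(samples.loc[samples["sample_type"] == "blank", "sample_id"])
        blanks = [s for s in spectra if s.sample_id in blank_ids]
        if blanks:
            markers = [t for t in targets if t.name in thr.marker_lipids]
            blank_assessment(blanks, markers, thr).to_csv(
                out / "blank_assessment.csv", index=False, float_format=lambda v: repr(float(v))
            )
        if (out / "curve_spectra.csv").exists():
            curve_spectra = read_spectra(out / "curve_spectra.csv")
            _, curve_raw = match_all(curve_spectra, targets, thr)
            write_matrix(curve_raw, out / "curve_matrix.csv")
        manifest["counts"]["match"] = {
            "spectra": len(spectra),
            "targets": len(targets),
            "detected_pairs": int(matches["detected"].sum()),
        }

    if "sample-qc" in config.stages:
        _require(out, "sample-qc", "matches.csv", "raw_matrix.csv", "samples.csv")
        matches = pd.read_csv(out / "matches.csv")
        raw = read_matrix(out / "raw_matrix.csv")
        samples = read_samples(out / "samples.csv")
        frames = []
        for _, sub in samples.groupby("experiment_id"):
            ids = set(sub["sample_id"])
            frames.append(
                classify_samples(
                    matches[matches["sample_id"].isin(ids)],
                    raw.subset([s for s in raw.sample_ids if s in ids]),
                    sub,
                    thr,
                )
            )
        qc = pd.concat(frames, ignore_index=True)
        qc.to_csv(out / "sample_qc.csv", index=False, float_format=lambda v: repr(float(v)))
        manifest["counts"]["sample-qc"] = qc["status"].value_counts().to_dict()

    if "normalize" in config.stages:
        _require(out, "normalize", "raw_matrix.csv", "sample_qc.csv", "samples.csv")
        raw = read_matrix(out / "raw_matrix.csv")
        samples = read_samples(out / "samples.csv")
        qc = pd.read_csv(out / "sample_qc.csv")
        passing = qc.loc[qc["status"] == STATUS_PASS, "sample_id"].astype(str)
        keep_types = samples["sample_type"].isin(["qc_pool"])
        keep = sorted(set(passing) | set(samples.loc[keep_types, "sample_id"]))
        usable = raw.subset([s for s in raw.sample_ids if s in keep])
        detected_any = usable.values.notna().any(axis=1)
        usable = usable.subset(list(usable.values.index[detected_any]))
        norm = total_signal_normalize(usable)
        write_matrix(norm, out / "normalized_matrix.csv")
        qc_meta = samples[samples["sample_type"] == "qc_pool"]
        n_plates_with_qc = (
            qc_meta.groupby("plate")["sample_id"].count().ge(2).sum() if len(qc_meta) else 0
        )
        if n_plates_with_qc >= 2:
            qc_ids = [s for s in usable.sample_ids if s in set(qc_meta["sample_id"])]
            batch = plate_batch_check(
                usable.subset(qc_ids), norm.subset(qc_ids), samples
            )
            batch.to_csv(out / "batch_check.csv", index=False, float_format=lambda v: repr(float(v)))
            manifest["counts"]["normalize"] = {
                "samples_normalized": norm.shape[0],
                "batch_effect_removed": int(batch["batch_effect_removed"].sum()),
            }
        else:
            manifest["counts"]["normalize"] = {"samples_normalized": norm.shape[0]}
        order_seed = manifest["seed"] if manifest["seed"] is not None else (config.seed or 0)
        cell_ids = [s for s in norm.sample_ids if s in set(passing)]
        if len(cell_ids) >= 3:
            injection_order_check(
                norm.subset(cell_ids), samples, seed=order_seed
            ).to_csv(out / "injection_order.csv", index=False, float_format=lambda v: repr(float(v)))

    if "lipid-qc" in config.stages:
        _require(out, "lipid-qc", "matches.csv", "raw_matrix.csv", "sample_qc.csv", "samples.csv")
        matches = pd.read_csv(out / "matches.csv")
        raw = read_matrix(out / "raw_matrix.csv")
        samples = read_samples(out / "samples.csv")
        qc = pd.read_csv(out / "sample_qc.csv")
        passing = set(qc.loc[qc["status"] == STATUS_PASS, "sample_id"].astype(str))
        curve_matrix = curve_counts = None
        if (out / "curve_matrix.csv").exists():
            curve_matrix = read_matrix(out / "curve_matrix.csv")
            curve_samples = read_samples(out / "curve_samples.csv")
            curve_counts = curve_samples.set_index("sample_id")["n_cells"]
        reports = []
        for exp_id, sub in samples.groupby("experiment_id"):
            if exp_id == "curve":
                continue
            ids = [s for s in sub["sample_id"] if s in passing]
            if not ids:
                continue
            reports.append(
                apply_filters(
                    matches, raw, ids, curve_matrix, curve_counts, thr, experiment_id=str(exp_id)
                )
            )
        lipid_report = pd.concat(reports, ignore_index=True)
        lipid_report.to_csv(out / "lipid_qc.csv", index=False, float_format=lambda v: repr(float(v)))
        manifest["counts"]["lipid-qc"] = {
            "lipids_passing_per_experiment": lipid_report.groupby("experiment_id")["passes"]
            .sum()
            .astype(int)
            .to_dict()
        }

    if "tiers" in config.stages:
        _require(out, "tiers", "lipid_qc.csv")
        lipid_report = pd.read_csv(out / "lipid_qc.csv")
        tiers = assign_tiers(lipid_report)
        tiers.to_csv(out / "tiers.csv", index=False)
        manifest["counts"]["tiers"] = {
            "levels": tiers["level"].value_counts().sort_index().to_dict(),
            "dropped": tiers.attrs["n_dropped"],
        }

    if "stats" in config.stages:
        _require(out, "stats", "normalized_matrix.csv", "sample_qc.csv", "samples.csv")
        norm = read_matrix(out / "normalized_matrix.csv")
        samples = read_samples(out / "samples.csv")
        qc = pd.read_csv(out / "sample_qc.csv")
        passing = qc.loc[qc["status"] == STATUS_PASS, "sample_id"].astype(str)
        cells = norm.subset([s for s in norm.sample_ids if s in set(passing)])
        profiles = population_profiles(cells, samples)
        profiles.to_csv(out / "population_profiles.csv", float_format=lambda v: repr(float(v)))
        variables = list(cells.values.columns) + ["PC/PE"]
        geno_rows = []
        for var in variables:
            comp = genotype_test(cells, samples, var)
            geno_rows.append(comp.as_row())
        pd.DataFrame(geno_rows).to_csv(
            out / "genotype_tests.csv", index=False, float_format=lambda v: repr(float(v))
        )
        cohort, rule = stratify_by_lipid(cells, samples, config.stratify_lipid)
        cohort.to_csv(out / "strata.csv", index=False)
        strat = stratified_tests(cells, cohort)
        strat.to_csv(out / "stratified_tests.csv", index=False, float_format=lambda v: repr(float(v)))
        manifest["counts"]["stats"] = {
            "cells_tested": cells.shape[0],
            "stratification": rule,
            "significant_stratified": int(
                (strat["evaluable"] & (strat["p_value"] < 0.05)).sum()
            ),
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
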