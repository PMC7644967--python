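"""Downstream comparisons: genotype contrasts, stratification and lipid ratios.

Group contrasts use a Gaussian linear model of log-transformed unit-sum
abundances on the group indicator (multiplicative noise is the norm for MS
intensities), with a two-sided Wald test on the group coefficient; with a
single binary covariate this is exactly the equal-variance two-sample
t-test. Fold changes are reported on the natural scale as the ratio of
group means. Raw p-values are the primary decision quantity; Benjamini-
Hochberg q-values are reported alongside.

Cells can further be stratified into high/low strata by one lipid's
abundance (within-genotype median split; ties at the median go to low) to
ask which other lipids mirror that heterogeneity, and the per-sample ratio
of total PC to total PE is available as a derived membrane-composition
variable that is invariant to total-signal normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import AbundanceMatrix, parse_lipid_name

__all__ = [
    "GroupComparison",
    "population_profiles",
    "genotype_test",
    "stratify_by_lipid",
    "stratified_tests",
    "pc_pe_ratio",
    "density_summary",
]


@dataclass
class GroupComparison:
    """Two-group contrast of one variable (a lipid or the PC/PE ratio)."""

    variable: str
    reference: str
    comparison: str
    n: dict[str, int]
    mean: dict[str, float]
    sd: dict[str, float]
    fold_change: float | None  # mean(comparison) / mean(reference)
    p_value: float | None
    evaluable: bool
    note: str = ""

    def as_row(self) -> dict:
        return {
            "variable": self.variable,
            "reference": self.reference,
            "comparison": self.comparison,
            "n_reference": self.n.get(self.reference, 0),
            "n_comparison": self.n.get(self.comparison, 0),
            "mean_reference": self.mean.get(self.reference, np.nan),
            "mean_comparison": self.mean.get(self.comparison, np.nan),
            "sd_reference": self.sd.get(self.reference, np.nan),
            "sd_comparison": self.sd.get(self.comparison, np.nan),
            "fold_change": np.nan if self.fold_change is None else self.fold_change,
            "p_value": np.nan if self.p_value is None else self.p_value,
            "evaluable": self.evaluable,
            "note": self.note,
        }


def _variable_values(matrix: AbundanceMatrix, variable: str) -> pd.Series:
    if variable == "PC/PE":
        return pc_pe_ratio(matrix)
    if variable not in matrix.values.columns:
        raise KeyError(f"variable {variable!r} not in matrix")
    return matrix.values[variable]


def population_profiles(matrix: AbundanceMatrix, samples: pd.DataFrame) -> pd.DataFrame:
    """Mean lipid profile per (genotype, replicate) over single-cell samples.

    Averages are over detected values only; a lipid missing in every cell of
    a replicate stays missing in that population profile. Replicates with
    zero cells are dropped with a warning. The ``n_cells`` column reports the
    cell count behind each profile.
    """
    cells = samples[samples["sample_type"] == "single_cell"].set_index("sample_id")
    ids = [s for s in matrix.sample_ids if s in cells.index]
    if not ids:
        raise ValueError("no single-cell samples present in the matrix")
    vals = matrix.values.loc[ids]
    keys = cells.loc[ids, ["genotype", "replicate"]]
    grouped = vals.groupby([keys["genotype"], keys["replicate"]])
    profiles = grouped.mean()
    profiles["n_cells"] = grouped.size()
    empty = profiles.index[profiles["n_cells"] == 0].tolist()
    if empty:  # pragma: no cover - groupby never emits empty groups
        warnings.warn(f"dropping empty replicates: {empty}", stacklevel=2)
        profiles = profiles.drop(index=empty)
    return profiles


def _two_group_fit(
    variable: str,
    values: pd.Series,
    group: pd.Series,
    reference: str,
    comparison: str,
    log_transform: bool,
) -> GroupComparison:
    note = ""
    df = pd.DataFrame({"y": values, "g": group}).dropna()
    if log_transform:
        pos = df["y"] > 0
        if not pos.all():
            note = f"dropped {int((~pos).sum())} non-positive value(s) before log transform"
            df = df[pos]
    ref = df.loc[df["g"] == reference, "y"]
    cmp_ = df.loc[df["g"] == comparison, "y"]
    n = {reference: int(len(ref)), comparison: int(len(cmp_))}
    mean = {reference: float(ref.mean()), comparison: float(cmp_.mean())}
    sd = {reference: float(ref.std(ddof=1)), comparison: float(cmp_.std(ddof=1))}
    fc = mean[comparison] / mean[reference] if mean.get(reference) else None
    if len(ref) < 3 or len(cmp_) < 3:
        return GroupComparison(
            variable, reference, comparison, n, mean, sd, fc, None, False,
            note or "fewer than 3 non-missing values in a group",
        )
    y = np.log(df["y"].to_numpy()) if log_transform else df["y"].to_numpy()
    if np.ptp(y) == 0:
        return GroupComparison(
            variable, reference, comparison, n, mean, sd, fc, None, False,
            "degenerate variance",
        )
    x = sm.add_constant((df["g"] == comparison).to_numpy(float))
    res = sm.OLS(y, x).fit()
    p = float(res.pvalues[1])
    if np.isnan(p):
        return GroupComparison(
            variable, reference, comparison, n, mean, sd, fc, None, False,
            "degenerate variance",
        )
    return GroupComparison(variable, reference, comparison, n, mean, sd, fc, p, True, note)


def genotype_test(
    matrix: AbundanceMatrix,
    samples: pd.DataFrame,
    variable: str,
    log_transform: bool = True,
    reference: str | None = None,
) -> GroupComparison:
    """Two-genotype contrast of one lipid (or "PC/PE") over single cells.

    Fits a Gaussian linear model of the (log-transformed by default)
    abundance on the genotype indicator; the two-sided Wald p-value of the
    indicator is reported together with the natural-scale fold change
    relative to the reference genotype (default: first in sorted order).
    """
    cells = samples[samples["sample_type"] == "single_cell"].set_index("sample_id")
    values = _variable_values(matrix, variable)
    values = values[values.index.isin(cells.index)]
    group = cells.loc[values.index, "genotype"]
    levels = sorted(g for g in group.dropna().unique() if g != "")
    if len(levels) != 2:
        raise ValueError(f"genotype_test needs exactly 2 genotypes, found {levels}")
    ref = reference if reference is not None else levels[0]
    if ref not in levels:
        raise ValueError(f"reference {ref!r} not among genotypes {levels}")
    other = [g for g in levels if g != ref][0]
    return _two_group_fit(variable, values, group, ref, other, log_transform)


def stratify_by_lipid(
    matrix: AbundanceMatrix,
    samples: pd.DataFrame,
    lipid: str = "PC 36:2",
) -> tuple[pd.DataFrame, dict]:
    """Split single cells into high/low strata by one lipid's abundance.

    Median split within each genotype; values tied with the median go to the
    low stratum. Cells in which the lipid is missing are unassigned and
    excluded. Returns the cohort table (sample_id, genotype, stratum) and a
    record of the rule applied (per-genotype thresholds, degeneracy flags).
    """
    if lipid not in matrix.values.columns:
        raise KeyError(f"stratification lipid {lipid!r} not in matrix")
    cells = samples[samples["sample_type"] == "single_cell"].set_index("sample_id")
    vals = matrix.values[lipid]
    vals = vals[vals.index.isin(cells.index)].dropna()
    rule: dict = {"lipid": lipid, "rule": "median split within genotype; ties to low", "thresholds": {}}
    rows = []
    for genotype, sub in vals.groupby(cells.loc[vals.index, "genotype"]):
        if len(sub) < 4:
            raise ValueError(
                f"genotype {genotype!r} has only {len(sub)} assignable cells (need >= 4)"
            )
        med = float(sub.median())
        rule["thresholds"][genotype] = med
        if float(sub.min()) == float(sub.max()):
            rule.setdefault("degenerate", []).append(genotype)
        for sid, v in sub.items():
            rows.append(
                {"sample_id": sid, "genotype": genotype, "stratum": "low" if v <= med else "high"}
            )
    return pd.DataFrame(rows), rule


def stratified_tests(
    matrix: AbundanceMatrix,
    cohort: pd.DataFrame,
    variables: list[str] | None = None,
    log_transform: bool = True,
) -> pd.DataFrame:
    """High-vs-low contrasts within each genotype for every variable.

    ``variables`` defaults to every lipid in the matrix plus the derived
    "PC/PE" ratio. Fold change is relative to the low stratum. Benjamini-
    Hochberg q-values are computed within genotype across evaluable
    variables.
    """
    if variables is None:
        variables = list(matrix.values.columns) + ["PC/PE"]
    frames = []
    for genotype, sub in cohort.groupby("genotype"):
        stratum = sub.set_index("sample_id")["stratum"]
        rows = []
        for var in variables:
            values = _variable_values(matrix, var)
            values = values[values.index.isin(stratum.index)]
            comp = _two_group_fit(var, values, stratum.loc[values.index], "low", "high", log_transform)
            row = comp.as_row()
            row["genotype"] = genotype
            rows.append(row)
        gdf = pd.DataFrame(rows)
        mask = gdf["evaluable"] & gdf["p_value"].notna()
        gdf["q_value"] = np.nan
        if mask.any():
            gdf.loc[mask, "q_value"] = multipletests(
                gdf.loc[mask, "p_value"].to_numpy(), method="fdr_bh"
            )[1]
        frames.append(gdf)
    return pd.concat(frames, ignore_index=True)


def pc_pe_ratio(matrix: AbundanceMatrix) -> pd.Series:
    """Per-sample ratio of total detected PC signal to total detected PE signal.

    Not evaluable (NaN) for samples with no detected PC or no detected PE.
    Because numerator and denominator share any per-sample divisor, the ratio
    is invariant to total-signal normalization.
    """
    classes = {name: parse_lipid_name(name)[0] for name in matrix.values.columns}
    pc_cols = [n for n, c in classes.items() if c == "PC"]
    pe_cols = [n for n, c in classes.items() if c == "PE"]
    if not pc_cols or not pe_cols:
        raise ValueError("matrix must contain both PC and PE lipids")
    pc = matrix.values[pc_cols]
    pe = matrix.values[pe_cols]
    num = pc.sum(axis=1, skipna=True)
    den = pe.sum(axis=1, skipna=True)
    ok = pc.notna().any(axis=1) & pe.notna().any(axis=1) & (den > 0)
    out = pd.Series(np.nan, index=matrix.values.index, name="PC/PE")
    out[ok] = num[ok] / den[ok]
    return out


def density_summary(values: pd.Series, n_points: int = 128) -> pd.DataFrame:
    """Gaussian-KDE density grid of one variable, for plotting elsewhere.

    Returns columns ``x`` and ``density``; needs >= 3 distinct finite values.
    """
    v = pd.Series(values).dropna().to_numpy(float)
    if np.unique(v).size < 3:
        raise ValueError("density_summary needs >= 3 distinct values")
    kde = sps.gaussian_kde(v)
    pad = 0.1 * np.ptp(v)
    x = np.linspace(v.min() - pad, v.max() + pad, n_points)
    return pd.DataFrame({"x": x, "density": kde(x)})
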