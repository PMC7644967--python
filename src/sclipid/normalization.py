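"""Total-signal normalization and batch/injection-order diagnostics.

Cell size is the dominant driver of raw single-cell signal (a bigger cell
simply contains more lipid), so abundances are divided by the sample's total
detected signal, turning each profile into unit-sum composition. The same
division removes multiplicative plate batch effects, which is verified here
by a per-lipid between-plate test on the pooled-QC wells before and after
normalization, and by checking that ordination coordinates of the normalized
profiles carry no injection-order trend.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import AbundanceMatrix

__all__ = ["total_signal_normalize", "plate_batch_check", "injection_order_check", "pca_scores"]


def total_signal_normalize(raw: AbundanceMatrix) -> AbundanceMatrix:
    """Divide each detected value by the sum of its sample's detected values.

    Missing values stay missing and do not enter the denominator. Idempotent:
    a unit-sum matrix is returned unchanged. A sample with zero detected
    lipids is an error naming the sample — it should have been excluded by
    sample QC upstream.
    """
    vals = raw.values
    totals = vals.sum(axis=1, skipna=True)
    dead = totals[(totals == 0) | vals.notna().sum(axis=1).eq(0)]
    if len(dead):
        raise ValueError(
            f"sample(s) with no detected signal cannot be normalized: {list(dead.index)[:5]}"
        )
    return AbundanceMatrix(vals.div(totals, axis=0), normalized=True)


def _group_test(groups: list[np.ndarray], test: str) -> float:
    """Between-group p-value; degenerate (zero-variance) input maps to p = 1."""
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if test == "anova":
            stat = sps.f_oneway(*groups)
        else:
            stat = sps.kruskal(*groups)
    p = float(stat.pvalue)
    return 1.0 if np.isnan(p) else p


def plate_batch_check(
    raw: AbundanceMatrix,
    normalized: AbundanceMatrix,
    samples: pd.DataFrame,
    test: str = "anova",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-lipid between-plate test on pooled-QC wells, raw vs normalized.

    ``test`` is ``"anova"`` (one-way, default) or ``"kruskal"``. Plates with
    fewer than 2 QC wells are dropped with a warning; at least 2 usable
    plates are required. Returns one row per lipid with the raw and
    normalized p-values, per-plate means, and ``batch_effect_removed``
    (raw p < alpha and normalized p >= alpha).
    """
    if test not in ("anova", "kruskal"):
        raise ValueError("test must be 'anova' or 'kruskal'")
    qc = samples[samples["sample_type"] == "qc_pool"]
    counts = qc.groupby("plate")["sample_id"].count()
    small = counts[counts < 2].index.tolist()
    if small:
        warnings.warn(f"dropping plates with < 2 QC wells: {small}", stacklevel=2)
        qc = qc[~qc["plate"].isin(small)]
    plates = sorted(qc["plate"].unique())
    if len(plates) < 2:
        raise ValueError("plate_batch_check needs >= 2 plates with >= 2 QC wells each")
    rows = []
    for lipid in raw.lipid_names:
        row: dict = {"lipid_name": lipid}
        pvals = {}
        for label, matrix in (("raw", raw), ("normalized", normalized)):
            groups = []
            for p in plates:
                ids = qc.loc[qc["plate"] == p, "sample_id"]
                v = matrix.values.loc[ids, lipid].dropna().to_numpy()
                groups.append(v)
                row[f"mean_{label}_plate{p}"] = float(v.mean()) if v.size else np.nan
            usable = [g for g in groups if g.size >= 2]
            pvals[label] = _group_test(usable, test) if len(usable) >= 2 else np.nan
        row["p_raw"] = pvals["raw"]
        row["p_normalized"] = pvals["normalized"]
        row["batch_effect_removed"] = bool(
            pvals["raw"] < alpha and pvals["normalized"] >= alpha
        )
        rows.append(row)
    return pd.DataFrame(rows)


def pca_scores(matrix: AbundanceMatrix, n_components: int = 2) -> pd.DataFrame:
    """Principal-component scores of profiles, with min/2 imputation of missing.

    Each lipid's missing values are imputed as half its observed minimum
    (a below-LLOD surrogate); columns with no observed value are dropped.
    Scores are computed on centred values.
    """
    from sklearn.decomposition import PCA

    vals = matrix.values.copy()
    vals = vals.loc[:, vals.notna().any(axis=0)]
    fill = vals.min(axis=0, skipna=True) / 2.0
    vals = vals.fillna(fill)
    k = min(n_components, vals.shape[0] - 1, vals.shape[1])
    if k < 1:
        raise ValueError("not enough samples for ordination")
    scores = PCA(n_components=k, svd_solver="full").fit_transform(vals.to_numpy())
    return pd.DataFrame(
        scores, index=vals.index, columns=[f"PC{i + 1}" for i in range(k)]
    )


def injection_order_check(
    matrix: AbundanceMatrix,
    samples: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Spearman association of the first two ordination coordinates with injection order.

    Permutation p-values (order labels shuffled) guard against the
    small-sample normal approximation. Fewer than 3 samples or a constant
    coordinate yields rho = 0 with p marked not-evaluable (NaN handled as
    association 0 by convention).
    """
    meta = samples.set_index("sample_id")
    ids = [s for s in matrix.sample_ids if s in meta.index]
    order = meta.loc[ids, "injection_order"].to_numpy(float)
    if len(ids) < 3:
        return pd.DataFrame(
            [{"coordinate": "PC1", "rho": np.nan, "p_value": np.nan, "evaluable": False}]
        )
    scores = pca_scores(matrix.subset(ids), n_components=2)
    rng = np.random.default_rng(seed)
    rows = []
    for col in scores.columns:
        y = scores[col].to_numpy()
        if np.ptp(y) == 0 or np.ptp(order) == 0:
            rows.append({"coordinate": col, "rho": 0.0, "p_value": 1.0, "evaluable": True})
            continue
        rho = float(sps.spearmanr(order, y).statistic)
        perm = np.empty(n_permutations)
        for i in range(n_permutations):
            perm[i] = sps.spearmanr(rng.permutation(order), y).statistic
        p = float((np.sum(np.abs(perm) >= abs(rho)) + 1) / (n_permutations + 1))
        rows.append({"coordinate": col, "rho": rho, "p_value": p, "evaluable": True})
    return pd.DataFrame(rows)
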