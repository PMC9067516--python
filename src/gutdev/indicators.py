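"""Indicator-species analysis and group-difference statistics.

IndVal for a feature and group g is the product of specificity
``A = mean abundance in g / sum of group mean abundances`` and fidelity
``B = fraction of g's samples where the feature is present``; the
statistic is the maximum of A*B over groups and its significance comes
from permuting group labels (add-one rule).  Group differences use
Kruskal-Wallis with Dunn's post hoc z tests (normal approximation, tie
corrected) and Benjamini-Hochberg adjustment; covariate-adjusted
associations use a fixed-effects linear model on transformed
abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .data import AbundanceTable, to_relative

__all__ = [
    "IndicatorResult",
    "indval_indicators",
    "kruskal_dunn_bh",
    "covariate_adjusted_associations",
]


@dataclass
class IndicatorResult:
    feature_id: str
    best_group: str
    A: float
    B: float
    indval: float
    p: float
    n_perm: int
    significant: bool


def _indval_stats(
    X: np.ndarray, codes: np.ndarray, n_groups: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-feature IndVal: returns (stat, best_group, A, B)."""
    means = np.empty((n_groups, X.shape[1]))
    pres = np.empty((n_groups, X.shape[1]))
    for g in range(n_groups):
        sub = X[codes == g]
        means[g] = sub.mean(axis=0)
        pres[g] = (sub > 0).mean(axis=0)
    denom = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(denom > 0, means / denom, 0.0)
    iv = a * pres
    best = iv.argmax(axis=0)
    cols = np.arange(X.shape[1])
    return iv[best, cols], best, a[best, cols], pres[best, cols]


def indval_indicators(
    table: AbundanceTable,
    groups: pd.Series | np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """IndVal statistics with a seeded permutation test per feature.

    Expects features already filtered (>10 % prevalence and >0.01 % mean
    relative abundance in at least one group is the upstream default).
    Returns one row per feature with A, B, indval, best group, p and a
    significance flag at ``alpha``.
    """
    rel = table if table.kind == "relative" else to_relative(table)
    groups = pd.Series(np.asarray(groups), index=rel.values.index)
    codes, uniques = pd.factorize(groups)
    if (np.bincount(codes) < 2).any():
        small = uniques[np.argmin(np.bincount(codes))]
        raise ValueError(f"group {small!r} has fewer than 2 samples")
    X = rel.matrix()
    stat, best, a, b = _indval_stats(X, codes, len(uniques))
    rng = np.random.default_rng(seed)
    hits = np.zeros(X.shape[1], dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        pstat, *_ = _indval_stats(X, perm, len(uniques))
        hits += pstat >= stat
    p = (1 + hits) / (n_perm + 1)
    out = pd.DataFrame(
        {
            "feature_id": rel.feature_ids,
            "best_group": [str(uniques[i]) for i in best],
            "A": a,
            "B": b,
            "indval": stat,
            "p": p,
            "n_perm": n_perm,
            "significant": p < alpha,
        }
    ).set_index("feature_id")
    return out.sort_values("indval", ascending=False)


def _dunn_pairs(values: np.ndarray, codes: np.ndarray, uniques) -> list[dict]:
    """Dunn's pairwise z tests on pooled ranks with tie correction."""
    n = values.size
    ranks = sps.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    rows = []
    k = len(uniques)
    for i in range(k):
        for j in range(i + 1, k):
            ni, nj = (codes == i).sum(), (codes == j).sum()
            ri = ranks[codes == i].mean()
            rj = ranks[codes == j].mean()
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / ni + 1.0 / nj))
            z = (ri - rj) / se if se > 0 else 0.0
            rows.append(
                {
                    "group_i": str(uniques[i]),
                    "group_j": str(uniques[j]),
                    "z": float(z),
                    "p": float(2 * sps.norm.sf(abs(z))),
                }
            )
    return rows


def kruskal_dunn_bh(
    table: AbundanceTable, groups: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Per-feature Kruskal-Wallis (or rank-sum for 2 groups) with Dunn + BH.

    BH adjustment runs across features for the omnibus p, and across
    pairwise comparisons within each feature separately.  Returns a
    tidy frame with one row per feature and a ``pairwise`` column of
    per-pair records.
    """
    groups = pd.Series(np.asarray(groups), index=table.values.index)
    codes, uniques = pd.factorize(groups)
    k = len(uniques)
    if k < 2:
        raise ValueError("need at least two groups")
    X = table.matrix()
    rows = []
    for f, fid in enumerate(table.feature_ids):
        v = X[:, f]
        if np.ptp(v) == 0:
            warnings.warn(f"feature {fid!r} is constant; p set to 1")
            rows.append({"feature_id": fid, "statistic": 0.0, "p": 1.0, "pairwise": []})
            continue
        samples = [v[codes == g] for g in range(k)]
        if k == 2:
            stat, p = sps.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
            pairwise = []
        else:
            stat, p = sps.kruskal(*samples)
            pairwise = _dunn_pairs(v, codes, uniques)
            if pairwise:
                _, q, _, _ = multipletests([r["p"] for r in pairwise], method="fdr_bh")
                for r, qi in zip(pairwise, q):
                    r["q"] = float(qi)
        rows.append(
            {"feature_id": fid, "statistic": float(stat), "p": float(p), "pairwise": pairwise}
        )
    out = pd.DataFrame(rows).set_index("feature_id")
    _, out["q"], _, _ = multipletests(out["p"], method="fdr_bh")
    return out


def covariate_adjusted_associations(
    table: AbundanceTable,
    meta: pd.DataFrame,
    target: str,
    covariates: list[str] | None = None,
    transform: str = "arcsinsqrt",
) -> pd.DataFrame:
    """Per-feature linear model of transformed abundance on target + covariates.

    A simplified fixed-effects analogue of the usual multivariable
    microbiome association model: no random subject effects, Gaussian
    errors on arcsine-square-root (default) or log10 transformed
    relative abundances.  BH adjustment across features.
    """
    import statsmodels.api as sm

    rel = table if table.kind == "relative" else to_relative(table)
    covariates = covariates or []
    cols = [target] + covariates
    design_raw = meta.loc[rel.values.index, cols]
    parts = []
    for c in cols:
        col = design_raw[c]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float).rename(c))
        else:
            dummies = pd.get_dummies(col, prefix=c, drop_first=True).astype(float)
            parts.append(dummies)
    design = pd.concat(parts, axis=1)
    design.insert(0, "const", 1.0)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {design.shape[1]}); "
            f"columns: {list(design.columns)}"
        )
    target_cols = [c for c in design.columns if c == target or c.startswith(f"{target}_")]

    X = rel.matrix()
    if transform == "arcsinsqrt":
        Y = np.arcsin(np.sqrt(np.clip(X, 0.0, 1.0)))
    elif transform == "log":
        Y = np.log10(X + 1e-6)
    else:
        raise ValueError(f"unknown transform {transform!r}")

    rows = []
    exog = design.to_numpy()
    for f, fid in enumerate(rel.feature_ids):
        fit = sm.OLS(Y[:, f], exog).fit()
        ti = design.columns.get_loc(target_cols[0])
        rows.append(
            {
                "feature_id": fid,
                "coef": float(fit.params[ti]),
                "statistic": float(fit.tvalues[ti]),
                "p": float(fit.pvalues[ti]),
            }
        )
    out = pd.DataFrame(rows).set_index("feature_id")
    _, out["q"], _, _ = multipletests(out["p"], method="fdr_bh")
    return out
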