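"""Distance-based community ecology statistics.

Bray-Curtis dissimilarity, Shannon diversity, non-metric
multidimensional scaling (NMDS), PERMANOVA, EnvFit covariate fitting,
LOESS heterogeneity curves, and PERMANOVA-based power estimation.

Permutation p-values everywhere use the add-one convention
``p = (1 + #extreme) / (n_perm + 1)``, so the smallest achievable p is
``1 / (n_perm + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.manifold import MDS
from statsmodels.nonparametric.smoothers_lowess import lowess

from .data import AbundanceTable, to_relative

__all__ = [
    "DistanceMatrix",
    "Ordination",
    "PermanovaResult",
    "PowerEstimate",
    "bray_curtis",
    "shannon_diversity",
    "nmds",
    "permanova",
    "envfit",
    "heterogeneity_curve",
    "permanova_power",
]


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with zero diagonal and sample ids."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have zero diagonal")

    def subset(self, ids: list[str]) -> "DistanceMatrix":
        pos = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.d[np.ix_(pos, pos)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


@dataclass
class Ordination:
    ids: list[str]
    coordinates: np.ndarray  # N x ndim, column-centred
    stress: float            # Kruskal stress-1
    n_restarts_used: int
    converged: bool = True


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_perm: int


@dataclass
class PowerEstimate:
    n_per_group: int
    power: float
    effect_size_omega2: float
    alpha: float
    n_boot: int


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on relative abundances: sum|x-y| / sum(x+y)."""
    rel = table if table.kind == "relative" else to_relative(table)
    d = squareform(pdist(rel.matrix(), metric="braycurtis"))
    return DistanceMatrix(rel.sample_ids, d)


def shannon_diversity(table: AbundanceTable) -> pd.Series:
    """Shannon index H = -sum p ln p (nats) per sample."""
    rel = table if table.kind == "relative" else to_relative(table)
    p = rel.matrix()
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
    return pd.Series(h, index=rel.values.index, name="shannon")


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

def _classical_scaling(d: np.ndarray, ndim: int) -> np.ndarray:
    """Torgerson classical metric scaling used as NMDS initialisation."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:ndim]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def nmds(
    dist: DistanceMatrix,
    ndim: int = 2,
    seed: int = 0,
    restarts: int = 10,
    max_iter: int = 300,
) -> Ordination:
    """Non-metric MDS minimising Kruskal stress-1, best of ``restarts``.

    Each restart starts from the classical-scaling configuration plus
    seeded Gaussian jitter (the first restart is unjittered).
    """
    n = len(dist.ids)
    if n <= ndim:
        raise ValueError("need more samples than ordination dimensions")
    base = _classical_scaling(dist.d, ndim)
    scale = np.abs(base).mean() + 1e-12
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray] | None = None
    used = 0
    for i in range(max(1, restarts)):
        init = base if i == 0 else base + rng.normal(0, 0.1 * scale, base.shape)
        mds = MDS(
            n_components=ndim,
            metric=False,
            dissimilarity="precomputed",
            n_init=1,
            max_iter=max_iter,
            normalized_stress=True,
            random_state=int(rng.integers(2**31)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords = mds.fit_transform(dist.d, init=init)
        used += 1
        if best is None or mds.stress_ < best[0]:
            best = (float(mds.stress_), coords)
    stress, coords = best
    coords = coords - coords.mean(axis=0, keepdims=True)
    return Ordination(list(dist.ids), coords, stress, used)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float, float, float]:
    """Pseudo-F from partitioned sums of squared distances.

    SS_total = sum_{i<j} d_ij^2 / N; SS_within = sum over groups of the
    within-group pair term; F = (SS_between/(k-1)) / (SS_within/(N-k)).
    """
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_between = ss_total - ss_within
    df_b = n_groups - 1
    df_w = n - n_groups
    f = (ss_between / df_b) / (ss_within / df_w) if ss_within > 0 else np.inf
    return f, ss_between, ss_within, ss_total


def permanova(
    dist: DistanceMatrix,
    labels: pd.Series | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA with seeded label permutations."""
    labels = pd.Series(np.asarray(labels), index=dist.ids)
    codes, uniques = pd.factorize(labels)
    k = len(uniques)
    if k < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise ValueError("every group needs at least two samples")
    d2 = dist.d**2
    f_obs, ssb, ssw, sst = _permanova_f(d2, codes, k)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        f_perm, *_ = _permanova_f(d2, perm, k)
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return PermanovaResult(float(f_obs), float(ssb / sst), float(p), n_perm)


# ---------------------------------------------------------------------------
# EnvFit
# ---------------------------------------------------------------------------

def envfit(
    ordination: Ordination,
    covariates: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit covariates onto ordination axes and permutation-test their r2.

    Continuous covariates: squared multiple correlation of the
    least-squares vector fit of the covariate onto the coordinates.
    Categorical covariates: fraction of coordinate variation explained
    by group centroids.  Significance by permuting covariate values.
    """
    covariates = covariates.loc[ordination.ids]
    coords = ordination.coordinates
    rng = np.random.default_rng(seed)
    rows = []
    for name in covariates.columns:
        col = covariates[name]
        numeric = pd.api.types.is_numeric_dtype(col)
        if numeric and col.nunique() <= 1 or (not numeric and col.nunique() <= 1):
            warnings.warn(f"covariate {name!r} is constant; r2=0, p=1")
            rows.append({"covariate": name, "r2": 0.0, "p": 1.0, "kind": "constant"})
            continue
        values = col.to_numpy()
        stat = _envfit_r2(coords, values, numeric)
        hits = 0
        for _ in range(n_perm):
            if _envfit_r2(coords, rng.permutation(values), numeric) >= stat:
                hits += 1
        rows.append(
            {
                "covariate": name,
                "r2": float(stat),
                "p": (1 + hits) / (n_perm + 1),
                "kind": "vector" if numeric else "factor",
            }
        )
    return pd.DataFrame(rows).set_index("covariate")


def _envfit_r2(coords: np.ndarray, values: np.ndarray, numeric: bool) -> float:
    if numeric:
        y = values.astype(float)
        y = y - y.mean()
        denom = (y**2).sum()
        if denom <= 0:
            return 0.0
        beta, *_ = np.linalg.lstsq(coords, y, rcond=None)
        fitted = coords @ beta
        return float((fitted**2).sum() / denom)
    codes, _ = pd.factorize(values)
    total = ((coords - coords.mean(axis=0)) ** 2).sum()
    if total <= 0:
        return 0.0
    within = 0.0
    for g in np.unique(codes):
        sub = coords[codes == g]
        within += ((sub - sub.mean(axis=0)) ** 2).sum()
    return float(1.0 - within / total)


# ---------------------------------------------------------------------------
# heterogeneity curve
# ---------------------------------------------------------------------------

def heterogeneity_curve(
    dist: DistanceMatrix,
    meta: pd.DataFrame,
    group: str,
    span: float = 0.75,
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Within-group heterogeneity vs age, LOESS-smoothed with bootstrap CI.

    Each sample's response is its mean Bray-Curtis distance to all other
    samples of the same group; the response is LOESS-regressed
    (tricube, locally linear) on age, with a 95 % percentile bootstrap
    CI over samples.
    """
    ids = [s for s in dist.ids if meta.loc[s, "group"] == group]
    if len(ids) < 10:
        raise ValueError(f"need >= 10 samples in group {group!r}, got {len(ids)}")
    sub = dist.subset(ids)
    n = len(ids)
    response = sub.d.sum(axis=1) / (n - 1)
    ages = meta.loc[ids, "age_months"].to_numpy(dtype=float)
    grid = np.unique(ages)
    fit = lowess(response, ages, frac=span, return_sorted=True, xvals=grid)
    rng = np.random.default_rng(seed)
    boots = np.full((n_boot, grid.size), np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            boots[b] = lowess(
                response[idx], ages[idx], frac=span, return_sorted=True, xvals=grid
            )
    lo = np.nanpercentile(boots, 2.5, axis=0)
    hi = np.nanpercentile(boots, 97.5, axis=0)
    return pd.DataFrame(
        {"age_months": grid, "heterogeneity": fit, "ci_lower": lo, "ci_upper": hi}
    )


# ---------------------------------------------------------------------------
# power analysis
# ---------------------------------------------------------------------------

def permanova_power(
    dist: DistanceMatrix,
    labels: pd.Series,
    n_per_group: int,
    alpha: float = 0.05,
    n_boot: int = 100,
    n_perm: int = 199,
    seed: int = 0,
) -> PowerEstimate:
    """Subsampling-based PERMANOVA power and effect size (omega^2).

    Repeatedly draws ``n_per_group`` samples per group, runs PERMANOVA,
    and reports the rejection fraction at ``alpha`` together with the
    mean omega^2 = (SS_between - (k-1) MS_within) / (SS_total + MS_within).
    """
    labels = pd.Series(np.asarray(labels), index=dist.ids)
    groups = labels.groupby(labels).groups
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, idx in groups.items():
        if len(idx) < n_per_group:
            raise ValueError(f"group {g!r} has only {len(idx)} samples (< {n_per_group})")
    rng = np.random.default_rng(seed)
    rejections = 0
    omegas = []
    id_arr = {g: np.asarray(idx) for g, idx in groups.items()}
    for b in range(n_boot):
        chosen = np.concatenate(
            [rng.choice(idx, size=n_per_group, replace=False) for idx in id_arr.values()]
        )
        sub = dist.subset(list(chosen))
        sub_labels = labels.loc[list(chosen)]
        res = permanova(sub, sub_labels, n_perm=n_perm, seed=int(rng.integers(2**31)))
        rejections += res.p < alpha
        codes, uniq = pd.factorize(sub_labels)
        k = len(uniq)
        _, ssb, ssw, sst = _permanova_f(sub.d**2, codes, k)
        ms_within = ssw / (len(chosen) - k)
        omegas.append((ssb - (k - 1) * ms_within) / (sst + ms_within))
    return PowerEstimate(
        n_per_group=n_per_group,
        power=rejections / n_boot,
        effect_size_omega2=float(np.mean(omegas)),
        alpha=alpha,
        n_boot=n_boot,
    )
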