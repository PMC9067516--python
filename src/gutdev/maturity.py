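"""Microbiota and metabolite maturity scoring.

Estimated microbiota age (EMA) is a random-forest regression of
chronological age on taxon relative abundances, trained on the healthy
(non-AD) reference group only.  Reference samples are scored with
out-of-bag (OOB) predictions so the per-age-bin reference statistics
are not optimistically biased.  The microbiota-for-age z-score (MAZ) of
a sample is

    MAZ = (EMA - median EMA of reference samples in the same age bin)
          / SD of reference EMA in that bin

and a negative MAZ indicates delayed maturation.  The same machinery
applied to SCFA concentration profiles yields the SCFA-for-age z-score
(SAZ).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, cross_val_predict

from .data import AGE_BINS, AbundanceTable, to_relative, validate_scfa

__all__ = [
    "MaturityModel",
    "rfcv_select",
    "fit_age_model",
    "predict_ema",
    "z_score_by_age",
    "fit_scfa_age_model",
    "predict_scfa_age",
    "maturity_correlation",
]

log = logging.getLogger(__name__)


@dataclass
class MaturityModel:
    """A reference-trained age-regression model with per-bin z statistics."""

    selected_features: list[str]
    cv_error_curve: list[tuple[int, float]]
    regressor: RandomForestRegressor
    reference_stats: dict[str, tuple[float, float]]  # age_bin -> (median, sd)
    training_group: str
    training_ids: list[str]
    oob_predictions: pd.Series
    feature_importances: pd.Series
    seed: int
    n_trees: int
    oob_reference: bool = True  # audit flag: reference scores are out-of-bag

    def usable_bins(self) -> list[str]:
        return [b for b, (_, sd) in self.reference_stats.items() if sd > 0]


def rfcv_select(
    table: AbundanceTable,
    ages: pd.Series,
    folds: int = 5,
    step: float = 0.5,
    seed: int = 0,
    n_trees: int = 500,
) -> tuple[list[str], list[tuple[int, float]]]:
    """Recursive feature elimination with cross-validated error.

    Repeatedly fits a forest, ranks features by impurity importance and
    keeps the top ``step`` fraction, recording the ``folds``-fold CV
    mean squared error at each set size.  Returns the smallest feature
    set achieving the minimum CV error, plus the full error curve.
    """
    rel = table if table.kind == "relative" else to_relative(table)
    y = ages.loc[rel.values.index].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("ages are constant; nothing to regress on")
    if rel.shape[0] < folds:
        raise ValueError("need at least as many samples as CV folds")
    features = list(rel.feature_ids)
    curve: list[tuple[int, float]] = []
    best_sets: dict[int, list[str]] = {}
    rng = np.random.default_rng(seed)
    while features:
        X = rel.values.loc[:, features].to_numpy(dtype=float)
        rs = int(rng.integers(2**31))
        rf = RandomForestRegressor(n_estimators=n_trees, random_state=rs, n_jobs=1)
        cv = KFold(n_splits=folds, shuffle=True, random_state=rs)
        pred = cross_val_predict(rf, X, y, cv=cv)
        curve.append((len(features), float(np.mean((pred - y) ** 2))))
        best_sets[len(features)] = list(features)
        if len(features) == 1:
            break
        rf.fit(X, y)
        order = np.argsort(rf.feature_importances_)[::-1]
        keep = max(1, int(np.floor(len(features) * step)))
        features = [features[i] for i in sorted(order[:keep])]
    min_err = min(err for _, err in curve)
    best_size = min(size for size, err in curve if err == min_err)
    return best_sets[best_size], curve


def fit_age_model(
    table: AbundanceTable,
    meta: pd.DataFrame,
    reference_group: str = "nonAD",
    n_trees: int = 1000,
    seed: int = 0,
    select_features: bool = True,
    rfcv_folds: int = 5,
    rfcv_trees: int = 200,
) -> MaturityModel:
    """Train the EMA forest on the reference group and store per-bin stats."""
    rel = table if table.kind == "relative" else to_relative(table)
    ref_ids = [s for s in rel.sample_ids if meta.loc[s, "group"] == reference_group]
    if not ref_ids:
        raise ValueError(f"no samples in reference group {reference_group!r}")
    ref_meta = meta.loc[ref_ids]
    for b in AGE_BINS:
        if b in meta["age_bin"].unique() and b not in set(ref_meta["age_bin"]):
            raise ValueError(f"reference group has no samples in age bin {b!r}")
    ref = rel.subset_samples(ref_ids)
    ages = ref_meta["age_months"].astype(float)

    if select_features and rel.shape[1] > 2:
        selected, curve = rfcv_select(
            ref, ages, folds=rfcv_folds, seed=seed, n_trees=rfcv_trees
        )
    else:
        selected, curve = list(rel.feature_ids), []

    X = ref.values.loc[:, selected].to_numpy(dtype=float)
    rf = RandomForestRegressor(
        n_estimators=n_trees,
        oob_score=True,
        random_state=seed,
        min_samples_leaf=5,  # ranger's regression default; smooths OOB noise
        n_jobs=1,
    )
    rf.fit(X, ages.to_numpy())
    oob = pd.Series(rf.oob_prediction_, index=ref_ids, name="ema_oob")

    stats: dict[str, tuple[float, float]] = {}
    for b, idx in ref_meta.groupby("age_bin", observed=True).groups.items():
        vals = oob.loc[idx]
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        if sd <= 0:
            log.warning("age bin %s has zero EMA spread; flagged unusable", b)
        stats[str(b)] = (float(vals.median()), sd)

    return MaturityModel(
        selected_features=selected,
        cv_error_curve=curve,
        regressor=rf,
        reference_stats=stats,
        training_group=reference_group,
        training_ids=ref_ids,
        oob_predictions=oob,
        feature_importances=pd.Series(rf.feature_importances_, index=selected),
        seed=seed,
        n_trees=n_trees,
    )


def predict_ema(model: MaturityModel, table: AbundanceTable) -> pd.Series:
    """Per-sample estimated microbiota age (months).

    Training (reference) samples get their out-of-bag prediction;
    everything else is predicted by the full forest.
    """
    rel = table if table.kind == "relative" else to_relative(table)
    missing = [f for f in model.selected_features if f not in rel.feature_ids]
    if missing:
        raise ValueError(f"table is missing model features: {missing}")
    X = rel.values.loc[:, model.selected_features].to_numpy(dtype=float)
    ema = pd.Series(model.regressor.predict(X), index=rel.values.index, name="ema")
    oob_ids = [s for s in rel.sample_ids if s in set(model.training_ids)]
    ema.loc[oob_ids] = model.oob_predictions.loc[oob_ids]
    return ema


def z_score_by_age(
    values: pd.Series,
    meta: pd.DataFrame,
    reference_stats: dict[str, tuple[float, float]],
) -> pd.Series:
    """Z-score each value against the reference median/SD of its age bin.

    Samples whose bin is absent or has zero reference SD get NaN (and a
    logged warning) rather than an error.
    """
    out = pd.Series(np.nan, index=values.index, name="z")
    for sid, v in values.items():
        b = meta.loc[sid, "age_bin"]
        if b not in reference_stats:
            log.warning("no reference statistics for age bin %s (sample %s)", b, sid)
            continue
        med, sd = reference_stats[b]
        if sd <= 0:
            log.warning("unusable age bin %s (zero SD); sample %s unscored", b, sid)
            continue
        out.loc[sid] = (v - med) / sd
    return out


def fit_scfa_age_model(
    scfa: pd.DataFrame,
    meta: pd.DataFrame,
    reference_group: str = "nonAD",
    n_trees: int = 1000,
    seed: int = 0,
) -> MaturityModel:
    """Train the SCFA-age forest (age on the six SCFA concentrations)."""
    scfa = validate_scfa(scfa)
    if scfa.shape[1] < 2:
        raise ValueError("need at least two metabolites")
    # concentrations are regressed as-is (no relative-abundance conversion)
    ref_ids = [s for s in scfa.index if meta.loc[s, "group"] == reference_group]
    if not ref_ids:
        raise ValueError(f"no samples in reference group {reference_group!r}")
    ref_meta = meta.loc[ref_ids]
    ages = ref_meta["age_months"].astype(float)
    X = scfa.loc[ref_ids].to_numpy(dtype=float)
    rf = RandomForestRegressor(
        n_estimators=n_trees,
        oob_score=True,
        random_state=seed,
        min_samples_leaf=5,
        n_jobs=1,
    )
    rf.fit(X, ages.to_numpy())
    oob = pd.Series(rf.oob_prediction_, index=ref_ids, name="scfa_age_oob")
    stats: dict[str, tuple[float, float]] = {}
    for b, idx in ref_meta.groupby("age_bin", observed=True).groups.items():
        vals = oob.loc[idx]
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        stats[str(b)] = (float(vals.median()), sd)
    return MaturityModel(
        selected_features=list(scfa.columns),
        cv_error_curve=[],
        regressor=rf,
        reference_stats=stats,
        training_group=reference_group,
        training_ids=ref_ids,
        oob_predictions=oob,
        feature_importances=pd.Series(rf.feature_importances_, index=list(scfa.columns)),
        seed=seed,
        n_trees=n_trees,
    )


def predict_scfa_age(model: MaturityModel, scfa: pd.DataFrame) -> pd.Series:
    """Per-sample SCFA-based age prediction (months); OOB for training samples."""
    missing = [f for f in model.selected_features if f not in scfa.columns]
    if missing:
        raise ValueError(f"SCFA table is missing metabolites: {missing}")
    X = scfa.loc[:, model.selected_features].to_numpy(dtype=float)
    pred = pd.Series(model.regressor.predict(X), index=scfa.index, name="scfa_age")
    oob_ids = [s for s in scfa.index if s in set(model.training_ids)]
    pred.loc[oob_ids] = model.oob_predictions.loc[oob_ids]
    return pred


def maturity_correlation(scores: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between MAZ and SAZ columns."""
    paired = scores[["maz", "saz"]].dropna()
    if len(paired) < 3:
        raise ValueError("need at least 3 samples with both MAZ and SAZ")
    r, p = pearsonr(paired["maz"], paired["saz"])
    return float(r), float(p)
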