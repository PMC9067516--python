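"""Maturity scoring: EMA regression, MAZ/SAZ z-scores."""

import logging

import numpy as np
import pandas as pd
import pytest

from gutdev import AbundanceTable, default_config, generate_cohort, to_relative
from gutdev.maturity import (
    fit_age_model,
    fit_scfa_age_model,
    maturity_correlation,
    predict_ema,
    predict_scfa_age,
    rfcv_select,
    z_score_by_age,
)


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(default_config(n_samples=200, seed=21))


@pytest.fixture(scope="module")
def age_model(cohort):
    return fit_age_model(
        to_relative(cohort.counts), cohort.metadata, n_trees=300, seed=21,
        select_features=False,
    )


class TestRfcv:
    def test_curve_structure_and_planted_recovery(self, rng):
        n, n_noise = 150, 35
        informative = rng.random((n, 5))
        ages = 6 + 30 * informative.mean(axis=1)
        noise = rng.random((n, n_noise))
        X = np.hstack([informative, noise])
        X = X / X.sum(axis=1, keepdims=True)
        cols = [f"inf{i}" for i in range(5)] + [f"noise{i}" for i in range(n_noise)]
        t = AbundanceTable(
            pd.DataFrame(X, index=[f"s{i}" for i in range(n)], columns=cols),
            kind="relative",
        )
        selected, curve = rfcv_select(
            t, pd.Series(ages, index=t.values.index), seed=0, n_trees=150
        )
        sizes = [s for s, _ in curve]
        assert sizes[0] == 40 and all(a > b for a, b in zip(sizes, sizes[1:]))
        if len(selected) >= 5:
            assert sum(f.startswith("inf") for f in selected) >= 4

    def test_constant_ages_rejected(self, toy_counts):
        ages = pd.Series(10.0, index=toy_counts.values.index)
        with pytest.raises(ValueError, match="constant"):
            rfcv_select(to_relative(toy_counts), ages, folds=2)


class TestAgeModel:
    def test_reference_ema_tracks_age_monotone_signal(self):
        """With no subject-level maturation spread the OOB EMA tracks age."""
        cfg = default_config(n_samples=200, seed=13, maturity_sd=0.0)
        c = generate_cohort(cfg)
        m = fit_age_model(
            to_relative(c.counts), c.metadata, n_trees=300, seed=13,
            select_features=False,
        )
        ref = m.training_ids
        r = np.corrcoef(
            m.oob_predictions.loc[ref], c.metadata.loc[ref, "age_months"]
        )[0, 1]
        assert r > 0.9

    def test_reference_ema_tracks_age_default_cohort(self, cohort, age_model):
        """Developmental spread attenuates but does not break the age signal."""
        meta = cohort.metadata
        ref = age_model.training_ids
        r = np.corrcoef(
            age_model.oob_predictions.loc[ref], meta.loc[ref, "age_months"]
        )[0, 1]
        assert r > 0.7

    def test_reference_median_maz_zero_per_bin(self, cohort, age_model):
        rel = to_relative(cohort.counts)
        maz = z_score_by_age(predict_ema(age_model, rel), cohort.metadata,
                             age_model.reference_stats)
        ref_meta = cohort.metadata.loc[age_model.training_ids]
        for b, idx in ref_meta.groupby("age_bin", observed=True).groups.items():
            assert abs(maz.loc[idx].median()) < 1e-9

    def test_seed_reproducible(self, cohort):
        rel = to_relative(cohort.counts)
        m1 = fit_age_model(rel, cohort.metadata, n_trees=100, seed=5, select_features=False)
        m2 = fit_age_model(rel, cohort.metadata, n_trees=100, seed=5, select_features=False)
        assert m1.reference_stats == m2.reference_stats
        assert m1.selected_features == m2.selected_features

    def test_oob_discipline_flag(self, age_model):
        assert age_model.oob_reference

    def test_missing_reference_rejected(self, cohort):
        rel = to_relative(cohort.counts)
        meta = cohort.metadata.copy()
        with pytest.raises(ValueError, match="no samples in reference"):
            fit_age_model(rel, meta.assign(group="mildAD"), select_features=False)


class TestPredictEma:
    def test_training_samples_get_oob(self, cohort, age_model):
        rel = to_relative(cohort.counts)
        ema = predict_ema(age_model, rel)
        ref = age_model.training_ids
        pd.testing.assert_series_equal(
            ema.loc[ref], age_model.oob_predictions.loc[ref], check_names=False
        )

    def test_duplicated_sample_identical(self, cohort, age_model):
        rel = to_relative(cohort.counts)
        dup = AbundanceTable(
            pd.DataFrame(
                [rel.values.iloc[0].to_numpy()] * 2, index=["d1", "d2"],
                columns=rel.feature_ids,
            ),
            kind="counts",
        )
        dup.kind = "relative"
        ema = predict_ema(age_model, dup)
        assert ema.loc["d1"] == ema.loc["d2"]

    def test_missing_feature_listed(self, age_model):
        bad = AbundanceTable(
            pd.DataFrame([[1.0]], index=["x"], columns=["nope"]), kind="counts"
        )
        bad.kind = "relative"
        with pytest.raises(ValueError, match="missing model features"):
            predict_ema(age_model, bad)

    def test_disorder_pattern_recovered(self, cohort, age_model):
        """AD-group EMA exceeds reference before 12 months, reverses after."""
        rel = to_relative(cohort.counts)
        ema = predict_ema(age_model, rel)
        meta = cohort.metadata
        ad = meta["group"] != "nonAD"
        young = meta["age_months"] <= 12
        for sel, ref_sel, sign in (
            (ad & young, ~ad & young, 1),
            (ad & ~young, ~ad & ~young, -1),
        ):
            # compare per-bin to avoid age-composition confounding
            diffs = []
            for b in meta.loc[sel, "age_bin"].unique():
                a = ema[sel & (meta["age_bin"] == b)].mean()
                r = ema[ref_sel & (meta["age_bin"] == b)].mean()
                diffs.append(a - r)
            assert np.mean(diffs) * sign > 0


class TestZScore:
    def test_hand_example(self):
        # reference EMAs {10, 12, 14}: median 12, sample SD 2 -> z(16) = 2
        stats = {"m13_24": (12.0, 2.0)}
        meta = pd.DataFrame({"age_bin": ["m13_24"]}, index=["s"])
        z = z_score_by_age(pd.Series([16.0], index=["s"]), meta, stats)
        assert z.loc["s"] == pytest.approx(2.0)
        assert np.std([10, 12, 14], ddof=1) == pytest.approx(2.0)

    def test_median_and_one_sd(self):
        stats = {"m6": (8.0, 1.5)}
        meta = pd.DataFrame({"age_bin": ["m6", "m6"]}, index=["a", "b"])
        z = z_score_by_age(pd.Series([8.0, 9.5], index=["a", "b"]), meta, stats)
        assert z.loc["a"] == pytest.approx(0.0)
        assert z.loc["b"] == pytest.approx(1.0)

    def test_unusable_bin_gives_nan(self, caplog):
        stats = {"m6": (8.0, 0.0)}
        meta = pd.DataFrame({"age_bin": ["m6", "m25_36"]}, index=["a", "b"])
        with caplog.at_level(logging.WARNING):
            z = z_score_by_age(pd.Series([8.0, 30.0], index=["a", "b"]), meta, stats)
        assert z.isna().all()


class TestScfaModel:
    def test_butyrate_importance_ranks_first(self):
        """Only butyrate and propionate carry maturity signal; butyrate wins."""
        cfg = default_config(n_samples=200, seed=17)
        cfg.scfa_coupling = {
            "acetate": (60.0, 0.0, 5.0),
            "propionate": (4.0, 28.0, 1.0),
            "butyrate": (1.5, 50.0, 0.5),
            "iso-butyrate": (0.6, 0.0, 0.3),
            "valerate": (0.4, 0.0, 0.3),
            "iso-valerate": (0.8, 0.0, 0.3),
        }
        c = generate_cohort(cfg)
        m = fit_scfa_age_model(c.scfa, c.metadata, n_trees=300, seed=17)
        imp = m.feature_importances
        assert imp.idxmax() == "butyrate"
        assert imp["propionate"] > imp.drop(["butyrate", "propionate"]).max()

    def test_reference_median_saz_near_zero(self, cohort):
        m = fit_scfa_age_model(cohort.scfa, cohort.metadata, n_trees=300, seed=21)
        saz = z_score_by_age(predict_scfa_age(m, cohort.scfa), cohort.metadata,
                             m.reference_stats)
        ref_meta = cohort.metadata.loc[m.training_ids]
        for b, idx in ref_meta.groupby("age_bin", observed=True).groups.items():
            assert abs(saz.loc[idx].median()) < 1e-9


class TestCorrelation:
    def test_identity_gives_one(self):
        s = pd.DataFrame({"maz": [0.1, 0.5, -1.0, 2.0]})
        s["saz"] = s["maz"]
        r, p = maturity_correlation(s)
        assert r == pytest.approx(1.0)

    def test_shuffled_scores_uncorrelated(self, rng):
        rs = []
        for _ in range(50):
            maz = rng.standard_normal(100)
            s = pd.DataFrame({"maz": maz, "saz": rng.permutation(maz)})
            rs.append(maturity_correlation(s)[0])
        assert abs(np.mean(rs)) < 0.05

    def test_too_few_pairs_rejected(self):
        s = pd.DataFrame({"maz": [1.0, 2.0], "saz": [1.0, np.nan]})
        with pytest.raises(ValueError, match="at least 3"):
            maturity_correlation(s)
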