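"""Distance-based ecology statistics."""

import numpy as np
import pandas as pd
import pytest

from gutdev import AbundanceTable
from gutdev.ecology import (
    DistanceMatrix,
    bray_curtis,
    envfit,
    heterogeneity_curve,
    nmds,
    permanova,
    permanova_power,
    shannon_diversity,
)


def _rel(rows, ids=None):
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    return AbundanceTable(
        pd.DataFrame(rows, index=ids, columns=[f"f{j}" for j in range(rows.shape[1])]),
        kind="relative",
    )


class TestBrayCurtis:
    def test_hand_values(self):
        t = _rel([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.5, 0.5, 0.0], [1.0, 0.0, 0.0]])
        d = bray_curtis(t)
        assert d.d[0, 1] == pytest.approx(0.5)     # symmetric overlap
        assert d.d[0, 2] == pytest.approx(0.0)     # identical samples
        assert d.d[1, 3] == pytest.approx(1.0)     # disjoint supports
        assert np.allclose(d.d, d.d.T) and np.allclose(np.diag(d.d), 0)
        assert (d.d >= 0).all() and (d.d <= 1).all()


class TestShannon:
    def test_known_values(self):
        t = _rel([[1.0, 0, 0, 0], [0.25, 0.25, 0.25, 0.25], [0.5, 0.25, 0.25, 0.0]])
        h = shannon_diversity(t)
        assert h.iloc[0] == pytest.approx(0.0)
        assert h.iloc[1] == pytest.approx(np.log(4))
        assert h.iloc[2] == pytest.approx(1.0397, abs=1e-4)


class TestNmds:
    def test_line_embeds_with_low_stress(self):
        x = np.linspace(0, 1, 12)
        d = np.abs(x[:, None] - x[None, :])
        dist = DistanceMatrix([f"s{i}" for i in range(12)], d)
        o = nmds(dist, seed=0, restarts=4)
        assert o.stress < 0.01
        assert np.allclose(o.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_seed_determinism(self):
        rng = np.random.default_rng(0)
        pts = rng.random((10, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dist = DistanceMatrix([f"s{i}" for i in range(10)], d)
        o1 = nmds(dist, seed=3, restarts=3)
        o2 = nmds(dist, seed=3, restarts=3)
        np.testing.assert_array_equal(o1.coordinates, o2.coordinates)


class TestPermanova:
    def _toy(self):
        # 6 samples, 2 tight clusters
        pts = np.array([[0, 0], [0.1, 0], [0, 0.1], [5, 5], [5.1, 5], [5, 5.1]])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        return DistanceMatrix(list("abcdef"), d), pd.Series(
            ["g1"] * 3 + ["g2"] * 3, index=list("abcdef")
        )

    def test_f_matches_brute_force_oracle(self):
        dist, labels = self._toy()
        res = permanova(dist, labels, n_perm=99, seed=0)
        # explicit sums-of-squares oracle
        d2 = dist.d**2
        n, k = 6, 2
        sst = d2[np.triu_indices(n, 1)].sum() / n
        ssw = 0.0
        for grp in ("g1", "g2"):
            idx = np.flatnonzero(labels.to_numpy() == grp)
            ssw += d2[np.ix_(idx, idx)][np.triu_indices(3, 1)].sum() / 3
        f_oracle = ((sst - ssw) / (k - 1)) / (ssw / (n - k))
        assert res.pseudo_F == pytest.approx(f_oracle, abs=1e-8)
        assert res.R2 == pytest.approx((sst - ssw) / sst, abs=1e-8)

    def test_separated_clusters_minimal_p(self):
        # large enough that permutation ties are vanishingly unlikely
        rng = np.random.default_rng(7)
        pts = np.vstack([rng.normal(0, 0.1, (12, 2)), rng.normal(8, 0.1, (12, 2))])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ids = [f"s{i}" for i in range(24)]
        dist = DistanceMatrix(ids, d)
        labels = pd.Series(["g1"] * 12 + ["g2"] * 12, index=ids)
        res = permanova(dist, labels, n_perm=999, seed=1)
        assert res.p == pytest.approx(1.0 / 1000.0)

    def test_p_lower_bound_honoured(self):
        dist, labels = self._toy()
        res = permanova(dist, labels, n_perm=19, seed=2)
        assert res.p >= 1.0 / 20.0

    def test_single_group_rejected(self):
        dist, labels = self._toy()
        with pytest.raises(ValueError, match="two groups"):
            permanova(dist, pd.Series(["g"] * 6, index=dist.ids), n_perm=9, seed=0)


class TestEnvfit:
    def _ordination(self):
        rng = np.random.default_rng(5)
        coords = rng.standard_normal((30, 2))
        coords -= coords.mean(axis=0)
        from gutdev.ecology import Ordination

        return Ordination([f"s{i}" for i in range(30)], coords, 0.05, 1)

    def test_axis_covariate_perfect_fit(self):
        o = self._ordination()
        cov = pd.DataFrame({"axis1": o.coordinates[:, 0]}, index=o.ids)
        res = envfit(o, cov, n_perm=999, seed=0)
        assert res.loc["axis1", "r2"] == pytest.approx(1.0)
        assert res.loc["axis1", "p"] == pytest.approx(1.0 / 1000.0)

    def test_separated_factor_significant(self):
        from gutdev.ecology import Ordination

        coords = np.vstack([np.random.default_rng(0).normal(0, 0.1, (15, 2)) - 2,
                            np.random.default_rng(1).normal(0, 0.1, (15, 2)) + 2])
        coords -= coords.mean(axis=0)
        o = Ordination([f"s{i}" for i in range(30)], coords, 0.0, 1)
        cov = pd.DataFrame({"grp": ["a"] * 15 + ["b"] * 15}, index=o.ids)
        res = envfit(o, cov, n_perm=999, seed=0)
        assert res.loc["grp", "p"] == pytest.approx(1.0 / 1000.0)
        assert res.loc["grp", "r2"] > 0.9

    def test_constant_covariate_warns(self):
        o = self._ordination()
        cov = pd.DataFrame({"const": np.ones(30)}, index=o.ids)
        with pytest.warns(UserWarning, match="constant"):
            res = envfit(o, cov, n_perm=9, seed=0)
        assert res.loc["const", "r2"] == 0.0 and res.loc["const", "p"] == 1.0


class TestHeterogeneity:
    def _meta(self, n, ages):
        return pd.DataFrame(
            {"group": ["g"] * n, "age_months": ages}, index=[f"s{i}" for i in range(n)]
        )

    def test_identical_samples_flat_zero(self):
        n = 12
        d = DistanceMatrix([f"s{i}" for i in range(n)], np.zeros((n, n)))
        meta = self._meta(n, np.linspace(6, 36, n))
        curve = heterogeneity_curve(d, meta, "g", n_boot=20, seed=0)
        np.testing.assert_allclose(curve["heterogeneity"], 0.0, atol=1e-12)

    def test_linear_response_recovered(self):
        # craft distances whose per-sample mean is linear in age
        n = 20
        ages = np.linspace(6, 36, n)
        base = (ages - ages.min()) / (ages.max() - ages.min())
        d = 0.05 + 0.5 * (base[:, None] + base[None, :]) / 2
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        dist = DistanceMatrix([f"s{i}" for i in range(n)], d)
        meta = self._meta(n, ages)
        curve = heterogeneity_curve(dist, meta, "g", n_boot=10, seed=0)
        response = d.sum(axis=1) / (n - 1)
        fit = np.polyfit(ages, response, 1)
        interior = curve.iloc[3:-3]
        expected = np.polyval(fit, interior["age_months"])
        np.testing.assert_allclose(interior["heterogeneity"], expected, atol=5e-3)

    def test_seed_fixed_identical_ci(self):
        rng = np.random.default_rng(2)
        n = 15
        d = rng.random((n, n)); d = (d + d.T) / 2; np.fill_diagonal(d, 0)
        dist = DistanceMatrix([f"s{i}" for i in range(n)], d)
        meta = self._meta(n, np.linspace(6, 36, n))
        c1 = heterogeneity_curve(dist, meta, "g", n_boot=30, seed=9)
        c2 = heterogeneity_curve(dist, meta, "g", n_boot=30, seed=9)
        pd.testing.assert_frame_equal(c1, c2)

    def test_missing_group_rejected(self):
        n = 12
        d = DistanceMatrix([f"s{i}" for i in range(n)], np.zeros((n, n)))
        meta = self._meta(n, np.linspace(6, 36, n))
        with pytest.raises(ValueError, match="absent|>= 10"):
            heterogeneity_curve(d, meta, "other", seed=0)


class TestPower:
    def _clusters(self, sep, n_per, seed=0):
        rng = np.random.default_rng(seed)
        pts = np.vstack([rng.normal(0, 1, (n_per, 3)), rng.normal(sep, 1, (n_per, 3))])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ids = [f"s{i}" for i in range(2 * n_per)]
        return DistanceMatrix(ids, d), pd.Series(["a"] * n_per + ["b"] * n_per, index=ids)

    def test_separated_groups_high_power(self):
        dist, labels = self._clusters(5.0, 30)
        est = permanova_power(dist, labels, n_per_group=20, n_boot=40, n_perm=99, seed=0)
        assert est.power >= 0.95
        assert est.effect_size_omega2 > 0.1

    def test_power_monotone_in_n(self):
        dist, labels = self._clusters(0.8, 40, seed=3)
        powers = [
            permanova_power(dist, labels, n_per_group=n, n_boot=40, n_perm=99, seed=1).power
            for n in (5, 15, 35)
        ]
        assert powers[0] <= powers[1] + 0.1 and powers[1] <= powers[2] + 0.1
        assert powers[2] > powers[0]

    def test_oversized_subsample_rejected(self):
        dist, labels = self._clusters(1.0, 10)
        with pytest.raises(ValueError, match="only"):
            permanova_power(dist, labels, n_per_group=11, n_boot=5, seed=0)
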