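"""Bray-Curtis, PERMDISP, and the nested PERMANOVA engine."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway

from rhizoherit.community import (
    DistanceMatrix,
    NestedPermanova,
    Permdisp,
    Term,
    bray_curtis,
    signed_sqrt,
    variance_components_sqrt,
)


def _euclid(Y, ids):
    return DistanceMatrix(ids, squareform(pdist(np.atleast_2d(Y))))


class TestBrayCurtis:
    def test_hand_example(self):
        df = pd.DataFrame([[1, 2, 3], [3, 2, 1]], index=["u", "v"])
        assert bray_curtis(df).values[0, 1] == pytest.approx(1 / 3)

    def test_identical_rows_zero(self):
        df = pd.DataFrame([[2, 5], [2, 5]], index=["u", "v"])
        assert bray_curtis(df).values[0, 1] == 0.0

    def test_disjoint_support_one(self):
        df = pd.DataFrame([[3, 0], [0, 7]], index=["u", "v"])
        assert bray_curtis(df).values[0, 1] == 1.0

    def test_negative_input_rejected(self):
        df = pd.DataFrame([[1.0, -0.1]])
        with pytest.raises(ValueError, match="adjust_nonzero"):
            bray_curtis(df)

    def test_double_zero_pair_flagged_as_zero(self):
        df = pd.DataFrame([[0, 0], [0, 0], [1, 1]], index=["u", "v", "w"])
        dm = bray_curtis(df)
        assert dm.values[0, 1] == 0.0
        assert ("u", "v") in dm.zero_pairs

    def test_range_and_agreement_with_skbio(self, small_study):
        """Cross-check against an independent implementation."""
        skbio_dist = pytest.importorskip("skbio.diversity")
        X = small_study.counts.iloc[:25].astype(float)
        mine = bray_curtis(X)
        theirs = skbio_dist.beta_diversity(
            "braycurtis", X.to_numpy(), ids=list(X.index)
        )
        np.testing.assert_allclose(mine.values, theirs.data, atol=1e-12)
        assert mine.values.min() >= 0 and mine.values.max() <= 1


class TestPermdisp:
    def test_univariate_equals_classical_f_on_deviations(self):
        """Euclidean 1-D input: F matches one-way F on |value - group mean|."""
        rng = np.random.default_rng(0)
        g = np.repeat(["a", "b"], 20)
        v = np.concatenate([rng.normal(0, 1, 20), rng.normal(0, 3, 20)])
        ids = [f"s{i}" for i in range(40)]
        res = Permdisp(_euclid(v[:, None], ids), g).fit(n_perm=99, seed=1)
        dev = np.abs(v - np.array([v[g == k].mean() for k in ["a", "b"]])[(g == "b").astype(int)])
        f_ref = f_oneway(dev[g == "a"], dev[g == "b"]).statistic
        assert res.statistic == pytest.approx(f_ref, rel=1e-8)

    def test_inflated_dispersion_detected(self):
        """5x dispersion in one group: high rejection power at n=40/group."""
        rng = np.random.default_rng(2)
        g = np.repeat(["a", "b"], 40)
        rejections = 0
        for rep in range(20):
            Y = np.vstack([
                rng.normal(0, 1, (40, 3)),
                rng.normal(0, 5, (40, 3)),
            ])
            ids = [f"s{i}" for i in range(80)]
            res = Permdisp(_euclid(Y, ids), g).fit(n_perm=99, seed=rep)
            rejections += res.p_value < 0.05
        assert rejections >= 18  # >= 0.9 power

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(3)
        g = np.repeat(["a", "b"], 15)
        ps = []
        for rep in range(40):
            Y = rng.normal(size=(30, 4))
            ids = [f"s{i}" for i in range(30)]
            ps.append(Permdisp(_euclid(Y, ids), g).fit(n_perm=99, seed=rep).p_value)
        ps = np.array(ps)
        assert 0.2 < ps.mean() < 0.8
        assert (ps < 0.05).mean() <= 0.2

    def test_singleton_group_excluded_with_warning(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(9, 2))
        ids = [f"s{i}" for i in range(9)]
        groups = ["a"] * 4 + ["b"] * 4 + ["lone"]
        with pytest.warns(UserWarning, match="singleton"):
            res = Permdisp(_euclid(Y, ids), groups).fit(n_perm=49, seed=0)
        assert set(res.group_sizes.index) == {"a", "b"}

    def test_semimetric_input_accepted(self, small_study):
        """Bray-Curtis (negative PCoA eigenvalues) still yields finite stats."""
        dist = bray_curtis(small_study.counts.iloc[:30].astype(float))
        groups = small_study.metadata.loc[dist.ids, "family"]
        res = Permdisp(dist, groups).fit(n_perm=49, seed=0)
        assert np.isfinite(res.statistic)
        assert np.isfinite(res.centroid_distances).all()


class TestNestedPermanova:
    def test_univariate_balanced_oneway_equals_classical_f(self):
        rng = np.random.default_rng(5)
        g = np.repeat(["a", "b", "c"], 10)
        v = rng.normal(size=30) + np.where(g == "c", 1.0, 0.0)
        ids = [f"s{i}" for i in range(30)]
        meta = pd.DataFrame({"grp": g}, index=ids)
        res = NestedPermanova(_euclid(v[:, None], ids), meta, [Term("grp")]).fit(
            n_perm=49, seed=0
        )
        f_ref = f_oneway(*(v[g == k] for k in "abc")).statistic
        assert res.table.loc["grp", "pseudo_F"] == pytest.approx(f_ref, abs=1e-8)

    def test_partition_sums_to_total(self, small_study):
        adj = small_study.counts.iloc[:60].astype(float)
        dist = bray_curtis(adj)
        meta = small_study.metadata.loc[adj.index].copy()
        meta["soil_pc1"] = meta[["pH", "moisture", "total_C", "total_N"]].mean(axis=1)
        terms = [
            Term("batch"), Term("soil_pc1", "continuous"),
            Term("family", "random"),
            Term("genotype", "random", nested_in="family"),
        ]
        res = NestedPermanova(dist, meta, terms).fit(n_perm=19, seed=0)
        G_trace = res.table["SS"].sum()
        n = len(adj)
        total = (dist.values**2).sum() / (2 * n)
        assert G_trace == pytest.approx(total, rel=1e-8)

    def test_exhaustive_enumeration_small_n(self):
        """n = 6, one factor: engine p matches full enumeration."""
        v = np.array([0.1, 0.4, 0.2, 1.9, 2.2, 1.4])
        g = np.array(["a", "a", "a", "b", "b", "b"])
        ids = [f"s{i}" for i in range(6)]
        meta = pd.DataFrame({"grp": g}, index=ids)
        dist = _euclid(v[:, None], ids)
        model = NestedPermanova(dist, meta, [Term("grp")])
        n_perm = 999
        res = model.fit(n_perm=n_perm, seed=1)

        # brute-force oracle over all 720 orderings of the samples
        D2 = dist.values**2

        def pseudo_f(order):
            vv = v[list(order)]
            msb = sum(3 * (vv[i:i + 3].mean() - vv.mean()) ** 2 for i in (0, 3)) / 1
            ssw = sum(((vv[i:i + 3] - vv[i:i + 3].mean()) ** 2).sum() for i in (0, 3))
            return msb / (ssw / 4)

        f_obs = pseudo_f(range(6))
        stats = [pseudo_f(p) for p in itertools.permutations(range(6))]
        p_exact = np.mean([s >= f_obs - 1e-12 for s in stats])
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert res.table.loc["grp", "p_perm"] == pytest.approx(
            p_exact, abs=3 * se + 1 / (n_perm + 1)
        )

    def test_family_type_one_error_nominal(self):
        """Null family effect (genotype variance present): ~5% rejections."""
        rng = np.random.default_rng(42)
        F, Gp, R = 15, 3, 2
        n = F * Gp * R
        fam = np.repeat([f"f{i}" for i in range(F)], Gp * R)
        gen = np.repeat([f"g{i}" for i in range(F * Gp)], R)
        ids = [f"s{i}" for i in range(n)]
        meta = pd.DataFrame({"family": fam, "genotype": gen}, index=ids)
        terms = [Term("family", "random"), Term("genotype", "random", nested_in="family")]
        rejections = 0
        n_reps = 60
        for rep in range(n_reps):
            u_g = rng.normal(0, 0.7, (F * Gp, 4))
            Y = u_g[np.repeat(np.arange(F * Gp), R)] + rng.normal(0, 1, (n, 4))
            res = NestedPermanova(_euclid(Y, ids), meta, terms).fit(n_perm=99, seed=rep)
            rejections += res.table.loc["family", "p_perm"] < 0.05
        # 95% binomial interval around 0.05 at 60 reps: [0, 7]
        assert rejections <= 7

    def test_aliased_term_raises(self):
        ids = [f"s{i}" for i in range(8)]
        meta = pd.DataFrame(
            {"a": list("xxyyxxyy"), "b": list("xxyyxxyy")}, index=ids
        )
        rng = np.random.default_rng(0)
        dist = _euclid(rng.normal(size=(8, 2)), ids)
        with pytest.raises(ValueError, match="aliased"):
            NestedPermanova(dist, meta, [Term("a"), Term("b")])

    def test_signed_sqrt_convention(self):
        assert signed_sqrt(4.0) == 2.0
        assert signed_sqrt(-4.0) == -2.0
        assert signed_sqrt(0.0) == 0.0
        tab = pd.DataFrame({"component_of_variation": [9.0, -2.25]})
        np.testing.assert_allclose(variance_components_sqrt(tab), [3.0, -1.5])

    def test_components_match_classical_nested_anova(self):
        """Euclidean univariate nested design: CVs equal the classical
        balanced nested-ANOVA moment estimators exactly."""
        rng = np.random.default_rng(6)
        F, Gp, R = 30, 3, 4
        fam_eff = rng.normal(0, np.sqrt(2.0), F)
        gen_eff = rng.normal(0, np.sqrt(1.0), F * Gp)
        fam_idx = np.repeat(np.arange(F), Gp * R)
        gen_idx = np.repeat(np.arange(F * Gp), R)
        v = fam_eff[fam_idx] + gen_eff[gen_idx] + rng.normal(0, 1.0, F * Gp * R)
        ids = [f"s{i}" for i in range(len(v))]
        meta = pd.DataFrame(
            {"family": [f"f{i}" for i in fam_idx], "genotype": [f"g{i}" for i in gen_idx]},
            index=ids,
        )
        terms = [Term("family", "random"), Term("genotype", "random", nested_in="family")]
        res = NestedPermanova(_euclid(v[:, None], ids), meta, terms).fit(n_perm=19, seed=0)

        # classical balanced nested ANOVA oracle
        grand = v.mean()
        fmean = np.array([v[fam_idx == f].mean() for f in range(F)])
        gmean = np.array([v[gen_idx == g].mean() for g in range(F * Gp)])
        msf = Gp * R * ((fmean - grand) ** 2).sum() / (F - 1)
        msg = R * ((gmean - fmean[np.repeat(np.arange(F), Gp)]) ** 2).sum() / (F * (Gp - 1))
        mse = ((v - gmean[gen_idx]) ** 2).sum() / (F * Gp * (R - 1))
        sg = (msg - mse) / R
        sf = (msf - mse - R * sg) / (Gp * R)

        cv = res.table["component_of_variation"]
        assert cv["family"] == pytest.approx(sf, rel=1e-8)
        assert cv["genotype"] == pytest.approx(sg, rel=1e-8)
        assert cv["residual"] == pytest.approx(mse, rel=1e-8)

    def test_ancestry_model_preset(self, small_study):
        """Ancestry variant: ancestry fixed, family nested in ancestry."""
        from rhizoherit.community import ANCESTRY_TERMS

        adj = small_study.counts.iloc[:60].astype(float)
        dist = bray_curtis(adj)
        meta = small_study.metadata.loc[adj.index].copy()
        fams = sorted(meta["family"].unique())
        origin = {f: ("mainland" if i % 2 else "island") for i, f in enumerate(fams)}
        meta["ancestry"] = meta["family"].map(origin)
        meta["soil_pc1"] = meta[["pH", "moisture", "total_C", "total_N"]].mean(axis=1)
        res = NestedPermanova(dist, meta, ANCESTRY_TERMS).fit(n_perm=19, seed=0)
        assert list(res.table.index) == [
            "batch", "soil_pc1", "ancestry", "family", "genotype", "residual"
        ]
        assert np.isfinite(res.table["SS"]).all()

    def test_permutation_pvalues_seed_stable(self, small_study):
        adj = small_study.counts.iloc[:45].astype(float)
        dist = bray_curtis(adj)
        meta = small_study.metadata.loc[adj.index]
        terms = [Term("family", "random"), Term("genotype", "random", nested_in="family")]
        p1 = NestedPermanova(dist, meta, terms).fit(n_perm=49, seed=3).table["p_perm"]
        p2 = NestedPermanova(dist, meta, terms).fit(n_perm=49, seed=3).table["p_perm"]
        pd.testing.assert_series_equal(p1, p2)
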