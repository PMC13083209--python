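"""REML variance components, heritability, and the per-ASV scan."""

import numpy as np
import pandas as pd
import pytest

from rhizoherit.pedigree import RelationshipMatrix
from rhizoherit.quantgen import (
    GeneticMixedModel,
    HeritabilityEstimate,
    MixedModelSpec,
    VarianceComponents,
    Z_THRESHOLD,
    build_design,
    heritability,
    heritability_scan,
    reml_fit,
)
from rhizoherit.simulate import simulate_mixed_model_response


def _clonal_design(G=40, k=5, seed=0):
    rng = np.random.default_rng(seed)
    geno = np.repeat(np.arange(G), k)
    Z = np.zeros((G * k, G))
    Z[np.arange(G * k), geno] = 1.0
    return rng, geno, Z


class TestRemlEngine:
    def test_matches_balanced_anova_estimator(self):
        """A = I clonal design: REML equals (MSB - MSW)/k when interior."""
        G, k = 40, 5
        rng, geno, Z = _clonal_design(G, k, seed=3)
        u = rng.normal(0, np.sqrt(0.5), G)
        y = u[geno] + rng.normal(0, 1.0, G * k)
        vc = GeneticMixedModel(
            y, np.ones((G * k, 1)), [("genotype", Z @ Z.T)], n_levels=[G]
        ).fit()
        ybar = y.reshape(G, k).mean(1)
        msb = k * ((ybar - ybar.mean()) ** 2).sum() / (G - 1)
        msw = ((y.reshape(G, k) - ybar[:, None]) ** 2).sum() / (G * (k - 1))
        assert (msb - msw) / k > 0  # interior case
        assert vc["genotype"] == pytest.approx((msb - msw) / k, rel=1e-6)
        assert vc["residual"] == pytest.approx(msw, rel=1e-6)
        assert vc.converged

    def test_null_response_components_near_zero(self, study_design):
        """Pure-noise responses: genetic components pile at the boundary."""
        meta = study_design.metadata
        A = study_design.A.subset(sorted(set(meta["genotype"])))
        spec0 = MixedModelSpec(
            np.zeros(len(meta)), np.ones((len(meta), 1)),
            list(meta["genotype"]), list(meta["family"]),
            genotype_levels=A.labels,
        )
        base = GeneticMixedModel.from_spec(spec0, A)
        rng = np.random.default_rng(0)
        genetic, resid = [], []
        for _ in range(12):
            y = rng.normal(0, 1.0, len(meta))
            vc = GeneticMixedModel(
                y, spec0.X, base.structures, n_levels=base._q[:-1]
            ).fit()
            genetic.append(vc["additive"] + vc["family"] + vc["clone"])
            resid.append(vc["residual"])
        assert np.mean(genetic) < 0.05
        assert np.mean(resid) == pytest.approx(1.0, abs=0.08)

    def test_constant_response_degenerate_flag(self, study_design):
        meta = study_design.metadata
        A = study_design.A.subset(sorted(set(meta["genotype"])))
        spec = MixedModelSpec(
            np.full(len(meta), 2.0), np.ones((len(meta), 1)),
            list(meta["genotype"]), list(meta["family"]),
            genotype_levels=A.labels,
        )
        vc = reml_fit(spec, A)
        assert vc.degenerate
        assert np.all(vc.estimates == 0.0)

    def test_scale_and_shift_invariance(self, study_design):
        """Components scale with c^2; heritabilities are invariant."""
        meta = study_design.metadata
        A = study_design.A.subset(sorted(set(meta["genotype"])))
        y = simulate_mixed_model_response(
            A, meta["genotype"], meta["family"],
            dict(additive=0.3, family=0.1, clone=0.2, residual=0.4), seed=1,
        )
        X = np.ones((len(y), 1))
        spec0 = MixedModelSpec(y, X, list(meta["genotype"]), list(meta["family"]),
                               genotype_levels=A.labels)
        base = GeneticMixedModel.from_spec(spec0, A)
        vc1 = base.fit()
        c = 3.7
        vc2 = GeneticMixedModel(c * y + 11.0, X, base.structures,
                                n_levels=base._q[:-1]).fit()
        np.testing.assert_allclose(vc2.estimates, c**2 * vc1.estimates, rtol=1e-3)
        h1, h2 = heritability(vc1), heritability(vc2)
        assert h1.H2 == pytest.approx(h2.H2, abs=1e-4)
        assert h1.h2 == pytest.approx(h2.h2, abs=1e-4)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            GeneticMixedModel(np.zeros(5), np.ones((4, 1)), [])

    def test_genotype_multiple_families_rejected(self):
        with pytest.raises(ValueError, match="multiple families"):
            MixedModelSpec(
                np.zeros(2), np.ones((2, 1)), ["g1", "g1"], ["f1", "f2"]
            )


class TestHeritability:
    def test_equal_components_direct_substitution(self):
        k = 4
        vc = VarianceComponents(
            ["additive", "family", "clone", "residual"],
            np.ones(k), np.full(k, 0.1), 0.01 * np.eye(k),
            loglik=-1.0, converged=True, n_iter=5,
            at_boundary=np.zeros(k, bool),
        )
        est = heritability(vc)
        assert est.H2 == pytest.approx(0.75)
        assert est.h2 == pytest.approx(0.25)
        assert est.h2 <= est.H2

    def test_null_genetics_zero_heritability(self):
        k = 4
        vc = VarianceComponents(
            ["additive", "family", "clone", "residual"],
            np.array([0.0, 0.0, 0.0, 1.0]), np.zeros(k), np.zeros((k, k)),
            loglik=-1.0, converged=True, n_iter=3,
            at_boundary=np.array([True, True, True, False]),
        )
        est = heritability(vc)
        assert est.H2 == 0.0 and est.h2 == 0.0
        assert not est.significant_H2

    def test_zero_total_flagged_undefined(self):
        k = 4
        vc = VarianceComponents(
            ["additive", "family", "clone", "residual"],
            np.zeros(k), np.zeros(k), np.zeros((k, k)),
            loglik=np.nan, converged=True, n_iter=0,
            at_boundary=np.ones(k, bool), degenerate=True,
        )
        assert heritability(vc).undefined

    def test_delta_se_matches_parametric_bootstrap(self, study_design):
        """Delta-method SE of H2 vs bootstrap SD of refitted estimates.

        Uses the pedigree-structured design: with A = I the additive and
        clone structures would be aliased.
        """
        meta = study_design.metadata
        A = study_design.A.subset(sorted(set(meta["genotype"])))
        spec = MixedModelSpec(
            np.zeros(len(meta)), np.ones((len(meta), 1)),
            list(meta["genotype"]), list(meta["family"]),
            genotype_levels=A.labels,
        )
        base = GeneticMixedModel.from_spec(spec, A)
        truth = dict(additive=0.5, family=0.2, clone=0.3, residual=1.0)

        def draw(seed):
            return simulate_mixed_model_response(
                A, meta["genotype"], meta["family"], truth, seed=seed
            )

        vc0 = GeneticMixedModel(draw(0), spec.X, base.structures,
                                n_levels=base._q[:-1]).fit()
        est0 = heritability(vc0)
        boot = [
            heritability(
                GeneticMixedModel(draw(1000 + b), spec.X, base.structures,
                                  n_levels=base._q[:-1]).fit()
            ).H2
            for b in range(200)
        ]
        boot_sd = np.std(boot, ddof=1)
        assert est0.H2_se == pytest.approx(boot_sd, rel=0.25)

    def test_wrong_component_order_rejected(self):
        vc = VarianceComponents(
            ["genotype", "residual"], np.ones(2), np.ones(2), np.eye(2),
            loglik=0.0, converged=True, n_iter=1, at_boundary=np.zeros(2, bool),
        )
        with pytest.raises(ValueError):
            heritability(vc)


class TestHeritabilityScan:
    def test_empty_matrix_empty_results(self, study_design):
        empty = pd.DataFrame(index=study_design.metadata.index)
        table, summary = heritability_scan(
            empty, study_design.metadata, study_design.A
        )
        assert table.empty and summary == {}

    def test_null_scan_significance_near_alpha(self, study_design):
        """Null data: z > 1.65 calls occur at roughly the nominal 5% rate."""
        meta = study_design.metadata.copy()
        meta["soil_pc1"] = 0.0  # constant soil axis would be aliased; drop it
        meta = meta.drop(columns=["soil_pc1"])
        rng = np.random.default_rng(5)
        n_asvs = 40
        resid = pd.DataFrame(
            rng.normal(size=(len(meta), n_asvs)),
            index=meta.index,
            columns=[f"ASV{j}" for j in range(n_asvs)],
        )
        table, summary = heritability_scan(
            resid, meta, study_design.A, soil_col="absent"
        )
        assert summary["n_asvs"] == n_asvs
        # one-sided 5% test; binomial 95% bound at 40 trials allows <= 6
        assert summary["n_significant_H2"] <= 6

    def test_heritable_asvs_rank_top(self, study_design):
        """Planted heritable ASVs sort to the top of the H2 table."""
        meta = study_design.metadata
        A = study_design.A.subset(sorted(set(meta["genotype"])))
        rng = np.random.default_rng(9)
        cols = {}
        for j in range(6):  # strong genetic signal
            cols[f"HER{j}"] = simulate_mixed_model_response(
                A, meta["genotype"], meta["family"],
                dict(additive=0.4, family=0.1, clone=0.2, residual=0.3),
                seed=200 + j,
            )
        for j in range(12):  # nulls
            cols[f"NUL{j}"] = rng.normal(size=len(meta))
        resid = pd.DataFrame(cols, index=meta.index)
        table, summary = heritability_scan(
            resid, meta, study_design.A,
            core_asvs=[f"NUL{j}" for j in range(12)],
            soil_col="absent",
        )
        top8 = set(table.index[:8])
        assert sum(a.startswith("HER") for a in top8) >= 5
        assert summary["core"]["n"] == 12
        assert summary["noncore"]["n"] == 6
        assert (table["h2"] <= table["H2"] + 1e-12).all()

    def test_build_design_reference_coding(self, study_design):
        meta = study_design.metadata.copy()
        meta["soil_pc1"] = np.linspace(-1, 1, len(meta))
        X, names = build_design(meta)
        assert names[0] == "intercept"
        n_batches = meta["batch"].nunique()
        assert X.shape[1] == 1 + (n_batches - 1) + 1
        assert np.linalg.matrix_rank(X) == X.shape[1]


def test_z_threshold_is_one_sided_alpha_05():
    """The 1.65 significance threshold corresponds to one-sided alpha = 0.05."""
    from scipy.stats import norm

    assert abs(Z_THRESHOLD - norm.isf(0.05)) <= 0.0052
    assert round(float(norm.sf(Z_THRESHOLD)), 2) == 0.05
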