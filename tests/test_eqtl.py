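"""Interaction Bayes factors, posterior model probabilities and the cis scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, special

from gcresponse.eqtl import (
    MODELS,
    ModelPriors,
    cis_scan,
    classify,
    interaction_bayes_factors,
    log_marginal_bf,
    marginal_bf,
    posterior_probs,
)
from gcresponse.simulate import GenotypeMatrix, PairedExpression


def _toy(seed=0, n=5, beta_t=1.0, beta_c=0.0):
    rng = np.random.default_rng(seed)
    g = rng.integers(0, 3, size=n).astype(float)
    y_t = 1.0 + beta_t * g + rng.normal(0, 0.5, n)
    y_c = 1.0 + beta_c * g + rng.normal(0, 0.5, n)
    return y_t, y_c, g


def _design(g, model):
    zero = np.zeros_like(g)
    cols = {
        "no_interaction": [np.concatenate([g, g])],
        "gc_only": [np.concatenate([g, zero])],
        "control_only": [np.concatenate([zero, g])],
        "general": [np.concatenate([g, zero]), np.concatenate([zero, g])],
    }[model]
    return np.column_stack(cols)


def _bf_by_quadrature(y_t, y_c, g, model, sigma_a):
    """Independent oracle: integrate the effect out numerically.

    The residual variance is integrated analytically (inverse-gamma
    integral), the genotype effect(s) numerically via adaptive
    quadrature; no determinant identity is used.
    """
    n = len(y_t)
    gc = g - g.mean()
    y = np.concatenate([y_t - y_t.mean(), y_c - y_c.mean()])
    Z = _design(gc, model)
    half = Z.shape[0] // 2
    Z = Z.copy()
    Z[:half] -= Z[:half].mean(axis=0)
    Z[half:] -= Z[half:].mean(axis=0)
    q = Z.shape[1]
    nu = 2 * n - 2
    rss0 = float(y @ y)
    s2a = sigma_a**2

    log_norm = (
        -0.5 * q * np.log(2 * np.pi * s2a)
        + special.gammaln((nu + q) / 2)
        - special.gammaln(nu / 2)
        + 0.5 * nu * np.log(rss0 / 2)
    )

    if q == 1:
        z = Z[:, 0]

        def f(gamma):
            S = float((y - gamma * z) @ (y - gamma * z)) + gamma**2 / s2a
            return (S / 2) ** (-(nu + q) / 2)

        val, _ = integrate.quad(f, -np.inf, np.inf, limit=200)
    else:

        def f(g2, g1):
            r = y - Z @ np.array([g1, g2])
            S = float(r @ r) + (g1**2 + g2**2) / s2a
            return (S / 2) ** (-(nu + q) / 2)

        val, _ = integrate.dblquad(
            f, -np.inf, np.inf, lambda _: -np.inf, lambda _: np.inf
        )
    return float(np.exp(log_norm) * val)


class TestBayesFactors:
    @pytest.mark.parametrize("model", MODELS)
    @pytest.mark.parametrize("sigma_a", [0.2, 0.8])
    def test_closed_form_matches_quadrature(self, model, sigma_a):
        y_t, y_c, g = _toy(seed=4)
        bf = marginal_bf(y_t, y_c, g, model, sigma_grid=(sigma_a,))
        oracle = _bf_by_quadrature(y_t, y_c, g, model, sigma_a)
        assert np.isclose(bf, oracle, rtol=2e-3)

    def test_grid_average_matches_quadrature(self):
        y_t, y_c, g = _toy(seed=8)
        grid = (0.1, 0.2, 0.4, 0.8, 1.6)
        bf = marginal_bf(y_t, y_c, g, "gc_only", sigma_grid=grid)
        oracle = np.mean([_bf_by_quadrature(y_t, y_c, g, "gc_only", s) for s in grid])
        assert np.isclose(bf, oracle, rtol=2e-3)

    def test_monomorphic_genotype_gives_unit_bf(self):
        y_t, y_c, _ = _toy()
        bfs, mono = interaction_bayes_factors(y_t, y_c, np.ones(5))
        assert mono
        assert all(bf == 1.0 for bf in bfs.values())

    def test_location_scale_invariance(self):
        y_t, y_c, g = _toy(seed=2)
        for model in MODELS:
            b1 = log_marginal_bf(y_t, y_c, g, model)
            b2 = log_marginal_bf(3.7 * y_t - 5, 3.7 * y_c - 5, g, model)
            assert np.isclose(b1, b2, rtol=1e-9, atol=1e-9)

    def test_condition_swap_exchanges_gc_and_control(self):
        y_t, y_c, g = _toy(seed=6, beta_t=2.0, beta_c=-0.5)
        fwd, _ = interaction_bayes_factors(y_t, y_c, g)
        rev, _ = interaction_bayes_factors(y_c, y_t, g)
        assert np.isclose(fwd["gc_only"], rev["control_only"], rtol=1e-12)
        assert np.isclose(fwd["control_only"], rev["gc_only"], rtol=1e-12)
        assert np.isclose(fwd["no_interaction"], rev["no_interaction"], rtol=1e-12)
        assert np.isclose(fwd["general"], rev["general"], rtol=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            log_marginal_bf([1, 2, 3], [1, 2, 3], [0, 1, 2], "gc_only")

    def test_missing_genotypes_mean_imputed(self):
        y_t, y_c, g = _toy(seed=3, n=8)
        g_missing = g.copy()
        g_missing[0] = np.nan
        g_imputed = g.copy()
        g_imputed[0] = g[1:].mean()
        b1 = log_marginal_bf(y_t, y_c, g_missing, "general")
        b2 = log_marginal_bf(y_t, y_c, g_imputed, "general")
        assert np.isclose(b1, b2)


class TestPosteriors:
    def test_unit_bfs_return_prior(self):
        post = posterior_probs({m: 1.0 for m in MODELS})
        assert np.isclose(post["null"], 0.999)
        for m in MODELS:
            assert np.isclose(post[m], 0.001 / 4)

    def test_large_gc_bf_dominates(self):
        bfs = {m: 1.0 for m in MODELS}
        bfs["gc_only"] = 1e6
        post = posterior_probs(bfs)
        expected = (0.00025 * 1e6) / (0.00025 * 1e6 + 0.999 + 3 * 0.00025)
        assert np.isclose(post["gc_only"], expected)
        assert np.isclose(post["gc_only"], 0.99601, atol=5e-5)

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.floats(1e-6, 1e6), min_size=4, max_size=4))
    def test_posteriors_normalize(self, raw):
        post = posterior_probs(dict(zip(MODELS, raw)))
        assert np.isclose(sum(post.values()), 1.0, atol=1e-12)

    def test_nonpositive_bf_rejected(self):
        with pytest.raises(ValueError):
            posterior_probs({**{m: 1.0 for m in MODELS}, "gc_only": 0.0})

    def test_invalid_priors_rejected(self):
        with pytest.raises(ValueError):
            ModelPriors(null=0.9, alternatives={m: 0.1 for m in MODELS})


class TestClassify:
    def test_null_dominated(self):
        post = {"null": 0.999, **{m: 0.00025 for m in MODELS}}
        assert classify(post) == "null"

    def test_confident_alternative(self):
        post = {"null": 0.003, "gc_only": 0.996, "control_only": 0.0005,
                "no_interaction": 0.0003, "general": 0.0002}
        assert classify(post) == "gc_only"

    def test_threshold_one_forces_null(self):
        post = {"null": 0.01, "gc_only": 0.99, "control_only": 0.0,
                "no_interaction": 0.0, "general": 0.0}
        assert classify(post, threshold=1.0) == "null"


class TestCisScan:
    def _tiny(self, offsets):
        rng = np.random.default_rng(1)
        samples = pd.Index([f"i{j}" for j in range(10)], name="sample")
        snps = pd.Index([f"s{j}" for j in range(len(offsets))], name="snp")
        dos = pd.DataFrame(
            rng.integers(0, 3, size=(10, len(offsets))).astype(float),
            index=samples, columns=snps,
        )
        gm = GenotypeMatrix(
            dosages=dos,
            positions=pd.Series([500_000 + o for o in offsets], index=snps),
        )
        genes = pd.DataFrame({"gene": ["gA"], "chrom": "chrS", "tss": [500_000]})
        expr = PairedExpression(
            treated=pd.DataFrame(rng.normal(size=(1, 10)), index=["gA"], columns=samples),
            control=pd.DataFrame(rng.normal(size=(1, 10)), index=["gA"], columns=samples),
        )
        return expr, gm, genes

    def test_window_boundary_inclusive(self):
        expr, gm, genes = self._tiny([100_000, 100_001])
        scan = cis_scan(expr, gm, genes)
        assert list(scan["snp"]) == ["s0"]

    def test_gene_without_cis_snp_omitted(self):
        expr, gm, genes = self._tiny([200_000])
        assert cis_scan(expr, gm, genes).empty


class TestPlantedRecovery:
    def test_interaction_classes_recovered(self, recovery_config, recovery_cohort):
        genotypes, expression, truth = recovery_cohort
        calls = {}
        for gene, row in truth.iterrows():
            g = genotypes.dosages[row["snp"]].to_numpy()
            bfs, _ = interaction_bayes_factors(
                expression.treated.loc[gene].to_numpy(),
                expression.control.loc[gene].to_numpy(),
                g,
            )
            calls[gene] = classify(posterior_probs(bfs))
        calls = pd.Series(calls)
        for cls in ("gc_only", "control_only"):
            planted = truth.index[truth["class"] == cls]
            recovered = (calls.loc[planted] == cls).mean()
            assert recovered >= 0.8, f"{cls}: {recovered:.2f}"
        null_genes = truth.index[truth["class"] == "null"]
        fp = (calls.loc[null_genes] != "null").mean()
        assert fp < 0.05, f"null false calls: {fp:.3f}"
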