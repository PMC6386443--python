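"""Marginal statistics and texture features, both normalization variants."""

import numpy as np
import pytest

from glcminv import (
    CooccurrenceCounts,
    GLCMDistribution,
    compute_all,
    compute_feature,
    marginal_stats,
    maximal_correlation_coefficient,
    normalize_density,
    normalize_pmf,
    q_matrix,
    standard_offsets,
)
from glcminv.features import DEFAULT_FEATURE_NAMES, FEATURE_NAMES

from _oracles import oracle_features
from conftest import random_counts


class TestMarginalStats:
    def test_uniform_original_moments(self, uniform_glcms):
        p, _ = uniform_glcms
        ms = marginal_stats(p)
        assert ms.mu_x == pytest.approx(2.5)
        assert ms.var_x == pytest.approx(1.25)

    def test_uniform_invariant_mean(self, uniform_glcms):
        _, pt = uniform_glcms
        ms = marginal_stats(pt)
        assert ms.mu_x == pytest.approx(0.625)  # mu_x / N

    def test_degenerate_single_cell(self):
        m = np.zeros((4, 4))
        m[1, 2] = 1.0
        glcm = GLCMDistribution(m, 4, "original")
        ms = marginal_stats(glcm)
        assert np.array_equal(ms.p_x, [0, 1, 0, 0])
        assert np.array_equal(ms.p_y, [0, 0, 1, 0])
        assert ms.hxy == pytest.approx(0.0)

    def test_original_marginals_normalize(self, rng):
        ms = marginal_stats(normalize_pmf(random_counts(rng, 8)))
        for vec in (ms.p_x, ms.p_y, ms.p_xplusy, ms.p_xminusy):
            assert vec.sum() == pytest.approx(1.0, abs=1e-10)

    def test_invariant_marginal_riemann_sums(self, rng):
        """Density marginals integrate per the printed differentials.

        p_x, p_y and p_{x-y} integrate to 1 against delta = 1/N; the
        printed sum-marginal formula makes p_{x+y} integrate to
        N/(2N-1) against delta_{x+y}.
        """
        for n in (4, 16):
            glcm = normalize_density(random_counts(rng, n))
            ms = marginal_stats(glcm)
            d = glcm.delta
            assert ms.p_x.sum() * d == pytest.approx(1.0, abs=1e-10)
            assert ms.p_y.sum() * d == pytest.approx(1.0, abs=1e-10)
            assert ms.p_xminusy.sum() * d == pytest.approx(1.0, abs=1e-10)
            assert ms.p_xplusy.sum() * glcm.delta_xplusy == pytest.approx(
                n / (2 * n - 1), abs=1e-10
            )

    def test_invariant_relations_to_original(self, rng):
        for n in (4, 8, 16):
            counts = random_counts(rng, n)
            mo = marginal_stats(normalize_pmf(counts))
            mi = marginal_stats(normalize_density(counts))
            assert np.allclose(mi.p_x, n * mo.p_x, atol=1e-10)
            assert mi.mu_x == pytest.approx(mo.mu_x / n, abs=1e-10)
            assert mi.var_x == pytest.approx(mo.var_x / n**2, abs=1e-10)
            assert mi.hx == pytest.approx(mo.hx - np.log(n), abs=1e-10)
            assert mi.hxy == pytest.approx(mo.hxy - 2 * np.log(n), abs=1e-10)
            assert mi.hxy1 == pytest.approx(mo.hxy1 - 2 * np.log(n), abs=1e-10)
            assert mi.hxy2 == pytest.approx(mo.hxy2 - 2 * np.log(n), abs=1e-10)


class TestFeatureValues:
    def test_uniform_energy_and_entropy(self, uniform_glcms):
        p, pt = uniform_glcms
        assert compute_feature(p, "energy") == pytest.approx(1 / 16)
        assert compute_feature(pt, "energy") == pytest.approx(1.0)
        # differential entropy of the uniform density on the unit square
        assert compute_feature(pt, "entropy") == pytest.approx(0.0, abs=1e-12)

    def test_unknown_feature_error_lists_names(self, uniform_glcms):
        with pytest.raises(KeyError, match="autocorrelation"):
            compute_feature(uniform_glcms[0], "no_such_feature")

    def test_degenerate_correlation_error(self):
        m = np.zeros((4, 4))
        m[1, 1] = 1.0
        glcm = GLCMDistribution(m, 4, "original")
        with pytest.raises(ValueError, match="variance"):
            compute_feature(glcm, "correlation")

    def test_imc1_uniform_marginals_error(self, uniform_glcms):
        # invariant uniform marginals have zero differential entropy
        _, pt = uniform_glcms
        with pytest.raises(ValueError, match="max"):
            compute_feature(pt, "information_measure_of_correlation_1")

    def test_oracle_equivalence_small(self, rng):
        """Vectorized features match the naive loop transcription."""
        for n in (4, 8):
            counts = random_counts(rng, n)
            for glcm in (normalize_pmf(counts), normalize_density(counts)):
                expected, _ = oracle_features(glcm.matrix, n, glcm.variant)
                got = compute_all(glcm, include_mcc=True).values
                for name in FEATURE_NAMES:
                    assert got[name] == pytest.approx(
                        expected[name], rel=1e-10, abs=1e-12
                    ), name

    def test_closed_form_variant_relations(self, rng):
        for n in (4, 8, 32):
            counts = random_counts(rng, n)
            fo = compute_all(normalize_pmf(counts)).values
            fi = compute_all(normalize_density(counts)).values
            p = normalize_pmf(counts).matrix
            ii, jj = np.meshgrid(np.arange(1, n + 1), np.arange(1, n + 1), indexing="ij")
            rel = pytest.approx
            assert fi["contrast"] == rel(fo["contrast"] / n**2, rel=1e-10)
            assert fi["dissimilarity"] == rel(fo["dissimilarity"] / n, rel=1e-10)
            assert fi["autocorrelation"] == rel(fo["autocorrelation"] / n**2, rel=1e-10)
            assert fi["sum_of_squares"] == rel(fo["sum_of_squares"] / n**2, rel=1e-10)
            assert fi["energy"] == rel(fo["energy"] * n**2, rel=1e-10)
            assert fi["entropy"] == rel(fo["entropy"] - 2 * np.log(n), rel=1e-10)
            assert fi["maximum_probability"] == rel(fo["maximum_probability"] * n**2, rel=1e-10)
            assert fi["correlation"] == rel(fo["correlation"], rel=1e-10)
            # index-normalized (Clausi) forms
            clausi_h = float(np.sum(p / (1.0 + ((ii - jj) / n) ** 2)))
            clausi_id = float(np.sum(p / (1.0 + np.abs(ii - jj) / n)))
            assert fi["homogeneity"] == rel(clausi_h, rel=1e-10)
            assert fi["inverse_difference"] == rel(clausi_id, rel=1e-10)

    def test_invariant_features_scale_free(self, rng):
        """Multiplying the raw counts by a constant changes nothing.

        Power-of-two multipliers leave every float division bit-identical;
        other multipliers agree to rounding error.
        """
        counts = random_counts(rng, 8)
        f1 = compute_all(normalize_density(counts), include_mcc=True).values
        for factor, tol in ((4, 0.0), (17, 1e-12)):
            scaled = CooccurrenceCounts(
                counts.matrix * factor, 8, counts.offsets, counts.symmetric
            )
            f2 = compute_all(normalize_density(scaled), include_mcc=True).values
            for name in FEATURE_NAMES:
                if tol == 0.0:
                    assert f1[name] == f2[name], name
                else:
                    assert f1[name] == pytest.approx(f2[name], rel=tol, abs=1e-12), name


class TestComputeAll:
    def test_default_count_order_and_finiteness(self, rng):
        fv = compute_all(normalize_pmf(random_counts(rng, 8)))
        assert tuple(fv.values) == DEFAULT_FEATURE_NAMES
        assert all(np.isfinite(v) for v in fv.values.values())

    def test_include_mcc_flag(self, rng):
        fv = compute_all(normalize_density(random_counts(rng, 6)), include_mcc=True)
        assert len(fv.values) == 20
        assert tuple(fv.values) == FEATURE_NAMES

    def test_symmetric_correlation_identical_across_variants(self, rng):
        x = rng.integers(0, 20, size=(8, 8))
        x = x + x.T + np.eye(8, dtype=int)
        counts = CooccurrenceCounts(x, 8, standard_offsets(2, True), symmetric=True)
        fo = compute_all(normalize_pmf(counts)).values
        fi = compute_all(normalize_density(counts)).values
        assert fi["correlation"] == pytest.approx(fo["correlation"], abs=1e-10)

    def test_error_carries_feature_name(self):
        m = np.zeros((4, 4))
        m[2, 2] = 1.0
        with pytest.raises(ValueError, match="correlation"):
            compute_all(GLCMDistribution(m, 4, "original"))


class TestQMatrix:
    def test_uniform_entries_are_one_over_n(self):
        for n in (2, 4):
            m = np.full((n, n), 1.0 / n**2)
            q = q_matrix(GLCMDistribution(m, n, "original"))
            assert np.allclose(q, 1.0 / n)

    def test_invariant_equals_original(self, rng):
        counts = random_counts(rng, 6)
        q_o = q_matrix(normalize_pmf(counts))
        q_i = q_matrix(normalize_density(counts))
        assert np.allclose(q_o, q_i, atol=1e-12)

    def test_single_cell_rank_one(self):
        m = np.zeros((4, 4))
        m[1, 2] = 1.0
        q = q_matrix(GLCMDistribution(m, 4, "original"))
        assert np.count_nonzero(q) == 1
        assert q[1, 1] == pytest.approx(1.0)

    def test_matches_loop_oracle(self, rng):
        for variant, norm in (("original", normalize_pmf), ("invariant", normalize_density)):
            glcm = norm(random_counts(rng, 7))
            _, q_ref = oracle_features(glcm.matrix, 7, variant)
            assert np.allclose(q_matrix(glcm), q_ref, atol=1e-12)


class TestMaximalCorrelationCoefficient:
    def test_degenerate_and_uniform_are_zero(self, uniform_glcms):
        m = np.zeros((4, 4))
        m[1, 2] = 1.0
        assert maximal_correlation_coefficient(
            GLCMDistribution(m, 4, "original")
        ) == pytest.approx(0.0, abs=1e-12)
        assert maximal_correlation_coefficient(uniform_glcms[0]) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_matches_eigensolver_oracle_and_sqrt_flag(self, rng):
        x = rng.integers(0, 20, size=(6, 6))
        x = x + x.T + np.eye(6, dtype=int)
        counts = CooccurrenceCounts(x, 6, standard_offsets(2, True), symmetric=True)
        glcm = normalize_pmf(counts)
        expected, _ = oracle_features(glcm.matrix, 6, "original")
        mcc = maximal_correlation_coefficient(glcm)
        assert mcc == pytest.approx(expected["maximal_correlation_coefficient"], abs=1e-10)
        assert maximal_correlation_coefficient(glcm, sqrt=True) == pytest.approx(
            np.sqrt(max(mcc, 0.0))
        )
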