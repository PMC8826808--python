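import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from oracles import naive_pearson_matrix
from pandanet.preprocess import (
    CooperativityPrior,
    ExpressionMatrix,
    RegulatoryPrior,
    assemble_priors,
    build_network_triple,
    compute_coexpression_prior,
    normalize_network,
)


def expr_of(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values)


class TestAssemblePriors:
    MOTIF = [("A", "g1", 1.0), ("A", "g2", 1.0), ("B", "g1", 1.0),
             ("B", "g3", 1.0), ("B", "g4", 1.0), ("B", "g5", 1.0)]
    PPI = [("B", "C", 1.0)]

    def expr(self):
        rng = np.random.default_rng(0)
        return expr_of(rng.standard_normal((3, 5)), genes=["g1", "g2", "g3"])

    def test_intersection_indices(self):
        motif, ppi, expr = assemble_priors(self.MOTIF, self.PPI, self.expr(),
                                           mode="intersection")
        assert motif.tf_ids == ["B"]
        # gene index = motif genes ∩ expression genes, regardless of TF filter
        assert motif.gene_ids == ["g1", "g2", "g3"]
        assert ppi.tf_ids == ["B"]
        assert expr.gene_ids == ["g1", "g2", "g3"]
        # weights land in the right cells: B targets g1 and g3, not g2
        assert motif.values.tolist() == [[1.0, 0.0, 1.0]]

    def test_union_indices_and_fill(self):
        motif, ppi, expr = assemble_priors(self.MOTIF, self.PPI, self.expr(),
                                           mode="union")
        assert motif.tf_ids == ["A", "B", "C"]
        assert motif.gene_ids == ["g1", "g2", "g3", "g4", "g5"]
        # TF C has no motif evidence -> zero row
        assert motif.values[2].sum() == 0
        # PPI for A: zero off-diagonal, unit diagonal
        a = ppi.tf_ids.index("A")
        assert ppi.values[a, a] == 1.0
        assert np.delete(ppi.values[a], a).sum() == 0
        # genes g4, g5 missing from expression -> zero rows
        assert expr.values[expr.gene_ids.index("g4")].sum() == 0

    def test_alignment_is_idempotent(self):
        out1 = assemble_priors(self.MOTIF, self.PPI, self.expr(), mode="union")
        motif_e = [(t, g, out1[0].values[i, j])
                   for i, t in enumerate(out1[0].tf_ids)
                   for j, g in enumerate(out1[0].gene_ids)]
        ppi_e = [(a, b, out1[1].values[i, j])
                 for i, a in enumerate(out1[1].tf_ids)
                 for j, b in enumerate(out1[1].tf_ids) if j >= i]
        out2 = assemble_priors(motif_e, ppi_e, out1[2], mode="intersection")
        assert out2[0].tf_ids == out1[0].tf_ids
        assert out2[0].gene_ids == out1[0].gene_ids
        np.testing.assert_array_equal(out2[0].values, out1[0].values)
        np.testing.assert_array_equal(out2[1].values, out1[1].values)

    def test_empty_intersection_names_sources(self):
        with pytest.raises(ValueError, match="PPI"):
            assemble_priors([("A", "g1", 1.0)], [("X", "Y", 1.0)],
                            self.expr(), mode="intersection")
        with pytest.raises(ValueError, match="expression"):
            assemble_priors([("A", "zz", 1.0)], [("A", "B", 1.0)],
                            self.expr(), mode="intersection")

    def test_duplicate_edges_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            assemble_priors(self.MOTIF + [("A", "g1", 0.0)], self.PPI, self.expr())
        with pytest.raises(ValueError, match="duplicate"):
            assemble_priors(self.MOTIF, [("B", "C", 1.0), ("C", "B", 1.0)],
                            self.expr())

    def test_bad_mode(self):
        with pytest.raises(ValueError, match="mode"):
            assemble_priors(self.MOTIF, self.PPI, self.expr(), mode="outer")


class TestNormalizeNetwork:
    def test_two_by_two(self):
        out = normalize_network([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_allclose(out, [[-1.0, 0.0], [0.0, 1.0]], atol=1e-12)

    def test_constant_matrix_is_zero(self):
        out = normalize_network(np.full((4, 5), 7.0))
        np.testing.assert_array_equal(out, np.zeros((4, 5)))

    def test_against_definition(self, rng):
        M = rng.standard_normal((6, 9))
        zr = (M - M.mean(1, keepdims=True)) / M.std(1, ddof=1, keepdims=True)
        zc = (M - M.mean(0)) / M.std(0, ddof=1)
        np.testing.assert_allclose(normalize_network(M),
                                   (zr + zc) / math.sqrt(2), atol=1e-12)

    def test_degenerate_row_uses_column_score_only(self, rng):
        M = rng.standard_normal((4, 4))
        M[2, :] = 5.0  # constant row
        out = normalize_network(M)
        zc = (M - M.mean(0)) / M.std(0, ddof=1)
        np.testing.assert_allclose(out[2], zc[2] / math.sqrt(2), atol=1e-12)
        assert np.all(np.isfinite(out))

    def test_shift_invariance(self, rng):
        M = rng.standard_normal((5, 7))
        np.testing.assert_allclose(normalize_network(M),
                                   normalize_network(M + 13.7), atol=1e-10)

    def test_nonfinite_rejected_with_location(self):
        M = np.ones((3, 3))
        M[1, 2] = np.nan
        with pytest.raises(ValueError, match=r"\(1, 2\)"):
            normalize_network(M)

    def test_too_small(self):
        with pytest.raises(ValueError):
            normalize_network(np.ones((1, 5)))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(arrays(np.float64, (4, 6),
                  elements=st.floats(-1e4, 1e4, allow_nan=False)))
    def test_output_always_finite(self, M):
        assert np.all(np.isfinite(normalize_network(M)))


class TestCoexpressionPrior:
    def test_identical_and_negated_profiles(self, rng):
        base = rng.standard_normal(8)
        X = np.vstack([base, base, -base])
        C = compute_coexpression_prior(expr_of(X))
        assert C[0, 1] == pytest.approx(1.0)
        assert C[0, 2] == pytest.approx(-1.0)
        np.testing.assert_array_equal(np.diag(C), np.ones(3))

    def test_matches_naive_pairwise_loop(self, rng):
        X = rng.standard_normal((5, 10))
        np.testing.assert_allclose(compute_coexpression_prior(expr_of(X)),
                                   naive_pearson_matrix(X), atol=1e-12)

    def test_constant_gene_gets_zero_correlations(self, rng):
        X = rng.standard_normal((4, 6))
        X[1] = 3.0
        C = compute_coexpression_prior(expr_of(X))
        assert C[1, 1] == 1.0
        assert np.all(C[1, [0, 2, 3]] == 0)
        assert np.all(C[[0, 2, 3], 1] == 0)

    def test_affine_invariance(self, rng):
        X = rng.standard_normal((6, 12))
        C1 = compute_coexpression_prior(expr_of(X))
        C2 = compute_coexpression_prior(expr_of(2.5 * X + 7.0))
        np.testing.assert_allclose(C1, C2, atol=1e-10)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError, match="2 samples"):
            compute_coexpression_prior(expr_of(np.ones((3, 1))))


class TestDomainTypes:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            RegulatoryPrior(["A"], ["g1", "g2"], np.ones((2, 2)))
        with pytest.raises(ValueError, match="symmetric"):
            CooperativityPrior(["A", "B"], np.array([[1.0, 2.0], [0.0, 1.0]]))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ExpressionMatrix(["g1", "g1"], ["s1"], np.ones((2, 1)))

    def test_build_triple_dimensions(self, small_inputs):
        motif, ppi, expr = small_inputs
        triple = build_network_triple(motif, ppi, expr)
        assert triple.W.shape == (20, 50)
        assert triple.P.shape == (20, 20)
        assert triple.C.shape == (50, 50)
        for m in (triple.W, triple.P, triple.C):
            assert np.all(np.isfinite(m))
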