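import math
import warnings

import numpy as np
import pytest

from oracles import naive_panda_step, naive_update_diagonal
from pandanet.panda import (
    ConvergenceWarning,
    NumericalError,
    PandaConfig,
    PandaState,
    panda_step,
    run_panda,
    run_puma,
    run_spider,
    update_diagonal,
)
from pandanet.preprocess import build_network_triple
from pandanet.similarity import METRICS
from pandanet.synthetic import FixtureSpec, gen_expression, gen_motif, gen_ppi


def state_of(triple):
    return PandaState(W=triple.W.copy(), P=triple.P.copy(), C=triple.C.copy())


class TestUpdateDiagonal:
    def test_two_by_two_has_zero_diagonal(self):
        M = np.array([[0.0, 3.0], [5.0, 0.0]])
        out = update_diagonal(M, alpha=0.3, k=4)
        assert out[0, 0] == 0.0 and out[1, 1] == 0.0
        assert out[0, 1] == 3.0 and out[1, 0] == 5.0

    def test_unit_exponent_at_step_zero(self, rng):
        M = rng.standard_normal((4, 4))
        out0 = update_diagonal(M, alpha=0.7, k=0)
        for i in range(4):
            off = np.delete(M[i], i)
            assert out0[i, i] == pytest.approx(4 * off.std(ddof=0), abs=1e-12)

    def test_matches_scalar_recomputation(self, rng):
        M = rng.standard_normal((5, 5))
        np.testing.assert_allclose(update_diagonal(M, 0.1, 3),
                                   naive_update_diagonal(M, 0.1, 3), atol=1e-12)

    def test_rejects_non_square(self):
        with pytest.raises(ValueError):
            update_diagonal(np.ones((2, 3)), 0.1, 0)


class TestPandaStep:
    @pytest.mark.parametrize("metric", METRICS)
    def test_matches_scalar_oracle(self, tiny_triple, metric):
        cfg = PandaConfig(alpha=0.15, metric=metric)
        new = panda_step(state_of(tiny_triple), cfg)
        W2, P2, C2, R, A, ham = naive_panda_step(
            tiny_triple.W, tiny_triple.P, tiny_triple.C, 0.15, metric, 0)
        np.testing.assert_allclose(new.W, W2, atol=1e-12)
        np.testing.assert_allclose(new.P, P2, atol=1e-12)
        np.testing.assert_allclose(new.C, C2, atol=1e-12)
        np.testing.assert_allclose(new.R, R, atol=1e-12)
        np.testing.assert_allclose(new.A, A, atol=1e-12)
        assert new.hamming == pytest.approx(ham, abs=1e-12)
        assert new.iteration == 1

    def test_alpha_one_jumps_to_message_average(self, tiny_triple):
        cfg = PandaConfig(alpha=1.0)
        new = panda_step(state_of(tiny_triple), cfg)
        np.testing.assert_array_equal(new.W, (new.R + new.A) / 2.0)

    def test_repeat_call_is_bit_identical(self, tiny_triple):
        cfg = PandaConfig(alpha=0.1)
        a = panda_step(state_of(tiny_triple), cfg)
        b = panda_step(state_of(tiny_triple), cfg)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.P, b.P)
        np.testing.assert_array_equal(a.C, b.C)

    def test_nonfinite_input_names_stage(self, tiny_triple):
        st = state_of(tiny_triple)
        st.P[0, 0] = np.inf
        with pytest.raises(NumericalError, match="stage"):
            panda_step(st, PandaConfig())
        st2 = state_of(tiny_triple)
        st2.C[1, 1] = np.nan
        with pytest.raises(NumericalError, match="stage"):
            panda_step(st2, PandaConfig(metric="euclidean"))


class TestRunPanda:
    def test_huge_tolerance_returns_prior_unchanged(self, small_triple):
        net = run_panda(small_triple, PandaConfig(tolerance=1e12))
        assert net.iterations_used == 0
        assert net.converged
        np.testing.assert_array_equal(net.weights, small_triple.W)

    def test_deterministic_across_runs(self, small_triple):
        cfg = PandaConfig()
        a = run_panda(small_triple, cfg)
        b = run_panda(small_triple, cfg)
        np.testing.assert_array_equal(a.weights, b.weights)
        assert a.iterations_used == b.iterations_used

    def test_converges_on_small_fixture(self, small_triple):
        net = run_panda(small_triple, PandaConfig(alpha=0.1, metric="tfunction"))
        assert net.converged
        assert net.iterations_used <= 200
        assert net.hamming_trace[-1] < 1e-3
        assert np.all(np.isfinite(net.weights))

    def test_hamming_trace_matches_step_sequence(self, tiny_triple):
        cfg = PandaConfig(alpha=0.2, tolerance=1e-4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            net = run_panda(tiny_triple, cfg)
        st = state_of(tiny_triple)
        for expected in net.hamming_trace[:-1]:
            st = panda_step(st, cfg)
            assert st.hamming == pytest.approx(expected, rel=1e-12)

    def test_nonconvergence_warns_not_raises(self, small_triple):
        cfg = PandaConfig(max_iter=2, tolerance=1e-9)
        with pytest.warns(ConvergenceWarning):
            net = run_panda(small_triple, cfg)
        assert not net.converged
        assert net.iterations_used == 2

    @pytest.mark.parametrize("metric", METRICS)
    @pytest.mark.parametrize("alpha", [0.1, 0.2, 0.3])
    def test_terminates_for_every_metric_and_alpha(self, small_triple, metric, alpha):
        net = run_panda(small_triple, PandaConfig(alpha=alpha, metric=metric))
        assert net.converged
        assert np.all(np.isfinite(net.weights))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PandaConfig(alpha=0.0)
        with pytest.raises(ValueError):
            PandaConfig(tolerance=-1)
        with pytest.raises(ValueError):
            PandaConfig(metric="nope")


class TestPuma:
    def test_empty_set_reduces_to_panda(self, small_triple):
        base = run_panda(small_triple, PandaConfig())
        puma = run_puma(small_triple, [], PandaConfig())
        np.testing.assert_array_equal(base.weights, puma.weights)
        assert base.iterations_used == puma.iterations_used

    def test_unknown_regulator_rejected(self, small_triple):
        with pytest.raises(ValueError, match="unknown regulator"):
            run_puma(small_triple, ["TF9999"], PandaConfig())

    def test_frozen_rows_stay_at_prior_every_step(self, tiny_triple):
        from pandanet.backend import BackendHandle, get_backend
        from pandanet.panda import _commit, _messages

        frozen_ids = [tiny_triple.tf_ids[0], tiny_triple.tf_ids[2]]
        idx = np.array([0, 2])
        backend = get_backend(BackendHandle())
        W, P, C = tiny_triple.W.copy(), tiny_triple.P.copy(), tiny_triple.C.copy()
        P0 = tiny_triple.P
        for k in range(5):
            R, A = _messages(W, P, C, "tfunction", backend)
            W, P, C = _commit(W, P, C, (R + A) / 2, 0.1, k, "tfunction",
                              backend, frozen=idx, P_prior=P0)
            np.testing.assert_array_equal(P[idx, :], P0[idx, :])
            np.testing.assert_array_equal(P[:, idx], P0[:, idx])
        # the full-run result also differs from PANDA when a freeze is active
        puma = run_puma(tiny_triple, frozen_ids, PandaConfig())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            base = run_panda(tiny_triple, PandaConfig())
        assert not np.array_equal(puma.weights, base.weights)

    def test_full_freeze_keeps_whole_prior(self, tiny_triple):
        from pandanet.backend import BackendHandle, get_backend
        from pandanet.panda import _commit, _messages

        idx = np.arange(len(tiny_triple.tf_ids))
        backend = get_backend(BackendHandle())
        W, P, C = tiny_triple.W.copy(), tiny_triple.P.copy(), tiny_triple.C.copy()
        for k in range(4):
            R, A = _messages(W, P, C, "tfunction", backend)
            W, P, C = _commit(W, P, C, (R + A) / 2, 0.1, k, "tfunction",
                              backend, frozen=idx, P_prior=tiny_triple.P)
            np.testing.assert_array_equal(P, tiny_triple.P)


class TestSpider:
    @pytest.fixture(scope="class")
    @staticmethod
    def inputs():
        spec = FixtureSpec(n_tf=8, n_genes=15, n_samples=10, seed=11)
        return gen_motif(spec), gen_ppi(spec), gen_expression(spec)

    def test_identity_mask_reduces_to_panda(self, inputs):
        motif, ppi, expr = inputs
        triple = build_network_triple(motif, ppi, expr)
        base = run_panda(triple, PandaConfig())
        spider = run_spider(motif, ppi, expr, np.ones_like(motif.values),
                            PandaConfig())
        np.testing.assert_array_equal(base.weights, spider.weights)

    def test_all_zero_mask_still_runs(self, inputs):
        motif, ppi, expr = inputs
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            net = run_spider(motif, ppi, expr, np.zeros_like(motif.values),
                             PandaConfig(max_iter=3))
        assert np.all(np.isfinite(net.weights))

    def test_random_mask_zeroes_prior_entries(self, inputs, rng):
        motif, ppi, expr = inputs
        mask = (rng.random(motif.values.shape) < 0.5).astype(float)
        masked = motif.values * mask
        assert np.all(masked[mask == 0] == 0)
        net = run_spider(motif, ppi, expr, mask, PandaConfig())
        assert np.all(np.isfinite(net.weights))

    def test_shape_and_value_validation(self, inputs):
        motif, ppi, expr = inputs
        with pytest.raises(ValueError, match="shape"):
            run_spider(motif, ppi, expr, np.ones((2, 2)), PandaConfig())
        bad = np.ones_like(motif.values)
        bad[0, 0] = 0.5
        with pytest.raises(ValueError, match="0 or 1"):
            run_spider(motif, ppi, expr, bad, PandaConfig())
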