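"""Expectation-maximization: initialization, E0 step, PWM step, full fits."""

import numpy as np
import pytest

from bindnseq import (
    EnergyModel,
    Pwm,
    ReadLibrary,
    classify_runs,
    fit_em,
    init_model,
    optimize_e0,
    update_pwm,
)
from bindnseq.em import best_shift_tv, e0_gradient
from bindnseq.background import annotate_priors, train_markov
from bindnseq.simulate import SimulationConfig, simulate_selection

from conftest import make_toy_library, random_pwm


class TestInitModel:
    @pytest.mark.parametrize("mode,consensus", [("random", None), ("consensus", "TGCA")])
    def test_rows_normalized(self, mode, consensus):
        m = init_model(6, mode, consensus=consensus, seed=3)
        assert np.allclose(m.pwm.matrix.sum(axis=1), 1.0, atol=1e-12)
        assert -np.inf < m.e0 <= 0

    def test_consensus_argmax_spells_motif(self):
        m = init_model(6, "consensus", consensus="TGCATG")
        assert m.pwm.consensus == "TGCATG"

    def test_short_consensus_centered_with_uniform_flanks(self):
        m = init_model(8, "consensus", consensus="TGCATG")
        assert np.allclose(m.pwm.matrix[0], 0.25, atol=1e-6)
        assert np.allclose(m.pwm.matrix[7], 0.25, atol=1e-6)
        assert m.pwm.consensus[1:7] == "TGCATG"

    def test_random_init_deterministic_under_seed(self):
        a = init_model(7, "random", seed=99)
        b = init_model(7, "random", seed=99)
        assert (a.pwm.matrix == b.pwm.matrix).all()

    def test_e0_initialized_from_mean_read_length(self):
        m = init_model(5, "random", seed=0, mean_read_length=20.0)
        assert m.e0 == pytest.approx(np.log(1 / 20))

    def test_invalid_consensus_errors(self):
        with pytest.raises(ValueError):
            init_model(6, "consensus", consensus="TGXATG")


class TestOptimizeE0:
    def test_agrees_with_grid_scan(self):
        from oracles import grid_optimize_e0

        lib = make_toy_library(31, n_reads=3, min_len=10, max_len=12)
        pwm = random_pwm(31, 5)
        e0 = optimize_e0(lib, pwm)
        oracle = grid_optimize_e0(
            lib.sequences, lib.counts, np.exp(lib.log_priors), pwm.matrix
        )
        assert e0 == pytest.approx(oracle, abs=1e-3)

    def test_interior_optimum_has_small_gradient(self, small_sim):
        fg = small_sim["fg"]
        pwm = Pwm.from_consensus("TGCATG", weight=0.85)
        res = optimize_e0(fg, pwm, full_output=True)
        assert not res.on_edge and not res.degenerate
        # Scale-invariant residual: gradient per read
        assert abs(e0_gradient(fg, pwm, res.e0)) / fg.total_count < 1e-6

    def test_e0_step_never_decreases_likelihood(self):
        from bindnseq.likelihood import log_likelihood

        lib = make_toy_library(8, n_reads=8)
        pwm = random_pwm(8, 5)
        before = log_likelihood(lib, EnergyModel(pwm, -1.0))
        after = log_likelihood(lib, EnergyModel(pwm, optimize_e0(lib, pwm)))
        assert after >= before - 1e-10

    def test_degenerate_when_no_specific_weight(self):
        # one-hot PWM matching no window; objective constant in E0
        lib = ReadLibrary(["CCCCC", "GGGGG"], [1, 1], np.log([0.5, 0.5]))
        res = optimize_e0(lib, Pwm.one_hot("AAAAA"), full_output=True)
        assert res.degenerate
        assert res.e0 == pytest.approx(-15.0)


class TestUpdatePwm:
    def test_one_hot_fixed_point(self):
        reads = ["TTACGTATT", "GGACGTAGG", "ACGTACCCC"]
        lib = ReadLibrary(reads, [1, 2, 1], np.log([0.3, 0.3, 0.4]))
        pwm = Pwm.one_hot("ACGTA", floor=0.0)
        new = update_pwm(lib, EnergyModel(pwm, -np.inf))
        assert np.allclose(new.matrix, pwm.matrix, atol=1e-9)

    def test_uniform_pwm_yields_window_frequency_matrix(self):
        lib = make_toy_library(5, n_reads=5, min_len=8, max_len=12)
        lw = 4
        new = update_pwm(lib, EnergyModel(Pwm.uniform(lw, floor=0.0), -np.inf))
        # every window of read S carries weight n_S / (L_S - lw + 1)
        accum = np.zeros((lw, 4))
        for seq, n in zip(lib.sequences, lib.counts):
            n_win = len(seq) - lw + 1
            for j in range(n_win):
                for i, b in enumerate(seq[j : j + lw]):
                    accum[i, "ACGT".index(b)] += n / n_win
        accum /= accum.sum(axis=1, keepdims=True)
        assert np.allclose(new.matrix, accum, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle(self, seed):
        from oracles import naive_update_pwm

        lib = make_toy_library(seed + 50, n_reads=6)
        pwm = random_pwm(seed + 50, 5)
        model = EnergyModel(pwm, -3.0)
        got = update_pwm(lib, model)
        raw = naive_update_pwm(lib.sequences, lib.counts, pwm.matrix, model.e0)
        expected = Pwm(raw, floor=pwm.floor)
        assert np.abs(got.matrix - expected.matrix).max() < 1e-12


class TestFitEm:
    def test_deterministic_under_seed(self, small_sim):
        a = fit_em(small_sim["fg"], 6, seed=5, max_iter=5)
        b = fit_em(small_sim["fg"], 6, seed=5, max_iter=5)
        assert (a.model.pwm.matrix == b.model.pwm.matrix).all()
        assert a.model.e0 == b.model.e0
        assert a.loglik_trace == b.loglik_trace

    def test_recovers_planted_motif(self, small_sim):
        """Best-of-restarts finds the planted PWM; E0 comes back specific and
        in the right region, with the known upward finite-depth bias of the
        self-normalized likelihood (the denominator runs over the observed
        reads only; see docs/methods.md)."""
        fits = [fit_em(small_sim["fg"], 6, seed=s) for s in range(4)]
        best = max(fits, key=lambda f: f.final_loglik)
        tv, _ = best_shift_tv(best.model.pwm, small_sim["config"].planted_pwm)
        assert best.convergent and best.specific
        assert tv < 0.1
        planted = small_sim["config"].planted_e0
        assert planted - 1.0 < best.model.e0 < planted + 2.0

    def test_converged_run_is_a_fixed_point(self, small_sim):
        fit = fit_em(small_sim["fg"], 6, seed=1)
        assert fit.reached_tol
        lib = small_sim["fg"].filter_min_length(6)
        again = update_pwm(lib, fit.model)
        assert ((again.matrix - fit.model.pwm.matrix) ** 2).sum() < 6 * 4 * 1e-6

    def test_typical_run_takes_tens_of_iterations(self, small_sim):
        fit = fit_em(small_sim["fg"], 6, seed=1)
        assert fit.reached_tol
        assert fit.iterations <= 100

    def test_flags_match_definitions(self, small_sim):
        fit = fit_em(small_sim["fg"], 6, seed=1, max_iter=30)
        assert fit.convergent == (fit.final_loglik > fit.initial_loglik)
        assert fit.specific == (fit.model.e0 < 0)

    def test_short_reads_are_filtered(self):
        lib = ReadLibrary(
            ["ACG", "ACGTACGTACGT", "TTGGCCAATTGG"], [1, 2, 2], np.log([0.2, 0.4, 0.4])
        )
        fit = fit_em(lib, 6, seed=0, max_iter=3)
        assert fit.lw == 6  # runs despite the 3-mer

    def test_all_reads_too_short_errors(self):
        lib = ReadLibrary(["ACGT"], [1], np.log([1.0]))
        with pytest.raises(ValueError):
            fit_em(lib, 6, seed=0)


class TestClassifyRuns:
    def _mk(self, convergent, specific):
        pwm = Pwm.uniform(5)
        from bindnseq.em import FitResult

        return FitResult(
            model=EnergyModel(pwm, -1.0 if specific else 0.0),
            lw=5, init_mode="random", seed=0, loglik_trace=[0.0],
            initial_loglik=0.0, final_loglik=1.0 if convergent else -1.0,
            iterations=1, convergent=convergent, specific=specific,
            reached_tol=True,
        )

    def test_all_good(self):
        runs = [self._mk(True, True) for _ in range(3)]
        s = classify_runs(runs)
        assert s["frac_convergent"] == 1.0
        assert s["frac_convergent_specific"] == 1.0

    def test_hand_built_fractions(self):
        runs = [self._mk(True, True), self._mk(True, False),
                self._mk(False, True), self._mk(False, False)]
        s = classify_runs(runs)
        assert s["n_convergent"] == 2
        assert s["n_convergent_specific"] == 1
        assert s["frac_convergent"] == 0.5
        assert s["frac_convergent_specific"] == 0.25

    def test_no_signal_library_yields_fewer_specific_runs(self):
        # planted uniform PWM: nothing to find, unspecific term dominates
        config = SimulationConfig(
            planted_pwm=Pwm.uniform(6), planted_e0=-4.0,
            n_background=4000, n_foreground=4000, seed=11,
        )
        exp = simulate_selection(config)
        fg = annotate_priors(train_markov(exp.background_library, 2), exp.foreground_library)
        runs = [fit_em(fg, 6, seed=s, max_iter=60) for s in range(8)]
        s = classify_runs(runs)
        assert s["frac_convergent_specific"] < s["frac_convergent"] or s["frac_convergent"] == 0
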