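"""Boltzmann weights, selection probabilities and the data log-likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bindnseq import (
    EnergyModel,
    Pwm,
    ReadLibrary,
    bound_probability,
    log_likelihood,
    read_weight,
    selection_probability,
    site_weight,
)
from bindnseq.likelihood import log_selection_probabilities

from conftest import make_toy_library, random_pwm
from oracles import naive_log_likelihood, naive_read_weight, naive_selection_probs, naive_site_weight


class TestSiteWeight:
    def test_uniform_pwm(self):
        assert site_weight(Pwm.uniform(5), "TGCAT") == pytest.approx(4.0**-5, rel=1e-12)

    def test_one_hot_indicator(self):
        pwm = Pwm.one_hot("ACGTA")
        assert site_weight(pwm, "ACGTA") == 1.0
        assert site_weight(pwm, "ACGTT") == 0.0

    def test_matches_elementwise_oracle(self):
        pwm = random_pwm(11, 5)
        assert site_weight(pwm, "TGCAT") == pytest.approx(
            naive_site_weight(pwm.matrix, "TGCAT"), rel=1e-12
        )

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            site_weight(Pwm.uniform(5), "ACGT")


class TestReadWeight:
    def test_uniform_pwm_counts_windows(self):
        assert read_weight(Pwm.uniform(5), "A" * 20) == pytest.approx(16 * 4.0**-5, rel=1e-12)

    def test_one_hot_single_match(self):
        assert read_weight(Pwm.one_hot("ACGTA"), "TTACGTATT") == pytest.approx(1.0, rel=1e-12)

    def test_read_shorter_than_lw_errors(self):
        with pytest.raises(ValueError):
            read_weight(Pwm.uniform(6), "ACGTA")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        read=st.text(alphabet="ACGT", min_size=6, max_size=30),
    )
    def test_equals_window_enumeration(self, seed, read):
        pwm = random_pwm(seed, 6)
        assert read_weight(pwm, read) == pytest.approx(
            naive_read_weight(pwm.matrix, read), rel=1e-9
        )


class TestBoundProbability:
    def test_zero_concentration(self):
        model = EnergyModel(Pwm.uniform(5), -3.0)
        assert bound_probability("ACGTACGTA", 0.0, model) == 0.0

    def test_monotone_in_c_and_saturates(self):
        model = EnergyModel(Pwm.uniform(5), -3.0)
        cs = np.logspace(-4, 6, 30)
        ps = [bound_probability("ACGTACGTA", c, model) for c in cs]
        assert all(b > a for a, b in zip(ps, ps[1:]))
        assert ps[-1] == pytest.approx(1.0, abs=1e-4)

    def test_linearization_taylor_bound(self):
        # |full - linear| / linear < 1.1e-4 whenever cW < 1e-4
        rng = np.random.default_rng(0)
        for seed in range(20):
            pwm = random_pwm(seed, 5)
            model = EnergyModel(pwm, float(-rng.uniform(2, 10)))
            read = "".join(rng.choice(list("ACGT"), size=15))
            w = naive_read_weight(pwm.matrix, read) + 11 * np.exp(model.e0)
            c = 0.99e-4 / w
            full = bound_probability(read, c, model, linearized=False)
            lin = bound_probability(read, c, model, linearized=True)
            assert lin <= 1e-4
            assert abs(full - lin) / lin < 1.1e-4


class TestSelectionProbability:
    def test_sums_to_one(self, toy_library):
        model = EnergyModel(random_pwm(2, 5), -4.0)
        log_p = log_selection_probabilities(toy_library, model)
        assert np.exp(log_p).sum() == pytest.approx(1.0, abs=1e-12)

    def test_reduces_to_priors_without_specific_signal(self):
        lib = make_toy_library(9, n_reads=5, min_len=10, max_len=10)
        model = EnergyModel(Pwm.uniform(4), 0.0)
        # uniform PWM + equal lengths: W identical for every read
        log_p = log_selection_probabilities(lib, model)
        f = np.exp(lib.log_priors)
        assert np.allclose(np.exp(log_p), f / f.sum(), atol=1e-12)

    def test_matches_scalar_oracle(self):
        lib = make_toy_library(17, n_reads=5)
        pwm = random_pwm(17, 5)
        model = EnergyModel(pwm, -3.5)
        expected = naive_selection_probs(
            lib.sequences, np.exp(lib.log_priors), pwm.matrix, model.e0
        )
        for seq, exp_p in zip(lib.sequences, expected):
            assert selection_probability(seq, lib, model) == pytest.approx(exp_p, rel=1e-9)

    def test_unannotated_library_errors(self):
        lib = ReadLibrary(["ACGTACGT"], [1])
        with pytest.raises(ValueError, match="prior"):
            selection_probability("ACGTACGT", lib, EnergyModel(Pwm.uniform(4), -1.0))


class TestLogLikelihood:
    def test_single_read_library_is_zero(self):
        lib = ReadLibrary(["ACGTACGTAC"], [7], np.array([np.log(0.3)]))
        assert log_likelihood(lib, EnergyModel(random_pwm(0, 5), -2.0)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_symmetric_two_read_split(self):
        lib = ReadLibrary(
            ["AACCGGTTAA", "CCGGTTAACC"], [1, 1], np.log([0.5, 0.5])
        )
        model = EnergyModel(Pwm.uniform(5), -np.inf)
        assert log_likelihood(lib, model) == pytest.approx(2 * np.log(0.5), rel=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_arithmetic(self, seed):
        lib = make_toy_library(seed, n_reads=6)
        pwm = random_pwm(seed + 100, 5)
        model = EnergyModel(pwm, -4.0)
        expected = naive_log_likelihood(
            lib.sequences, lib.counts, np.exp(lib.log_priors), pwm.matrix, model.e0
        )
        assert log_likelihood(lib, model) == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_reordering(self):
        lib = make_toy_library(23, n_reads=6)
        perm = np.random.default_rng(0).permutation(len(lib))
        shuffled = ReadLibrary(
            [lib.sequences[i] for i in perm], lib.counts[perm], lib.log_priors[perm]
        )
        model = EnergyModel(random_pwm(23, 5), -3.0)
        assert log_likelihood(shuffled, model) == pytest.approx(
            log_likelihood(lib, model), rel=1e-12
        )

    def test_duplicates_collapse_to_counts(self):
        a = ReadLibrary.from_reads(["ACGTACGTAC", "ACGTACGTAC", "TTTTGGGGCC"])
        b = ReadLibrary(["ACGTACGTAC", "TTTTGGGGCC"], [2, 1])
        lp = np.log([0.4, 0.6])
        model = EnergyModel(random_pwm(4, 4), -2.0)
        assert log_likelihood(a.with_priors(lp), model) == pytest.approx(
            log_likelihood(b.with_priors(lp), model), rel=1e-12
        )

    def test_zero_weight_read_gives_minus_inf(self):
        lib = ReadLibrary(["ACGTA", "TTTTT"], [1, 1], np.log([0.5, 0.5]))
        model = EnergyModel(Pwm.one_hot("ACGTA"), -np.inf)
        assert log_likelihood(lib, model) == -np.inf
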