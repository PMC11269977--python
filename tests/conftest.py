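import numpy as np
import pytest

from bindnseq import (
    MarkovBackground,
    Pwm,
    ReadLibrary,
    SimulationConfig,
    annotate_priors,
    simulate_selection,
    train_markov,
)

BASES = "ACGT"


def random_reads(rng, n, length):
    return ["".join(rng.choice(list(BASES), size=length)) for _ in range(n)]


def make_toy_library(seed, n_reads=6, min_len=8, max_len=15):
    """Small annotated library with random counts and random positive priors."""
    rng = np.random.default_rng(seed)
    seqs = set()
    while len(seqs) < n_reads:
        L = int(rng.integers(min_len, max_len + 1))
        seqs.add("".join(rng.choice(list(BASES), size=L)))
    seqs = sorted(seqs)
    counts = rng.integers(1, 6, size=n_reads)
    log_priors = np.log(rng.uniform(0.1, 1.0, size=n_reads))
    return ReadLibrary(seqs, counts, log_priors)


def random_pwm(seed, lw, floor=1e-9):
    rng = np.random.default_rng(seed)
    return Pwm(rng.dirichlet(np.ones(4), size=lw), floor=floor)


@pytest.fixture(scope="session")
def small_sim():
    """One shared planted-motif experiment (scaled-down pools) with the
    trained degree-4 background model and the annotated foreground."""
    config = SimulationConfig(n_background=20_000, n_foreground=20_000, seed=1)
    exp = simulate_selection(config)
    bg_model = train_markov(exp.background_library, degree=4, pseudocount=1.0)
    fg = annotate_priors(bg_model, exp.foreground_library)
    return {"config": config, "exp": exp, "bg_model": bg_model, "fg": fg}


@pytest.fixture
def toy_library():
    return make_toy_library(42)


@pytest.fixture
def uniform_bg():
    return MarkovBackground.uniform(0)
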