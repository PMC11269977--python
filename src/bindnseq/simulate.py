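"""Synthetic Bind'n-Seq experiment generator.

The simulator produces the two read pools an analysis consumes — an input
(background) pool and an RBP-selected (foreground) pool — from known ground
truth, so the whole inference pipeline can be exercised and scored without
external data.

Background reads are i.i.d. draws from a biased composition model (a base
frequency vector or a trained Markov chain; real input pools are typically
A-rich). Selection emulates the physical experiment, in which the synthesis
pool is enormous and every distinct oligomer is present with abundance
proportional to its composition prior f_S: a candidate set of distinct
sequences is drawn from the background process, each is assigned its
probability of being RBP-bound under a planted (PWM, E0, concentration)
model — full sigmoidal form or its linearization — and foreground reads
are sampled with replacement with probability proportional to
prior x bound. Sequenced copy numbers are then governed by f_S W_S, the
same law the selection likelihood assigns. An explicit candidate pool with
per-read priors may be supplied instead of the generated one.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .background import MarkovBackground
from .library import ReadLibrary
from .likelihood import EnergyModel, Pwm, _total_log_weights, library_log_weights

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Ground truth and pool sizes for one synthetic experiment.

    Defaults emulate a realistic single-concentration experiment: 20-nt
    reads, 5e4 reads per pool, a mildly A-rich input composition (30% A —
    strong enough to require the Markov prior correction while keeping the
    planted motif identifiable; see docs/methods.md), a planted hexamer PWM
    with consensus weight 0.85, unspecific log-weight -8, and a protein
    concentration low enough that binding stays far from saturation (the
    linearized and full models then agree).
    """

    planted_pwm: Pwm = field(default_factory=lambda: Pwm.from_consensus("TGCATG", weight=0.85))
    planted_e0: float = -8.0
    concentration: float = 1e-4
    read_length: int = 20
    n_background: int = 50_000
    n_foreground: int = 50_000
    n_candidates: int | None = None  # defaults to n_background
    background_bias: MarkovBackground | tuple | list = (0.30, 0.22, 0.22, 0.26)
    seed: int = 0
    mode: str = "linearized"

    def __post_init__(self) -> None:
        if self.mode not in ("linearized", "full"):
            raise ValueError("mode must be 'linearized' or 'full'")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.read_length < self.planted_pwm.length:
            raise ValueError("read_length shorter than planted PWM")

    @property
    def bias_model(self) -> MarkovBackground:
        if isinstance(self.background_bias, MarkovBackground):
            return self.background_bias
        return MarkovBackground.from_base_frequencies(self.background_bias)

    def check_linearization(self) -> None:
        """Linearized mode requires c * W_max << 1 (unsaturated binding)."""
        n_win = self.read_length - self.planted_pwm.length + 1
        w_max = n_win * (
            float(self.planted_pwm.matrix.max(axis=1).prod()) + np.exp(self.planted_e0)
        )
        if self.concentration * w_max >= 0.01:
            raise ValueError(
                f"linearized mode invalid: c*W_max = {self.concentration * w_max:.3g} "
                ">= 0.01; lower the concentration or use mode='full'"
            )

    def truth_dict(self) -> dict:
        return {
            "pwm": self.planted_pwm.matrix.tolist(),
            "consensus": self.planted_pwm.consensus,
            "e0": self.planted_e0,
            "concentration": self.concentration,
            "read_length": self.read_length,
            "mode": self.mode,
            "seed": self.seed,
        }


@dataclass
class SimulatedExperiment:
    background: list[str]
    foreground: list[str]
    truth: dict
    no_selection: bool = False

    @property
    def background_library(self) -> ReadLibrary:
        return ReadLibrary.from_reads(self.background)

    @property
    def foreground_library(self) -> ReadLibrary:
        return ReadLibrary.from_reads(self.foreground)


# ---------------------------------------------------------------------- #
def sample_background(config: SimulationConfig, n: int | None = None,
                      rng: np.random.Generator | None = None) -> list[str]:
    """Draw i.i.d. background reads from the configured composition bias."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = n if n is not None else config.n_background
    return config.bias_model.sample(n, config.read_length, rng)


def _log_bound_weights(
    lib: ReadLibrary, model: EnergyModel, c: float, mode: str
) -> np.ndarray:
    """Per-distinct-read log bound probability (or its linearization)."""
    log_e, n_win = library_log_weights(lib, model.pwm)
    log_w = _total_log_weights(log_e, n_win, model.e0)
    if c == 0:
        return np.full(len(lib), -np.inf)
    log_cw = np.log(c) + log_w
    if mode == "linearized":
        return log_cw
    # log sigmoid(log cW) = -log(1 + exp(-log cW))
    return -np.logaddexp(0.0, -log_cw)


def _candidate_log_priors(lib: ReadLibrary, chain: MarkovBackground) -> np.ndarray:
    out = np.empty(len(lib))
    for _, (idx, mat) in lib.by_length().items():
        out[idx] = chain.log_priors_matrix(mat)
    return out


def simulate_selection(
    config: SimulationConfig,
    candidates: list[str] | None = None,
    candidate_log_priors: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedExperiment:
    """Select a foreground pool from candidates by Boltzmann binding.

    Candidates are deduplicated, and each distinct sequence S is sampled
    (with replacement) with probability proportional to f_S x P(bound|S):
    the synthesis pool is vast, so a sequence's physical abundance tracks
    its prior and the observed copy numbers follow f_S W_S. Priors come
    from ``candidate_log_priors`` when an explicit pool is supplied, and
    from the configured bias model otherwise. At c = 0 (full mode) every
    bound probability vanishes; selection then falls back to
    prior-proportional sampling and the result is flagged ``no_selection``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if config.mode == "linearized":
        config.check_linearization()
    background = sample_background(config, rng=rng)
    if candidates is None:
        n_cand = config.n_candidates or config.n_background
        candidates = sample_background(config, n=n_cand, rng=rng)
        candidate_log_priors = None
    model = EnergyModel(config.planted_pwm, config.planted_e0)

    lib = ReadLibrary.from_reads(candidates)
    log_wt = _log_bound_weights(lib, model, config.concentration, config.mode)
    if candidate_log_priors is not None:
        prior_map = dict(zip(candidates, candidate_log_priors))
        log_prior = np.array([prior_map[s] for s in lib.sequences])
    else:
        log_prior = _candidate_log_priors(lib, config.bias_model)
    log_wt = log_wt + log_prior

    no_selection = False
    if np.isneginf(log_wt).all():
        # no binding at all: the selected pool is statistically just another
        # draw from the input process
        logger.warning("all bound probabilities are zero; sampling without selection")
        no_selection = True
        foreground = sample_background(config, n=config.n_foreground, rng=rng)
    else:
        p = np.exp(log_wt - logsumexp(log_wt))
        p = p / p.sum()
        draws = rng.choice(len(lib), size=config.n_foreground, replace=True, p=p)
        foreground = [lib.sequences[i] for i in draws]
    truth = config.truth_dict()
    truth["no_selection"] = no_selection
    return SimulatedExperiment(background, foreground, truth, no_selection)


def write_truth(path, truth: dict) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
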