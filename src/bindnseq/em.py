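"""Expectation-maximization inference of (PWM, E0).

The EM loop alternates two steps until the PWM stops moving:

1. Hold the PWM fixed and re-fit the unspecific log-weight E0 by bounded
   one-dimensional maximization of the data log-likelihood (Brent-style);
   the analytic likelihood derivative in E0 is exposed separately as a
   post-hoc residual check.
2. Hold E0 fixed and re-estimate the PWM by responsibility-weighted
   counting: every window s of every read S adds
   n_S e^{E(s)} / (e^{E(S)} + (L_S - Lw + 1) e^{E0}) to the matrix entries
   it touches, after which rows are renormalized (with the configured
   entry floor).

Iteration stops when the summed squared PWM change drops below
Lw * 4 * tol (tol defaults to 1e-6 per entry) or ``max_iter`` is reached.
A run is *convergent* when its final log-likelihood exceeds the initial
one, and *specific* when the fitted E0 is strictly negative — otherwise
the unspecific term dominates and the PWM does not explain the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .library import ReadLibrary
from .likelihood import (
    DEFAULT_FLOOR,
    EnergyModel,
    Pwm,
    _total_log_weights,
    library_log_weights,
    log_likelihood,
    window_log_scores,
)

logger = logging.getLogger(__name__)

DEFAULT_E0_BRACKET = (-30.0, 0.0)
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 500


@dataclass
class FitResult:
    """Outcome of a single EM run."""

    model: EnergyModel
    lw: int
    init_mode: str
    seed: int
    loglik_trace: list[float]
    initial_loglik: float
    final_loglik: float
    iterations: int
    convergent: bool
    specific: bool
    reached_tol: bool
    log_kd_rel: float | None = None

    def trace_non_decreasing(self, rtol: float = 1e-8) -> bool:
        t = np.asarray(self.loglik_trace)
        if len(t) < 2:
            return True
        drops = np.diff(t)
        return bool((drops >= -rtol * np.abs(t[:-1])).all())


# ---------------------------------------------------------------------- #
def init_model(
    lw: int,
    mode: str = "random",
    consensus: str | None = None,
    seed: int = 0,
    mean_read_length: float = 20.0,
    consensus_weight: float = 0.7,
    floor: float = DEFAULT_FLOOR,
) -> EnergyModel:
    """Initialize (PWM, E0) for an EM run.

    ``random`` draws each PWM row from a flat Dirichlet; ``consensus``
    polarizes the matrix toward a given motif (weight 0.7 on the consensus
    base, 0.1 elsewhere), centering shorter motifs with uniform flanks.
    E0 starts at log(1 / mean read length) in both modes.
    """
    if lw < 1:
        raise ValueError("lw must be >= 1")
    e0 = float(np.log(1.0 / mean_read_length))
    if mode == "random":
        rng = np.random.default_rng(seed)
        m = rng.dirichlet(np.ones(4), size=lw)
        pwm = Pwm(m, floor=floor)
    elif mode == "consensus":
        if consensus is None:
            raise ValueError("consensus mode requires a motif string")
        pwm = Pwm.from_consensus(consensus, length=lw, weight=consensus_weight, floor=floor)
    else:
        raise ValueError(f"unknown init mode {mode!r}")
    return EnergyModel(pwm, e0)


# ---------------------------------------------------------------------- #
def _profile_loglik(
    log_e: np.ndarray,
    n_win: np.ndarray,
    log_priors: np.ndarray,
    counts: np.ndarray,
    e0: float,
) -> float:
    log_w = _total_log_weights(log_e, n_win, e0)
    log_num = log_priors + log_w
    log_z = logsumexp(log_num)
    return float(np.dot(counts, log_num - log_z))


def e0_gradient(library: ReadLibrary, pwm: Pwm, e0: float) -> float:
    """Analytic d(log-likelihood)/dE0 at the given point.

    Used as a residual check on the optimizer: at an interior optimum it
    should vanish.
    """
    log_e, n_win = library_log_weights(library, pwm)
    counts = library.counts.astype(float)
    log_w = _total_log_weights(log_e, n_win, e0)
    term1 = float(np.dot(counts, np.exp(e0 + np.log(n_win) - log_w)))
    log_num = library.log_priors + log_w
    log_z = logsumexp(log_num)
    log_unspec = logsumexp(library.log_priors + np.log(n_win)) + e0
    term2 = float(counts.sum() * np.exp(log_unspec - log_z))
    return term1 - term2


@dataclass
class E0Optimum:
    e0: float
    on_edge: bool
    degenerate: bool


def optimize_e0(
    library: ReadLibrary,
    pwm: Pwm,
    bracket: tuple[float, float] = DEFAULT_E0_BRACKET,
    full_output: bool = False,
    _weights: tuple[np.ndarray, np.ndarray] | None = None,
):
    """Maximize the log-likelihood over E0 in ``bracket`` with the PWM fixed.

    Degenerate libraries in which every read has zero specific weight make
    the objective constant in E0; such runs return the bracket midpoint
    with a warning and a ``degenerate`` flag.
    """
    if not library.annotated:
        raise ValueError("library has no frequency priors")
    lo, hi = bracket
    if not (lo < hi <= 0):
        raise ValueError("bracket must satisfy lo < hi <= 0")
    log_e, n_win = _weights if _weights is not None else library_log_weights(library, pwm)
    counts = library.counts.astype(float)
    degenerate = bool(np.isneginf(log_e).all())
    if degenerate:
        logger.warning("optimize_e0: objective constant in E0 (no specific weight)")
        e0 = 0.5 * (lo + hi)
        res = E0Optimum(e0, on_edge=False, degenerate=True)
        return res if full_output else e0
    neg = lambda e0: -_profile_loglik(log_e, n_win, library.log_priors, counts, e0)
    opt = minimize_scalar(neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-9})
    # the bounded method never returns the bracket ends themselves; snap to an
    # end when it is at least as good, so edge-dominated solutions (notably
    # E0 = 0, the unspecific-dominated case) are represented exactly
    cand = [(neg(lo), lo), (neg(hi), hi), (opt.fun, float(opt.x))]
    e0 = min(cand, key=lambda t: t[0])[1]
    on_edge = e0 == lo or e0 == hi
    res = E0Optimum(e0, on_edge=on_edge, degenerate=False)
    return res if full_output else e0


# ---------------------------------------------------------------------- #
def update_pwm(
    library: ReadLibrary,
    model: EnergyModel,
    _weights: tuple[np.ndarray, np.ndarray] | None = None,
) -> Pwm:
    """Responsibility-weighted PWM re-estimation.

    Each window s of read S contributes
    n_S e^{E(s)} / (e^{E(S)} + (L_S - Lw + 1) e^{E0}) to the four-column
    rows it overlaps; rows are then renormalized with the entry floor.
    """
    lw = model.lw
    accum = np.zeros((lw, 4))
    for L, (idx, mat) in library.by_length().items():
        scores = window_log_scores(model.pwm, mat)
        log_w = _total_log_weights(
            logsumexp(scores, axis=1), np.full(len(idx), L - lw + 1.0), model.e0
        )
        ok = np.isfinite(log_w)
        with np.errstate(invalid="ignore"):
            weights = np.where(
                ok[:, None], library.counts[idx, None] * np.exp(scores - log_w[:, None]), 0.0
            )
        n_win = L - lw + 1
        for i in range(lw):
            np.add.at(accum[i], mat[:, i : i + n_win].ravel(), weights.ravel())
    return Pwm(accum, floor=model.pwm.floor)


# ---------------------------------------------------------------------- #
def fit_em(
    library: ReadLibrary,
    lw: int,
    init_mode: str = "random",
    consensus: str | None = None,
    consensus_weight: float = 0.7,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
    e0_bracket: tuple[float, float] = DEFAULT_E0_BRACKET,
    floor: float = DEFAULT_FLOOR,
) -> FitResult:
    """Run one EM fit of (PWM, E0) on an annotated library.

    Reads shorter than ``lw`` are dropped (logged). Convergence requires the
    summed squared PWM change to fall below lw * 4 * tol.
    """
    if not library.annotated:
        raise ValueError("library has no frequency priors")
    lib = library.filter_min_length(lw)
    mean_len = float(np.dot(lib.lengths, lib.counts) / lib.total_count)
    model = init_model(
        lw, init_mode, consensus=consensus, seed=seed,
        mean_read_length=mean_len, consensus_weight=consensus_weight, floor=floor,
    )
    initial_ll = log_likelihood(lib, model)
    if not np.isfinite(initial_ll):
        raise RuntimeError("non-finite initial log-likelihood; check priors and floor")
    trace = [initial_ll]
    pwm, e0 = model.pwm, model.e0
    threshold = lw * 4 * tol
    reached_tol = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        weights = library_log_weights(lib, pwm)
        e0 = optimize_e0(lib, pwm, bracket=e0_bracket, _weights=weights)
        new_pwm = update_pwm(lib, EnergyModel(pwm, e0), _weights=weights)
        delta_sq = float(((new_pwm.matrix - pwm.matrix) ** 2).sum())
        pwm = new_pwm
        ll = log_likelihood(lib, EnergyModel(pwm, e0))
        if not np.isfinite(ll):
            raise RuntimeError(f"non-finite log-likelihood at iteration {n_iter}")
        trace.append(ll)
        if delta_sq < threshold:
            reached_tol = True
            break
    final_model = EnergyModel(pwm, e0)
    final_ll = trace[-1]
    return FitResult(
        model=final_model,
        lw=lw,
        init_mode=init_mode,
        seed=seed,
        loglik_trace=trace,
        initial_loglik=initial_ll,
        final_loglik=final_ll,
        iterations=n_iter,
        convergent=final_ll > initial_ll,
        specific=final_model.e0 < 0,
        reached_tol=reached_tol,
    )


# ---------------------------------------------------------------------- #
def classify_runs(results: list[FitResult]) -> dict:
    """Pool runs (across Lw values) into convergent / specific fractions."""
    if not results:
        raise ValueError("no runs to classify")
    n = len(results)
    n_conv = sum(r.convergent for r in results)
    n_conv_spec = sum(r.convergent and r.specific for r in results)
    return {
        "n_runs": n,
        "n_convergent": n_conv,
        "n_convergent_specific": n_conv_spec,
        "frac_convergent": n_conv / n,
        "frac_convergent_specific": n_conv_spec / n,
    }


def select_best(results: list[FitResult]) -> FitResult | None:
    """Best convergent & specific run: highest final log-likelihood, ties
    (within 1e-6) broken by lower E0, then by seed."""
    good = [r for r in results if r.convergent and r.specific]
    if not good:
        return None
    best = good[0]
    for r in good[1:]:
        if r.final_loglik > best.final_loglik + 1e-6:
            best = r
        elif abs(r.final_loglik - best.final_loglik) <= 1e-6:
            if (r.model.e0, r.seed) < (best.model.e0, best.seed):
                best = r
    return best


def best_shift_tv(pwm_a: Pwm, pwm_b: Pwm, max_shift: int | None = None) -> tuple[float, int]:
    """Mean per-position total-variation distance, minimized over shifts.

    EM solutions are phase-degenerate (shifted motifs score alike), so
    recovered matrices are compared to the truth at the best relative
    offset; the distance averages 0.5 * sum |diff| over overlapping
    positions. Returns (distance, shift).
    """
    la, lb = pwm_a.length, pwm_b.length
    if max_shift is None:
        max_shift = max(la, lb) - 1
    best = (np.inf, 0)
    for shift in range(-max_shift, max_shift + 1):
        a_lo, b_lo = max(0, shift), max(0, -shift)
        n = min(la - a_lo, lb - b_lo)
        if n < 1:
            continue
        diff = pwm_a.matrix[a_lo : a_lo + n] - pwm_b.matrix[b_lo : b_lo + n]
        tv = float(0.5 * np.abs(diff).sum(axis=1).mean())
        if tv < best[0]:
            best = (tv, shift)
    return best
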