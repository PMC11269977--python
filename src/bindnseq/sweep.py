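"""Sweep orchestration: many EM runs across site lengths and restarts.

A sweep mirrors the standard run design for one RBP library pair: for each
site length Lw in a range (default 5..15), a batch of randomly initialized
EM runs (default 16) plus optionally a few consensus-seeded runs (default
4), each with a per-run seed that is a pure function of the base seed, the
Lw and the run index — re-running a sweep reproduces every row exactly.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .affinity import DEFAULT_LW_REF, log_relative_kd
from .background import MarkovBackground, annotate_priors, train_markov
from .em import DEFAULT_MAX_ITER, DEFAULT_TOL, FitResult, classify_runs, fit_em, select_best
from .io import write_pwm_meme, write_pwm_tsv, write_results_tsv
from .library import ReadLibrary

logger = logging.getLogger(__name__)


@dataclass
class SweepConfig:
    lw_min: int = 5
    lw_max: int = 15
    n_random: int = 16
    n_consensus: int = 4
    consensus: str | None = None
    tol: float = DEFAULT_TOL
    max_iter: int = DEFAULT_MAX_ITER
    base_seed: int = 0
    lw_ref: int = DEFAULT_LW_REF
    markov_degree: int = 4
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not (1 <= self.lw_min <= self.lw_max):
            raise ValueError("need 1 <= lw_min <= lw_max")
        if self.consensus is None:
            self.n_consensus = 0


def _safe(fn, plan):
    try:
        return fn(plan)
    except Exception:
        logger.exception("run failed: lw=%d mode=%s idx=%d", *plan)
        return None


def run_seed(base_seed: int, lw: int, run_index: int) -> int:
    """Deterministic per-run seed; pure function of its arguments."""
    return (base_seed * 1_000_003 + lw * 1_009 + run_index * 7) % (2**31 - 1)


def run_sweep(
    foreground: ReadLibrary,
    background: ReadLibrary | MarkovBackground,
    config: SweepConfig,
    out_dir: str | Path | None = None,
    rbp_label: str = "sample",
    threads: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Execute the full (Lw x init) grid of EM fits.

    Returns the per-run results table and a summary dict (pooled
    convergent/specific fractions plus the best run per the ranking rule).
    Per-run failures are logged and excluded from the summary. Runs are
    independent; with ``threads`` > 1 they execute concurrently and results
    are identical to the sequential order.
    """
    if isinstance(background, MarkovBackground):
        bg_model = background
    else:
        bg_model = train_markov(background, config.markov_degree, config.pseudocount)
    fg = annotate_priors(bg_model, foreground)

    max_lw = min(config.lw_max, int(fg.lengths.max()))
    if max_lw < config.lw_max:
        logger.warning("capping lw_max at longest read length %d", max_lw)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    plans = [
        (lw, mode, idx)
        for lw in range(config.lw_min, max_lw + 1)
        for mode, idx in (
            [("random", i) for i in range(config.n_random)]
            + [("consensus", config.n_random + i) for i in range(config.n_consensus)]
        )
    ]

    def one_run(plan):
        lw, mode, idx = plan
        seed = run_seed(config.base_seed, lw, idx)
        fit = fit_em(
            fg, lw, init_mode=mode, consensus=config.consensus,
            tol=config.tol, max_iter=config.max_iter, seed=seed,
        )
        return seed, fit

    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            outcomes = list(pool.map(lambda p: _safe(one_run, p), plans))
    else:
        outcomes = [_safe(one_run, p) for p in plans]

    rows: list[dict] = []
    results: list[FitResult] = []
    n_failed = 0
    for (lw, mode, idx), outcome in zip(plans, outcomes):
        if outcome is None:
            n_failed += 1
            continue
        seed, fit = outcome
        if fit.convergent and fit.specific:
            fit.log_kd_rel = log_relative_kd(fit, fg, config.lw_ref).log_kd_rel
        results.append(fit)
        pwm_path = ""
        if out_dir is not None:
            stem = f"{rbp_label}_lw{lw}_{mode}_{idx}"
            write_pwm_tsv(out_dir / f"{stem}.pwm.tsv", fit.model.pwm)
            write_pwm_meme(out_dir / f"{stem}.meme", fit.model.pwm, name=stem)
            pwm_path = f"{stem}.pwm.tsv"
        rows.append(
            {
                "rbp_label": rbp_label, "lw": lw, "init_mode": mode, "seed": seed,
                "iterations": fit.iterations,
                "initial_loglik": fit.initial_loglik,
                "final_loglik": fit.final_loglik,
                "e0": fit.model.e0,
                "convergent": fit.convergent, "specific": fit.specific,
                "log_kd_rel": fit.log_kd_rel, "pwm_path": pwm_path,
            }
        )
    if not results:
        raise RuntimeError("all sweep runs failed")
    summary = classify_runs(results)
    summary["n_failed"] = n_failed
    best = select_best(results)
    summary["best"] = best
    if best is not None:
        summary["best_consensus"] = best.model.pwm.consensus
        summary["best_log_kd_rel"] = best.log_kd_rel
    if out_dir is not None:
        table = write_results_tsv(out_dir / f"{rbp_label}_results.tsv", rows)
        if best is not None:
            write_pwm_meme(out_dir / f"{rbp_label}_best.meme", best.model.pwm, name="best")
            write_pwm_tsv(out_dir / f"{rbp_label}_best.pwm.tsv", best.model.pwm)
    else:
        table = pd.DataFrame(rows)
    return table, summary
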