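"""Model/Results front end.

:class:`BindnSeqModel` bundles a foreground (selected) pool, a background
(input) pool and the modelling choices — site length Lw, Markov background
order, PWM entry floor — into a single object whose :meth:`~BindnSeqModel.fit`
runs one or several EM restarts and returns a :class:`BindnSeqResults`
carrying the fitted PWM, the unspecific log-weight E0, the log-likelihood
trace, the convergent/specific diagnostics and the relative dissociation
constant, with a ``summary()`` table in the style of statistical modelling
packages.

    >>> model = BindnSeqModel(fg_reads, bg_reads, site_length=6)
    >>> res = model.fit(n_restarts=8, seed=0)
    >>> print(res.summary())
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .affinity import DEFAULT_LW_REF, log_relative_kd
from .background import MarkovBackground, annotate_priors, train_markov
from .em import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    FitResult,
    classify_runs,
    fit_em,
    select_best,
)
from .library import ReadLibrary


class BindnSeqModel:
    """Thermodynamic PWM model of one selected/input read-pool pair.

    Parameters
    ----------
    foreground, background
        Read pools as :class:`ReadLibrary` or iterables of A/C/G/T strings.
        The background pool trains the order-``markov_degree`` frequency
        prior; alternatively pass a pre-trained :class:`MarkovBackground`.
    site_length
        Binding-site length Lw of the PWM to infer.
    markov_degree, pseudocount
        Background chain order (default 4) and Laplace pseudocount.
    lw_ref
        Site length of the uniform no-unspecific-binding reference used for
        relative K_D values (default 5).
    """

    def __init__(
        self,
        foreground: Iterable[str] | ReadLibrary,
        background: Iterable[str] | ReadLibrary | MarkovBackground,
        site_length: int = 6,
        markov_degree: int = 4,
        pseudocount: float = 1.0,
        lw_ref: int = DEFAULT_LW_REF,
    ):
        if not isinstance(foreground, ReadLibrary):
            foreground = ReadLibrary.from_reads(foreground)
        if isinstance(background, MarkovBackground):
            self.background_model = background
        else:
            self.background_model = train_markov(background, markov_degree, pseudocount)
        self.site_length = int(site_length)
        self.lw_ref = lw_ref
        self.library = annotate_priors(self.background_model, foreground)

    def fit(
        self,
        init: str = "random",
        consensus: str | None = None,
        n_restarts: int = 8,
        seed: int = 0,
        tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER,
    ) -> "BindnSeqResults":
        """Run ``n_restarts`` independent EM fits and keep them all.

        Restart r uses seed ``seed + r``. The best convergent & specific
        run (highest final log-likelihood) becomes the headline result.
        """
        fits = []
        for r in range(n_restarts):
            fit = fit_em(
                self.library, self.site_length, init_mode=init, consensus=consensus,
                tol=tol, max_iter=max_iter, seed=seed + r,
            )
            if fit.convergent and fit.specific:
                fit.log_kd_rel = log_relative_kd(fit, self.library, self.lw_ref).log_kd_rel
            fits.append(fit)
        return BindnSeqResults(self, fits)


class BindnSeqResults:
    """Results of one or more EM restarts on a :class:`BindnSeqModel`."""

    def __init__(self, model: BindnSeqModel, fits: list[FitResult]):
        self.model = model
        self.fits = fits
        self.best: FitResult | None = select_best(fits)
        # fall back to the highest-likelihood run for inspection even when
        # nothing is convergent & specific
        self._headline = self.best or max(fits, key=lambda f: f.final_loglik)

    # headline accessors -------------------------------------------------
    @property
    def pwm(self):
        return self._headline.model.pwm

    @property
    def e0(self) -> float:
        return self._headline.model.e0

    @property
    def consensus(self) -> str:
        return self.pwm.consensus

    @property
    def log_kd_rel(self) -> float | None:
        return self._headline.log_kd_rel

    @property
    def converged(self) -> bool:
        return self._headline.reached_tol

    @property
    def specific(self) -> bool:
        return self._headline.specific

    @property
    def loglik(self) -> float:
        return self._headline.final_loglik

    def pwm_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pwm.matrix, columns=list("ACGT"),
            index=pd.RangeIndex(1, self.pwm.length + 1, name="position"),
        )

    def runs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "seed": [f.seed for f in self.fits],
                "init_mode": [f.init_mode for f in self.fits],
                "iterations": [f.iterations for f in self.fits],
                "initial_loglik": [f.initial_loglik for f in self.fits],
                "final_loglik": [f.final_loglik for f in self.fits],
                "e0": [f.model.e0 for f in self.fits],
                "convergent": [f.convergent for f in self.fits],
                "specific": [f.specific for f in self.fits],
                "log_kd_rel": [f.log_kd_rel for f in self.fits],
            }
        )

    def classification(self) -> dict:
        return classify_runs(self.fits)

    # --------------------------------------------------------------------
    def summary(self) -> str:
        cls = self.classification()
        h = self._headline
        lib = self.model.library
        lines = [
            "         Bind'n-Seq thermodynamic PWM fit",
            "=" * 58,
            f"Distinct reads:        {len(lib):>12d}",
            f"Total reads:           {lib.total_count:>12d}",
            f"Site length Lw:        {self.model.site_length:>12d}",
            f"Background order d:    {self.model.background_model.degree:>12d}",
            f"Restarts:              {len(self.fits):>12d}"
            f"   (convergent: {cls['n_convergent']}, specific: {cls['n_convergent_specific']})",
            "-" * 58,
            f"Best run seed:         {h.seed:>12d}   ({h.init_mode} init)",
            f"Iterations:            {h.iterations:>12d}",
            f"Log-likelihood:        {h.final_loglik:>12.4f}   (initial {h.initial_loglik:.4f})",
            f"E0 (unspecific):       {h.model.e0:>12.4f}",
            f"Consensus:             {self.consensus:>12s}",
        ]
        if h.log_kd_rel is not None:
            lines.append(
                f"log K_D (rel, Lw_ref={self.model.lw_ref}): {h.log_kd_rel:>7.4f}"
            )
        if self.best is None:
            lines.append("note: no convergent & specific run; showing best likelihood")
        lines.append("-" * 58)
        lines.append("PWM (rows = positions, columns = A C G T):")
        with pd.option_context("display.float_format", "{:.3f}".format):
            lines.append(self.pwm_frame().to_string())
        return "\n".join(lines)

    def plot_trace(self, ax=None):
        """Log-likelihood traces of all restarts (best run highlighted)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for f in self.fits:
            kw = {"color": "C1", "lw": 2} if f is self._headline else {"color": "0.7", "lw": 1}
            ax.plot(f.loglik_trace, **kw)
        ax.set_xlabel("EM iteration")
        ax.set_ylabel("log-likelihood")
        return ax
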