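"""Relative dissociation constants.

In the unsaturated, low-affinity regime the data log-likelihood of a fitted
model and the dissociation constant K_D of the binding reaction are related
up to constants that cancel when two models are compared on the same
library. Taking as reference a uniform PWM of length Lw_ref = 5 (a typical
RBP site size) with no unspecific binding (E0 -> -inf), whose likelihood
has the closed form

    logP_ref = sum_S n_S log[ f_S (L_S - Lw_ref + 1) / Z_ref ],

the log relative dissociation constant of a fit is

    log(K_D / K_D^ref) = [ logP_ref - logP_fit
                           + sum_S n_S log((L_S - Lw + 1)/(L_S - Lw_ref + 1)) ]
                         / sum_S n_S.

Division by the total read count removes the library-size dependence, and
the window-count term corrects for site/read-length differences, so
estimates at different Lw on the same library are directly comparable:
lower log K_D rel means higher affinity. Natural logs throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .em import FitResult
from .library import ReadLibrary

DEFAULT_LW_REF = 5


@dataclass
class KdEstimate:
    """log(K_D / K_D^ref) for one fit, natural-log scale."""

    log_kd_rel: float
    lw_ref: int
    fit: FitResult | None = None


def reference_loglik(library: ReadLibrary, lw_ref: int = DEFAULT_LW_REF) -> float:
    """Closed-form log-likelihood of the uniform length-``lw_ref`` reference.

    Equals the general log-likelihood with a uniform PWM of that length and
    E0 -> -inf (the constant 4^-lw_ref site factor cancels in the ratio).
    """
    if not library.annotated:
        raise ValueError("library has no frequency priors")
    lengths = library.lengths
    if (lengths < lw_ref).any():
        raise ValueError(f"all read lengths must be >= lw_ref={lw_ref}")
    counts = library.counts.astype(float)
    log_num = library.log_priors + np.log(lengths - lw_ref + 1.0)
    log_z = logsumexp(log_num)
    return float(np.dot(counts, log_num - log_z))


def log_relative_kd(
    fit: FitResult, library: ReadLibrary, lw_ref: int = DEFAULT_LW_REF
) -> KdEstimate:
    """Relative dissociation constant of a fitted model on its library.

    ``library`` must be the annotated library the fit was run on, restricted
    to reads of length >= fit.lw (as fit_em does internally).
    """
    lib = library.filter_min_length(fit.lw)
    lengths = lib.lengths
    counts = lib.counts.astype(float)
    n_total = counts.sum()
    ref_ll = reference_loglik(lib, lw_ref)
    length_term = float(
        np.dot(counts, np.log((lengths - fit.lw + 1.0) / (lengths - lw_ref + 1.0)))
    )
    value = (ref_ll - fit.final_loglik + length_term) / n_total
    return KdEstimate(log_kd_rel=float(value), lw_ref=lw_ref, fit=fit)


def rank_motifs(estimates: list[KdEstimate]) -> list[KdEstimate]:
    """Ascending by log K_D rel (highest affinity first); stable for ties."""
    if not estimates:
        raise ValueError("no estimates to rank")
    return sorted(estimates, key=lambda e: e.log_kd_rel)
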