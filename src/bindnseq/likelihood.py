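"""Thermodynamic binding model: Boltzmann weights and the data likelihood.

An RBP binds a site s of length Lw with Boltzmann weight
e^{E(s)} = prod_i m_{i, s_i}, where the position weight matrix entries
m_{i,alpha} = exp(E_{i,alpha}) are per-position probabilities. A read S
offers L_S - Lw + 1 contiguous sites plus a sequence-unspecific binding
mode of log-weight E0 per configuration, so its total weight is

    W_S = e^{E(S)} + (L_S - Lw + 1) e^{E0},   e^{E(S)} = sum_{s in S} e^{E(s)}.

In the unsaturated (linear) regime the probability that a sequenced
(selected) read is S is f_S W_S / sum_sigma f_sigma W_sigma — the protein
concentration cancels — and the data log-likelihood is the count-weighted
sum of the log selection probabilities. Everything here is accumulated in
natural-log space with log-sum-exp to avoid underflow at realistic library
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .library import ReadLibrary, encode

#: default floor applied to PWM entries at normalization time, keeping the
#: log-likelihood finite during EM
DEFAULT_FLOOR = 1e-9


class Pwm:
    """Position weight matrix: per-position nucleotide probabilities.

    Rows are positions 1..Lw, columns are A, C, G, T. Each row sums to 1;
    entries are floored at ``floor`` (applied at normalization) so that log
    weights stay finite. ``floor=0`` permits exact one-hot matrices.
    """

    def __init__(self, matrix, floor: float = DEFAULT_FLOOR, normalize: bool = True):
        m = np.array(matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM must have shape (Lw, 4)")
        if (m < 0).any() or not np.isfinite(m).all():
            raise ValueError("PWM entries must be finite and non-negative")
        if normalize:
            row_sums = m.sum(axis=1, keepdims=True)
            zero = row_sums[:, 0] == 0
            m[zero] = 0.25
            row_sums[zero] = 1.0
            m = m / row_sums
            if floor > 0:
                m = np.clip(m, floor, None)
                m = m / m.sum(axis=1, keepdims=True)
        else:
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("PWM rows must sum to 1")
        self.matrix = m
        self.floor = floor
        with np.errstate(divide="ignore"):
            self.log_matrix = np.log(m)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        """Argmax base at each position."""
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    def __repr__(self) -> str:
        return f"Pwm(Lw={self.length}, consensus={self.consensus})"

    @classmethod
    def uniform(cls, length: int, floor: float = DEFAULT_FLOOR) -> "Pwm":
        return cls(np.full((length, 4), 0.25), floor=floor)

    @classmethod
    def one_hot(cls, motif: str, floor: float = 0.0) -> "Pwm":
        m = np.zeros((len(motif), 4))
        m[np.arange(len(motif)), encode(motif)] = 1.0
        return cls(m, floor=floor)

    @classmethod
    def from_consensus(
        cls, motif: str, length: int | None = None, weight: float = 0.7,
        floor: float = DEFAULT_FLOOR,
    ) -> "Pwm":
        """Polarized PWM: consensus base gets ``weight``, others split the rest.

        A motif shorter than ``length`` is centered with uniform flanks.
        """
        length = length if length is not None else len(motif)
        if len(motif) > length:
            raise ValueError("motif longer than requested PWM length")
        m = np.full((length, 4), 0.25)
        offset = (length - len(motif)) // 2
        rest = (1.0 - weight) / 3.0
        for i, b in enumerate(encode(motif)):
            m[offset + i] = rest
            m[offset + i, b] = weight
        return cls(m, floor=floor)


@dataclass
class EnergyModel:
    """A PWM paired with the unspecific-binding log-weight E0 in (-inf, 0]."""

    pwm: Pwm
    e0: float

    def __post_init__(self) -> None:
        if not (self.e0 <= 0.0):  # NaN also rejected
            raise ValueError("E0 must lie in (-inf, 0]")

    @property
    def lw(self) -> int:
        return self.pwm.length


# ---------------------------------------------------------------------- #
# Site and read weights
# ---------------------------------------------------------------------- #
def log_site_weight(pwm: Pwm, site: str) -> float:
    codes = encode(site)
    if len(codes) != pwm.length:
        raise ValueError(f"site length {len(codes)} != Lw {pwm.length}")
    return float(pwm.log_matrix[np.arange(pwm.length), codes].sum())


def site_weight(pwm: Pwm, site: str) -> float:
    """Boltzmann weight e^{E(s)} = prod_i m_{i, s_i} of one Lw-mer."""
    return float(np.exp(log_site_weight(pwm, site)))


def window_log_scores(pwm: Pwm, mat: np.ndarray) -> np.ndarray:
    """Log site weights for all windows of equal-length encoded reads.

    ``mat`` is (n, L) int8; returns (n, L - Lw + 1).
    """
    lw = pwm.length
    n, L = mat.shape
    if L < lw:
        raise ValueError(f"read length {L} shorter than Lw {lw}")
    n_win = L - lw + 1
    scores = np.zeros((n, n_win))
    logm = pwm.log_matrix
    for i in range(lw):
        scores += logm[i, mat[:, i : i + n_win]]
    return scores


def log_read_weight(pwm: Pwm, read: str) -> float:
    mat = encode(read)[None, :]
    return float(logsumexp(window_log_scores(pwm, mat), axis=1)[0])


def read_weight(pwm: Pwm, read: str) -> float:
    """Specific weight e^{E(S)}: sum of site weights over all windows."""
    return float(np.exp(log_read_weight(pwm, read)))


def library_log_weights(library: ReadLibrary, pwm: Pwm) -> tuple[np.ndarray, np.ndarray]:
    """Per-read (log e^{E(S)}, window count L_S - Lw + 1) for a whole library.

    Reads shorter than Lw raise; filter them out first.
    """
    log_e = np.empty(len(library))
    n_win = np.empty(len(library))
    for L, (idx, mat) in library.by_length().items():
        scores = window_log_scores(pwm, mat)  # raises if L < Lw
        log_e[idx] = logsumexp(scores, axis=1)
        n_win[idx] = L - pwm.length + 1
    return log_e, n_win


def _total_log_weights(log_e: np.ndarray, n_win: np.ndarray, e0: float) -> np.ndarray:
    """log W_S = log(e^{E(S)} + (L_S - Lw + 1) e^{E0}), -inf-safe."""
    if e0 == -np.inf:
        return log_e
    return np.logaddexp(log_e, e0 + np.log(n_win))


# ---------------------------------------------------------------------- #
# Probabilities
# ---------------------------------------------------------------------- #
def bound_probability(
    read: str, c: float, model: EnergyModel, linearized: bool = False
) -> float:
    """Probability that the RBP is bound somewhere on ``read``.

    Full form: cW / (1 + cW) with W = e^{E(S)} + (L_S - Lw + 1) e^{E0};
    linearized form: cW, valid in the unsaturated regime cW << 1.
    """
    if c < 0:
        raise ValueError("concentration must be >= 0")
    lw = model.lw
    log_e = log_read_weight(model.pwm, read)
    log_w = _total_log_weights(
        np.array([log_e]), np.array([len(read) - lw + 1.0]), model.e0
    )[0]
    if c == 0:
        return 0.0
    log_cw = np.log(c) + log_w
    if linearized:
        return float(np.exp(log_cw))
    # cW/(1+cW) = sigmoid(log cW)
    return float(1.0 / (1.0 + np.exp(-log_cw)))


def log_selection_probabilities(library: ReadLibrary, model: EnergyModel) -> np.ndarray:
    """Log P(selected read = S) for every distinct read in the library.

    P(S) = f_S W_S / sum_sigma f_sigma W_sigma; the denominator runs over
    distinct reads weighted by their priors (not copy numbers).
    """
    if not library.annotated:
        raise ValueError("library has no frequency priors; run annotate_priors first")
    log_e, n_win = library_log_weights(library, model.pwm)
    log_w = _total_log_weights(log_e, n_win, model.e0)
    log_num = library.log_priors + log_w
    log_z = logsumexp(log_num)
    if np.isneginf(log_z):
        return np.full(len(library), -np.inf)
    return log_num - log_z


def selection_probability(read: str, library: ReadLibrary, model: EnergyModel) -> float:
    """Selection probability of one read that is a member of ``library``."""
    try:
        i = library.sequences.index(read)
    except ValueError as exc:
        raise ValueError("read not in library") from exc
    return float(np.exp(log_selection_probabilities(library, model)[i]))


def log_likelihood(library: ReadLibrary, model: EnergyModel) -> float:
    """Data log-likelihood: sum_S n_S log P(selected = S).

    Returns -inf (not an error) when some read has zero total weight under a
    floor-0 PWM with E0 = -inf.
    """
    log_p = log_selection_probabilities(library, model)
    counts = library.counts.astype(float)
    if np.isneginf(log_p).any():
        if (counts[np.isneginf(log_p)] > 0).any():
            return -np.inf
    return float(np.dot(counts, log_p))
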