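"""Order-d Markov background model and frequency priors.

The unselected (input) pool of a Bind'n-Seq experiment is not a uniform
random oligomer soup: synthesis, capture and sequencing biases skew the
nucleotide composition (the input pools this package targets are typically
A-rich). Because 4^20 possible 20-mers vastly outnumber the ~1e7 reads of a
library, a foreground read is almost never observed in the background pool,
so its expected unselected frequency f_S must be *predicted*. We do this
with an order-d Markov chain trained on the background pool: the prior of a
read is the probability of its leading d-mer times the product of the
base-given-context transition probabilities along the read.

f_S enters the selection likelihood only through the ratio
f_S W_S / sum_sigma f_sigma W_sigma, so any global rescaling of the priors
cancels; priors are stored as raw chain probabilities (normalized over all
sequences of each fixed length) and a pool-level rescale is available as an
explicit option.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .library import ALPHABET, ReadLibrary, encode

logger = logging.getLogger(__name__)

#: refuse to allocate transition tables with more contexts than this
MAX_CONTEXTS = 4**10


def _context_strings(degree: int) -> list[str]:
    if degree == 0:
        return [""]
    out = [""]
    for _ in range(degree):
        out = [s + b for s in out for b in ALPHABET]
    return out


@dataclass
class MarkovBackground:
    """Order-``degree`` Markov chain over A/C/G/T.

    Parameters
    ----------
    degree
        Order d of the chain; d=0 is a positionless base-composition model.
    initial_dist
        Probability of each of the 4^d leading d-mers (a single 1.0 for d=0).
    transitions
        (4^d, 4) matrix; row k is P(base | context k). Contexts are encoded
        base-4 with A=0..T=3, most significant digit first.
    pseudocount
        Laplace pseudocount per (context, base) cell used at training time;
        a positive value guarantees strictly positive priors for unseen
        contexts.
    """

    degree: int
    initial_dist: np.ndarray
    transitions: np.ndarray
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.initial_dist = np.asarray(self.initial_dist, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        n_ctx = 4**self.degree
        if self.initial_dist.shape != (n_ctx,):
            raise ValueError("initial_dist has wrong shape")
        if self.transitions.shape != (n_ctx, 4):
            raise ValueError("transitions has wrong shape")
        if not np.isclose(self.initial_dist.sum(), 1.0, atol=1e-12):
            raise ValueError("initial_dist must sum to 1")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each transition row must sum to 1")

    # ------------------------------------------------------------------ #
    @property
    def n_contexts(self) -> int:
        return 4**self.degree

    def _initial_codes(self, mat: np.ndarray) -> np.ndarray:
        c = np.zeros(mat.shape[0], dtype=np.int64)
        for i in range(self.degree):
            c = c * 4 + mat[:, i]
        return c

    def _context_codes(self, mat: np.ndarray) -> np.ndarray:
        """Rolling context codes for an (n, L) encoded read matrix.

        Returns (n, L-d) codes; column j is the code of the d-mer made of
        bases [j, j+d), i.e. the context of the base emitted at position d+j.
        """
        d = self.degree
        n, L = mat.shape
        n_emit = L - d
        codes = np.zeros((n, n_emit), dtype=np.int64)
        if d == 0 or n_emit == 0:
            return codes
        c = self._initial_codes(mat)
        codes[:, 0] = c
        mod = 4 ** (d - 1)
        for j in range(1, n_emit):
            c = (c % mod) * 4 + mat[:, d + j - 1]
            codes[:, j] = c
        return codes

    def log_prior(self, sequence: str) -> float:
        """Natural-log prior probability of a single sequence."""
        return float(self.log_priors_matrix(encode(sequence)[None, :])[0])

    def sequence_prior(self, sequence: str) -> float:
        """Prior probability of ``sequence`` under the chain.

        Summed over all 4^L sequences of any fixed length L >= degree the
        priors add to 1.
        """
        return float(np.exp(self.log_prior(sequence)))

    def log_priors_matrix(self, mat: np.ndarray) -> np.ndarray:
        """Vectorized log priors for equal-length encoded reads (n, L)."""
        d = self.degree
        n, L = mat.shape
        if L < d or (d == 0 and L < 1):
            raise ValueError(f"sequence length {L} shorter than model degree {d}")
        with np.errstate(divide="ignore"):
            log_init = np.log(self.initial_dist)
            log_trans = np.log(self.transitions)
        if d == 0:
            lp = log_trans[np.zeros_like(mat, dtype=np.int64), mat].sum(axis=1)
        else:
            lp = log_init[self._initial_codes(mat)]
            if L > d:
                codes = self._context_codes(mat)
                lp = lp + log_trans[codes, mat[:, d:]].sum(axis=1)
        return lp

    # ------------------------------------------------------------------ #
    def sample(self, n_reads: int, length: int, rng: np.random.Generator) -> list[str]:
        """Draw ``n_reads`` i.i.d. reads of ``length`` nt from the chain."""
        if length < max(self.degree, 1):
            raise ValueError("read length shorter than model degree")
        d = self.degree
        mat = np.empty((n_reads, length), dtype=np.int8)
        if d > 0:
            ctx = rng.choice(self.n_contexts, size=n_reads, p=self.initial_dist)
            for i in range(d - 1, -1, -1):
                mat[:, i] = ctx % 4
                ctx //= 4
        # rebuild rolling codes while sampling
        c = np.zeros(n_reads, dtype=np.int64)
        for i in range(d):
            c = c * 4 + mat[:, i]
        cum = np.cumsum(self.transitions, axis=1)
        mod = 4 ** (d - 1) if d > 0 else 1
        for j in range(d, length):
            u = rng.random(n_reads)
            mat[:, j] = (u[:, None] > cum[c]).sum(axis=1)
            if d > 0:
                c = (c % mod) * 4 + mat[:, j]
        return ["".join(ALPHABET[b] for b in row) for row in mat]

    # ------------------------------------------------------------------ #
    def to_json(self) -> str:
        ctx = _context_strings(self.degree)
        obj = {
            "degree": self.degree,
            "pseudocount": self.pseudocount,
            "initial_dist": dict(zip(ctx, self.initial_dist.tolist())),
            "transitions": {
                c: dict(zip(ALPHABET, row)) for c, row in zip(ctx, self.transitions.tolist())
            },
        }
        return json.dumps(obj, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MarkovBackground":
        obj = json.loads(text)
        d = int(obj["degree"])
        ctx = _context_strings(d)
        init = np.array([obj["initial_dist"][c] for c in ctx])
        trans = np.array([[obj["transitions"][c][b] for b in ALPHABET] for c in ctx])
        return cls(d, init, trans, float(obj["pseudocount"]))

    @classmethod
    def uniform(cls, degree: int = 0) -> "MarkovBackground":
        n_ctx = 4**degree
        return cls(degree, np.full(n_ctx, 1.0 / n_ctx), np.full((n_ctx, 4), 0.25))

    @classmethod
    def from_base_frequencies(cls, freqs) -> "MarkovBackground":
        """Degree-0 model from a length-4 base frequency vector (A,C,G,T)."""
        f = np.asarray(freqs, dtype=float)
        if f.shape != (4,) or (f < 0).any():
            raise ValueError("need 4 non-negative base frequencies")
        f = f / f.sum()
        return cls(0, np.array([1.0]), f[None, :])


# ---------------------------------------------------------------------- #
def train_markov(
    background_reads: Iterable[str] | ReadLibrary,
    degree: int = 4,
    pseudocount: float = 1.0,
) -> MarkovBackground:
    """Train an order-``degree`` Markov model on the background pool.

    Transition probabilities are Laplace-smoothed relative frequencies:
    P(b | x) = (count(x->b) + pc) / (count(x->.) + 4 pc), and analogously
    for the distribution of the leading d-mer. Reads are weighted by their
    copy number when a :class:`ReadLibrary` is passed.
    """
    if degree < 0:
        raise ValueError("degree must be >= 0")
    if 4**degree > MAX_CONTEXTS:
        raise ValueError(
            f"degree {degree} implies 4^{degree} contexts, above the cap of "
            f"{MAX_CONTEXTS}; use a lower degree"
        )
    if not isinstance(background_reads, ReadLibrary):
        background_reads = ReadLibrary.from_reads(background_reads)
    lib = background_reads
    n_ctx = 4**degree
    init_counts = np.zeros(n_ctx, dtype=float)
    trans_counts = np.zeros((n_ctx, 4), dtype=float)
    helper = MarkovBackground.uniform(degree)  # for context-code rolling only
    any_used = False
    for L, (idx, mat) in lib.by_length().items():
        if L <= degree:
            logger.warning("skipping %d reads of length %d <= degree %d", len(idx), L, degree)
            continue
        any_used = True
        w = lib.counts[idx].astype(float)
        codes = helper._context_codes(mat)
        np.add.at(init_counts, helper._initial_codes(mat), w)
        # context codes[:, j] emits base mat[:, degree + j]
        nxt = mat[:, degree:]
        wrep = np.broadcast_to(w[:, None], nxt.shape)
        np.add.at(trans_counts, (codes.ravel(), nxt.ravel()), wrep.ravel())
    if not any_used:
        raise ValueError(f"no reads longer than degree {degree}")
    init = init_counts + pseudocount
    init /= init.sum()
    trans = trans_counts + pseudocount
    row_sums = trans.sum(axis=1, keepdims=True)
    if pseudocount == 0:
        # avoid 0/0 for unseen contexts: leave them uniform
        unseen = row_sums[:, 0] == 0
        trans[unseen] = 0.25
        row_sums = trans.sum(axis=1, keepdims=True)
    trans /= row_sums
    if pseudocount == 0 and init_counts.sum() > 0:
        init = init_counts / init_counts.sum()
    return MarkovBackground(degree, init, trans, pseudocount)


def annotate_priors(
    model: MarkovBackground,
    library: ReadLibrary,
    rescale: float | None = None,
) -> ReadLibrary:
    """Return a copy of ``library`` with f_S set from the background model.

    Reads shorter than the model degree are skipped with a warning (their
    prior is left as -inf and they should be length-filtered downstream).
    ``rescale`` multiplies every prior by a constant; the selection
    likelihood is invariant to this choice.
    """
    log_priors = np.full(len(library), -np.inf)
    n_skipped = 0
    for L, (idx, mat) in library.by_length().items():
        if L < max(model.degree, 1):
            n_skipped += len(idx)
            continue
        log_priors[idx] = model.log_priors_matrix(mat)
    if n_skipped:
        logger.warning("annotate_priors: skipped %d reads shorter than degree", n_skipped)
    if n_skipped == len(library):
        raise ValueError("all reads shorter than the model degree")
    if rescale is not None:
        if rescale <= 0:
            raise ValueError("rescale must be positive")
        log_priors = log_priors + np.log(rescale)
    return library.with_priors(log_priors)
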