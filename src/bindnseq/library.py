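"""Collapsed read libraries.

A :class:`ReadLibrary` holds the distinct sequences of a sequencing pool
together with their copy numbers ``n_S`` and, once annotated from a trained
background model, the frequency priors ``f_S`` (stored in natural-log space).
All downstream quantities (selection probabilities, the data log-likelihood,
relative dissociation constants) are functions of these three columns.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_BASE_INDEX = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _BASE_INDEX[ord(_b)] = _i


def encode(sequence: str) -> np.ndarray:
    """Encode an A/C/G/T string as an int8 array (A=0, C=1, G=2, T=3)."""
    codes = _BASE_INDEX[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sorted(set(sequence) - set(ALPHABET))
        raise ValueError(f"sequence contains non-ACGT symbols: {bad}")
    return codes


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def is_valid(sequence: str) -> bool:
    return len(sequence) > 0 and set(sequence) <= set(ALPHABET)


@dataclass
class ReadLibrary:
    """Distinct reads with copy numbers and (optional) log frequency priors.

    Duplicate sequences are collapsed at construction time; ``counts[i]`` is
    the multiplicity ``n_S`` of ``sequences[i]``. ``log_priors`` is ``None``
    until :func:`bindnseq.background.annotate_priors` has been applied.
    """

    sequences: list[str]
    counts: np.ndarray
    log_priors: np.ndarray | None = None
    _encoded: dict[int, tuple[np.ndarray, np.ndarray]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.sequences) != len(self.counts):
            raise ValueError("sequences and counts length mismatch")
        if len(self.sequences) == 0:
            raise ValueError("empty read library")
        if (self.counts < 1).any():
            raise ValueError("all copy numbers must be >= 1")
        if self.log_priors is not None:
            self.log_priors = np.asarray(self.log_priors, dtype=float)
        self._encoded = None

    # ------------------------------------------------------------------ #
    @classmethod
    def from_reads(cls, reads: Iterable[str], drop_invalid: bool = True) -> "ReadLibrary":
        """Collapse an iterable of raw reads into a library.

        Reads containing characters outside A/C/G/T are dropped with a logged
        count (``drop_invalid=True``, the default) or raise an error.
        """
        counter: Counter[str] = Counter()
        n_dropped = 0
        for read in reads:
            read = read.upper().replace("U", "T")
            if not is_valid(read):
                if drop_invalid:
                    n_dropped += 1
                    continue
                raise ValueError(f"invalid read: {read!r}")
            counter[read] += 1
        if n_dropped:
            logger.warning("dropped %d reads with non-ACGT symbols", n_dropped)
        if not counter:
            raise ValueError("no valid reads")
        seqs = sorted(counter)
        counts = np.array([counter[s] for s in seqs], dtype=np.int64)
        return cls(seqs, counts)

    # ------------------------------------------------------------------ #
    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(zip(self.sequences, self.counts))

    @property
    def total_count(self) -> int:
        """Total number of reads, duplicates included (sum of n_S)."""
        return int(self.counts.sum())

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(s) for s in self.sequences], dtype=np.int64)

    @property
    def annotated(self) -> bool:
        return self.log_priors is not None

    def with_priors(self, log_priors: np.ndarray) -> "ReadLibrary":
        return ReadLibrary(self.sequences, self.counts.copy(), np.asarray(log_priors, float))

    def with_counts(self, counts: np.ndarray) -> "ReadLibrary":
        lp = None if self.log_priors is None else self.log_priors.copy()
        return ReadLibrary(list(self.sequences), counts, lp)

    def filter_min_length(self, min_length: int) -> "ReadLibrary":
        """Drop reads shorter than ``min_length`` (e.g. shorter than Lw)."""
        keep = self.lengths >= min_length
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropping %d reads shorter than %d nt", n_drop, min_length)
        if not keep.any():
            raise ValueError(f"no reads of length >= {min_length}")
        if not n_drop:
            return self
        seqs = [s for s, k in zip(self.sequences, keep) if k]
        lp = self.log_priors[keep] if self.log_priors is not None else None
        return ReadLibrary(seqs, self.counts[keep], lp)

    # ------------------------------------------------------------------ #
    def by_length(self) -> dict[int, tuple[np.ndarray, np.ndarray]]:
        """Group reads by length: {L: (indices, int8 matrix of shape (n, L))}.

        Cached; grouping lets window sums be computed as dense array ops even
        for mixed-length libraries.
        """
        if self._encoded is None:
            groups: dict[int, list[int]] = {}
            for i, s in enumerate(self.sequences):
                groups.setdefault(len(s), []).append(i)
            out = {}
            for L, idx in sorted(groups.items()):
                mat = np.stack([encode(self.sequences[i]) for i in idx])
                out[L] = (np.asarray(idx, dtype=np.int64), mat)
            self._encoded = out
        return self._encoded
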