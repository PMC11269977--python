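"""Baseline k-mer enrichment and motif comparison.

Counting every overlapping k-mer occurrence in the selected (foreground)
pool and normalizing by the input (background) pool is the standard
model-free first look at RBP specificity. The table reports, per k-mer,
pseudocount-adjusted natural-log enrichment

    log[(n_fg + pc) / sum(n_fg + pc)] - log[(n_bg + pc) / sum(n_bg + pc)]

over all 4^k possible k-mers (zeros included). The background column can
alternatively hold Markov-model expected counts. Top motifs from different
analyses are compared by Levenshtein (unit-cost edit) distance.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable

import edlib
import numpy as np
import pandas as pd

from .background import MarkovBackground
from .library import ALPHABET, ReadLibrary

logger = logging.getLogger(__name__)


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(ALPHABET, repeat=k)]


def count_kmers(reads: Iterable[str] | ReadLibrary, k: int) -> pd.Series:
    """Overlapping k-mer occurrence counts, copy-number weighted.

    Returns a Series indexed by all 4^k k-mers in lexicographic order;
    reads shorter than k contribute no windows.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not isinstance(reads, ReadLibrary):
        reads = ReadLibrary.from_reads(reads)
    counts = np.zeros(4**k, dtype=np.int64)
    n_short = 0
    for L, (idx, mat) in reads.by_length().items():
        if L < k:
            n_short += len(idx)
            continue
        n_win = L - k + 1
        codes = np.zeros((len(idx), n_win), dtype=np.int64)
        for i in range(k):
            codes = codes * 4 + mat[:, i : i + n_win]
        w = np.broadcast_to(reads.counts[idx, None], codes.shape)
        np.add.at(counts, codes.ravel(), w.ravel())
    if n_short:
        logger.info("count_kmers: %d reads shorter than k=%d", n_short, k)
    return pd.Series(counts, index=all_kmers(k), name="count")


def enrichment_table(
    fg_reads: Iterable[str] | ReadLibrary,
    bg_reads: Iterable[str] | ReadLibrary | None,
    k: int,
    pseudocount: float = 1.0,
    bg_model: MarkovBackground | None = None,
) -> pd.DataFrame:
    """Per-k-mer foreground-vs-background log enrichment, ranked descending.

    Background counts come from ``bg_reads`` or, if ``bg_model`` is given
    instead, from Markov-model expectations (total foreground windows times
    the model probability of each k-mer).
    """
    fg = count_kmers(fg_reads, k).astype(float)
    if bg_model is not None:
        kmers = all_kmers(k)
        if k < bg_model.degree:
            raise ValueError("k must be >= background model degree for model mode")
        probs = np.array([bg_model.sequence_prior(m) for m in kmers])
        bg = pd.Series(fg.sum() * probs, index=kmers)
    elif bg_reads is not None:
        bg = count_kmers(bg_reads, k).astype(float)
    else:
        raise ValueError("provide bg_reads or bg_model")
    log_enr = (
        np.log(fg + pseudocount)
        - np.log((fg + pseudocount).sum())
        - np.log(bg + pseudocount)
        + np.log((bg + pseudocount).sum())
    )
    table = pd.DataFrame(
        {"fg_count": fg, "bg_count": bg, "log_enrichment": log_enr}
    ).rename_axis("kmer")
    table = table.sort_values("log_enrichment", ascending=False, kind="stable")
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insert/delete/substitute) between strings."""
    if not a or not b:
        return max(len(a), len(b))
    return int(edlib.align(a, b, task="distance")["editDistance"])
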