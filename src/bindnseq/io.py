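"""Standard-format I/O: FASTA/FASTQ read pools, PWM files, results tables.

Reads come in as FASTA or FASTQ (gzip-transparent, format sniffed from the
first record); duplicate sequences are collapsed into copy numbers and
FASTQ quality scores are ignored — counts carry all the information the
model uses. PWMs are written both as MEME minimal motif format and as a
plain 4-column TSV (A, C, G, T; one row per position), with T rather than
U since libraries are sequenced as DNA.
"""

from __future__ import annotations

import gzip
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .library import ReadLibrary
from .likelihood import Pwm

logger = logging.getLogger(__name__)


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(handle) -> str:
    first = handle.read(1)
    handle.seek(0)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError("unrecognized read file: expected FASTA ('>') or FASTQ ('@')")


def read_reads(path) -> ReadLibrary:
    """Parse a FASTA/FASTQ(.gz) file into a collapsed ReadLibrary."""
    with _open_text(path) as handle:
        fmt = _sniff_format(handle)
        seqs = (str(rec.seq) for rec in SeqIO.parse(handle, fmt))
        try:
            return ReadLibrary.from_reads(seqs)
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc


def write_fasta(path, reads: list[str] | ReadLibrary, prefix: str = "read") -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        if isinstance(reads, ReadLibrary):
            i = 0
            for seq, count in reads:
                for _ in range(int(count)):
                    fh.write(f">{prefix}{i}\n{seq}\n")
                    i += 1
        else:
            for i, seq in enumerate(reads):
                fh.write(f">{prefix}{i}\n{seq}\n")


# ---------------------------------------------------------------------- #
# PWM formats
# ---------------------------------------------------------------------- #
def write_pwm_tsv(path, pwm: Pwm) -> None:
    df = pd.DataFrame(pwm.matrix, columns=list("ACGT"))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_pwm_tsv(path) -> Pwm:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != list("ACGT"):
        raise ValueError(f"{path}: expected columns A, C, G, T")
    return Pwm(df.to_numpy(), normalize=False)


def write_pwm_meme(path, pwm: Pwm, name: str = "motif1") -> None:
    """MEME minimal motif format (version 4 header, one motif)."""
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: +",
        "",
        "Background letter frequencies",
        "A 0.25 C 0.25 G 0.25 T 0.25",
        "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {pwm.length}",
    ]
    for row in pwm.matrix:
        lines.append(" ".join(f"{v:.10f}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_pwm_meme(path) -> Pwm:
    rows = []
    in_matrix = False
    width = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line.startswith("letter-probability matrix"):
            in_matrix = True
            m = re.search(r"w=\s*(\d+)", line)
            width = int(m.group(1)) if m else None
            continue
        if in_matrix:
            parts = line.split()
            if len(parts) != 4:
                break
            rows.append([float(v) for v in parts])
            if width is not None and len(rows) == width:
                break
    if not rows:
        raise ValueError(f"{path}: no letter-probability matrix found")
    return Pwm(np.array(rows))


# ---------------------------------------------------------------------- #
RESULT_COLUMNS = [
    "rbp_label", "lw", "init_mode", "seed", "iterations",
    "initial_loglik", "final_loglik", "e0", "convergent", "specific",
    "log_kd_rel", "pwm_path",
]


def write_results_tsv(path, rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return df
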