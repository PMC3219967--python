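"""Short-read containers and FASTQ/FASTA handling.

Reads carry per-base Phred qualities and the error probabilities derived
from them (``p = 10**(-Q/10)``).  ``N`` calls are assigned an error
probability of 3/4, which makes their emission probability uniform over
the four bases and therefore completely uninformative downstream.

Quality trimming follows the convention for Illumina 3'-end degradation:
the maximal contiguous run of *trailing* bases with quality at or below
the threshold is removed; interior low-quality bases are kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, TextIO

import numpy as np

__all__ = [
    "Read",
    "ReadPair",
    "phred_to_error_prob",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "trim_read_3prime",
    "filter_pairs",
]

PHRED_OFFSET = 33
#: Error probability assigned to ``N`` calls: makes Pr(base | reference)
#: uniform (1/4) whatever the reference distribution is.
N_ERROR_PROB = 0.75

_VALID_BASES = frozenset("ACGTN")


def phred_to_error_prob(quals: np.ndarray, bases: str) -> np.ndarray:
    """Convert Phred qualities to error probabilities, 10**(-Q/10).

    Positions called ``N`` get :data:`N_ERROR_PROB` regardless of the
    stored quality.
    """
    quals = np.asarray(quals, dtype=np.float64)
    p = np.power(10.0, -quals / 10.0)
    if "N" in bases:
        is_n = np.frombuffer(bases.encode("ascii"), dtype=np.uint8) == ord("N")
        p = np.where(is_n, N_ERROR_PROB, p)
    return p


@dataclass
class Read:
    """A called read: bases over {A,C,G,T,N} plus per-base Phred qualities."""

    id: str
    bases: str
    quals: np.ndarray  # integer Phred scores, one per base

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )
        if not set(self.bases) <= _VALID_BASES:
            bad = sorted(set(self.bases) - _VALID_BASES)
            raise ValueError(f"read {self.id!r}: invalid base(s) {bad}")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def error_probs(self) -> np.ndarray:
        """Per-base error probabilities p_k, strictly positive."""
        return phred_to_error_prob(self.quals, self.bases)


def _strip_mate_suffix(read_id: str) -> str:
    if read_id.endswith(("/1", "/2")):
        return read_id[:-2]
    return read_id


@dataclass
class ReadPair:
    """A paired-end read; ``read2`` is the reverse mate, stored as sequenced."""

    read1: Read
    read2: Read

    def __post_init__(self) -> None:
        if _strip_mate_suffix(self.read1.id) != _strip_mate_suffix(self.read2.id):
            raise ValueError(
                f"mate ids disagree: {self.read1.id!r} vs {self.read2.id!r}"
            )

    @property
    def id(self) -> str:
        return _strip_mate_suffix(self.read1.id)


class FastqParseError(ValueError):
    pass


def read_fastq(path_or_handle) -> Iterator[Read]:
    """Parse 4-line-record FASTQ with Sanger/Illumina-1.8 (Phred+33) qualities.

    Phred+64 input is rejected: a record whose quality string implies
    Q > 62 under offset 33 (i.e. characters beyond '_') combined with no
    character below ';' raises a parse error rather than being silently
    mis-decoded.
    """
    handle: TextIO
    own = False
    if hasattr(path_or_handle, "read"):
        handle = path_or_handle
    else:
        handle = open(path_or_handle)
        own = True
    try:
        line_no = 0
        while True:
            header = handle.readline()
            if not header:
                return
            line_no += 1
            if not header.startswith("@"):
                raise FastqParseError(f"line {line_no}: expected '@' header")
            seq = handle.readline().rstrip("\n")
            plus = handle.readline()
            qual = handle.readline().rstrip("\n")
            if not qual and not plus:
                raise FastqParseError(f"line {line_no}: truncated record")
            line_no += 3
            if not plus.startswith("+"):
                raise FastqParseError(f"line {line_no - 1}: expected '+' separator")
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"line {line_no}: sequence length {len(seq)} != "
                    f"quality length {len(qual)}"
                )
            q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16)
            q -= PHRED_OFFSET
            if len(q) and q.min() < 0:
                raise FastqParseError(f"line {line_no}: quality char below '!' (offset 33)")
            if len(q) and q.min() >= ord(";") - PHRED_OFFSET and q.max() > 62:
                raise FastqParseError(
                    f"line {line_no}: qualities look Phred+64 encoded; "
                    "only Phred+33 input is supported"
                )
            yield Read(header[1:].split()[0], seq.upper(), q)
    finally:
        if own:
            handle.close()


def write_fastq(reads: Iterable[Read], path_or_handle) -> None:
    handle: TextIO
    own = False
    if hasattr(path_or_handle, "write"):
        handle = path_or_handle
    else:
        handle = open(path_or_handle, "w")
        own = True
    try:
        for r in reads:
            qual = "".join(chr(int(q) + PHRED_OFFSET) for q in r.quals)
            handle.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")
    finally:
        if own:
            handle.close()


def read_fasta(path_or_handle) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) tuples from a FASTA file."""
    from Bio import SeqIO

    for rec in SeqIO.parse(path_or_handle, "fasta"):
        yield rec.id, str(rec.seq).upper()


def write_fasta(records: Iterable[tuple[str, str]], path_or_handle, width: int = 70) -> None:
    handle: TextIO
    own = False
    if hasattr(path_or_handle, "write"):
        handle = path_or_handle
    else:
        handle = open(path_or_handle, "w")
        own = True
    try:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
    finally:
        if own:
            handle.close()


def trim_read_3prime(read: Read, q_threshold: int = 2, min_len_to_trim: int = 0) -> Read:
    """Remove the maximal trailing run of bases with quality <= ``q_threshold``.

    Interior low-quality bases are retained.  If ``min_len_to_trim`` is
    positive, reads shorter than it are returned unchanged (short-read
    data sets are conventionally left untrimmed).  May return an empty
    read.
    """
    if len(read) < min_len_to_trim:
        return read
    keep = len(read)
    while keep > 0 and read.quals[keep - 1] <= q_threshold:
        keep -= 1
    if keep == len(read):
        return read
    return Read(read.id, read.bases[:keep], read.quals[:keep].copy())


def filter_pairs(pairs: Iterable[ReadPair], min_len: int = 60) -> Iterator[ReadPair]:
    """Keep a pair iff both mates are at least ``min_len`` bases long.

    Order is preserved; assumes trimming has already been applied.
    """
    return (p for p in pairs if len(p.read1) >= min_len and len(p.read2) >= min_len)


def trim_and_filter(
    pairs: Iterable[ReadPair],
    q_threshold: int = 2,
    min_len: int = 60,
    no_trim: bool = False,
) -> Iterator[ReadPair]:
    """Convenience pipeline: 3'-trim both mates, then apply the pair filter."""
    if no_trim:
        trimmed: Iterable[ReadPair] = pairs
    else:
        trimmed = (
            ReadPair(
                trim_read_3prime(p.read1, q_threshold, min_len_to_trim=min_len),
                trim_read_3prime(p.read2, q_threshold, min_len_to_trim=min_len),
            )
            for p in pairs
        )
    return filter_pairs(trimmed, min_len=min_len)
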