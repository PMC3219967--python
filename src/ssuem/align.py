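"""Sequence encoding helpers and global-alignment identity measures.

Two identity definitions are used in different places and are kept
distinct on purpose:

* ungapped-column identity — matches / (matches + mismatches) over a
  global alignment, ignoring gap columns entirely.  Used when deciding
  whether two reconstructed sequences are the same OTU (merging) and
  when matching reconstructions to known sequences.
* clustering identity — matches / alignment columns, where terminal
  gap runs are excluded but internal gaps count against identity.
  Used for greedy centroid clustering of the reference database.

Both are computed from edlib's extended CIGAR of a Needleman-Wunsch
alignment.
"""

from __future__ import annotations

import re

import edlib
import numpy as np

__all__ = [
    "encode",
    "decode",
    "revcomp",
    "revcomp_codes",
    "identity_ungapped",
    "identity_clustering",
    "edit_distance",
]

#: A=0, C=1, G=2, T=3, N=4 (anything unrecognised also maps to 4).
_LUT = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (A,C,G,T,N -> 0..4)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[np.asarray(codes, dtype=np.int8)].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def _cigar_ops(a: str, b: str) -> list[tuple[int, str]]:
    res = edlib.align(a, b, mode="NW", task="path")
    cigar = res["cigar"]
    if cigar is None:  # pragma: no cover - edlib always returns a path for NW
        raise RuntimeError("edlib returned no alignment path")
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def edit_distance(a: str, b: str) -> int:
    """Needleman-Wunsch edit distance between two sequences."""
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def identity_ungapped(a: str, b: str) -> float:
    """Identity over non-gap columns of a global alignment.

    Returns matches / (matches + mismatches); gap columns are ignored.
    Two empty sequences have identity 0.
    """
    if not a or not b:
        return 0.0
    matches = mismatches = 0
    for n, op in _cigar_ops(a, b):
        if op == "=":
            matches += n
        elif op == "X":
            mismatches += n
    denom = matches + mismatches
    return matches / denom if denom else 0.0


def identity_clustering(a: str, b: str) -> float:
    """Identity = matches / alignment columns, excluding terminal gap runs.

    Internal insertions/deletions count as non-matching columns.
    """
    if not a or not b:
        return 0.0
    ops = _cigar_ops(a, b)
    # strip leading/trailing indel runs (end-gaps)
    start, end = 0, len(ops)
    while start < end and ops[start][1] in "ID":
        start += 1
    while end > start and ops[end - 1][1] in "ID":
        end -= 1
    ops = ops[start:end]
    matches = sum(n for n, op in ops if op == "=")
    columns = sum(n for n, _ in ops)
    return matches / columns if columns else 0.0
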