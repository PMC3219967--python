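"""Candidate reference database preparation and controlled corruption.

The reference set of curated SSU sequences is prepared by a length
filter (full-length genes only) followed by greedy centroid clustering
at a fixed identity, so that near-identical database entries do not
compete for the same reads.  For robustness experiments the prepared
database can be mutated at a chosen fraction of sites, simulating a
database that does not contain the community's true sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import decode, encode, identity_clustering
from .reads import read_fasta, write_fasta

__all__ = ["ReferenceSet", "prepare_db", "mutate_db"]

_IUPAC_CONCRETE = {
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class ReferenceSet:
    """An ordered set of (id, sequence) records with unique ids."""

    records: list[tuple[str, str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("reference ids are not unique")
        for rid, seq in self.records:
            if not seq:
                raise ValueError(f"reference {rid!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @classmethod
    def from_fasta(cls, path, provenance: str | None = None) -> "ReferenceSet":
        return cls(list(read_fasta(path)), provenance=provenance or str(path))

    def to_fasta(self, path) -> None:
        write_fasta(self.records, path)


def _normalize_sequence(seq: str, rng: np.random.Generator) -> str:
    """Uppercase, U->T; other ambiguity codes become a random concrete base."""
    seq = seq.upper().replace("U", "T")
    if set(seq) <= set("ACGT"):
        return seq
    out = []
    for ch in seq:
        if ch in "ACGT":
            out.append(ch)
        else:
            choices = _IUPAC_CONCRETE.get(ch, "ACGT")
            out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def prepare_db(
    refs: ReferenceSet,
    min_len: int = 1200,
    max_len: int = 1900,
    cluster_id: float = 0.97,
    seed: int = 0,
) -> ReferenceSet:
    """Length-filter and greedily cluster the reference set.

    Sequences outside ``[min_len, max_len]`` are removed.  Survivors are
    visited longest first; each either joins the first existing centroid
    it matches at >= ``cluster_id`` clustering identity, or founds a new
    centroid.  The output is the list of centroids, in the order they
    were founded.
    """
    rng = np.random.default_rng(seed)
    survivors = [
        (rid, _normalize_sequence(seq, rng))
        for rid, seq in refs
        if min_len <= len(seq) <= max_len
    ]
    if not survivors:
        warnings.warn("prepare_db: no sequences survive the length filter")
        return ReferenceSet([], provenance=f"{refs.provenance} [prepared: empty]")

    # stable sort keeps input order among equal lengths deterministic
    survivors.sort(key=lambda r: -len(r[1]))
    centroids: list[tuple[str, str]] = []
    for rid, seq in survivors:
        for _, cseq in centroids:
            if identity_clustering(seq, cseq) >= cluster_id:
                break
        else:
            centroids.append((rid, seq))
    return ReferenceSet(
        centroids,
        provenance=(
            f"{refs.provenance} [length {min_len}-{max_len}, "
            f"clustered at {cluster_id:.0%}]"
        ),
    )


def mutate_db(
    refs: ReferenceSet,
    fraction: float = 0.10,
    seed: int = 0,
) -> tuple[ReferenceSet, pd.DataFrame]:
    """Mutate ``round(fraction * L)`` random sites of every sequence.

    Each chosen site (distinct, uniform) is replaced by one of the three
    other bases, uniformly.  Returns the mutated set and a log with one
    row per mutation: ``seq_id``, ``position`` (0-based), ``ref_base``,
    ``new_base``.  Rounding is banker's rounding (ties to even), as with
    Python's ``round``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out_records: list[tuple[str, str]] = []
    log_rows: list[tuple[str, int, str, str]] = []
    for rid, seq in refs:
        codes = encode(seq).copy()
        if codes.max(initial=0) > 3:
            raise ValueError(
                f"mutate_db: sequence {rid!r} contains non-ACGT characters; "
                "run prepare_db first"
            )
        n_mut = round(fraction * len(seq))
        if n_mut:
            positions = rng.choice(len(seq), size=n_mut, replace=False)
            positions.sort()
            # new base = old + 1..3 (mod 4): always a different concrete base
            shifts = rng.integers(1, 4, size=n_mut)
            old = codes[positions].copy()
            codes[positions] = (old + shifts) % 4
            for pos, o, n in zip(positions, old, codes[positions]):
                log_rows.append((rid, int(pos), "ACGT"[o], "ACGT"[n]))
        out_records.append((rid, decode(codes)))
    log = pd.DataFrame(log_rows, columns=["seq_id", "position", "ref_base", "new_base"])
    mutated = ReferenceSet(
        out_records,
        provenance=f"{refs.provenance} [mutated at {fraction:.0%} of sites, seed {seed}]",
    )
    return mutated, log
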