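"""Candidate read placement.

The internal mapper reproduces a seed-and-extend short-read mapping
policy for ungapped paired-end alignment: at most ``max_seed_mismatches``
mismatches inside the first ``seed_len`` bases of each mate, a cap on
the summed Phred qualities of all mismatched bases per mate, and a
proper forward-reverse pair whose insert lies within a configurable
number of standard deviations of the expected median.  Valid placements
are reported either as the complete top stratum (all placements with
the minimal total mismatch count) or as a single placement drawn
uniformly at random from that stratum.

A SAM adapter converts alignments produced by any external mapper into
the same record stream; gapped or clipped alignments are skipped (the
model is ungapped) and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from . import _mapkernels as K
from .align import encode, revcomp_codes
from .reads import Read, ReadPair

__all__ = [
    "MappingPolicy",
    "MappingRecord",
    "ReadBank",
    "RefBank",
    "MappingArrays",
    "map_pairs",
    "map_reads",
    "sam_adapter",
]


@dataclass(frozen=True)
class MappingPolicy:
    """Validity rules for the internal mapper (bowtie-like semantics)."""

    seed_len: int = 20
    max_seed_mismatches: int = 3
    max_qual_sum_mismatch: int = 300
    insert_median: float = 200.0
    insert_sd: float = 25.0
    insert_tolerance_sds: float = 3.0
    report_mode: str = "all_top_stratum"  # or "best_single_random_tie"

    def __post_init__(self) -> None:
        for name in (
            "seed_len", "max_seed_mismatches", "max_qual_sum_mismatch",
            "insert_median", "insert_sd", "insert_tolerance_sds",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.report_mode not in ("all_top_stratum", "best_single_random_tie"):
            raise ValueError(f"unknown report_mode {self.report_mode!r}")

    @property
    def insert_bounds(self) -> tuple[int, int]:
        lo = self.insert_median - self.insert_tolerance_sds * self.insert_sd
        hi = self.insert_median + self.insert_tolerance_sds * self.insert_sd
        return int(np.ceil(lo)), int(np.floor(hi))


@dataclass(frozen=True)
class MappingRecord:
    """One ungapped placement of a read or pair on a candidate sequence."""

    read_id: str
    pair_flag: str  # "single" | "pair"
    candidate_id: str
    start1: int
    strand1: str  # "+" | "-"
    mismatch_count: int
    start2: int | None = None
    strand2: str | None = None


def _concat(arrays: list[np.ndarray], dtype) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lens = np.array([len(a) for a in arrays], dtype=np.int64)
    off = np.zeros(len(arrays) + 1, dtype=np.int64)
    np.cumsum(lens, out=off[1:])
    flat = (
        np.concatenate(arrays).astype(dtype)
        if arrays
        else np.empty(0, dtype=dtype)
    )
    return flat, off, lens


class ReadBank:
    """Column-oriented storage of reads or pairs for the vectorized engine.

    For each mate the bank keeps the forward-encoded bases, the
    reverse-complemented bases, stored-orientation qualities and error
    probabilities, all concatenated with shared offsets.
    """

    def __init__(self, items: Sequence[ReadPair] | Sequence[Read]):
        if not items:
            raise ValueError("empty read set")
        self.paired = isinstance(items[0], ReadPair)
        self.n = len(items)
        if self.paired:
            self.ids = [p.id for p in items]
            mates = ([p.read1 for p in items], [p.read2 for p in items])
        else:
            self.ids = [r.id for r in items]
            mates = ([r for r in items],)
        self.codes_fwd: list[np.ndarray] = []
        self.codes_rc: list[np.ndarray] = []
        self.quals: list[np.ndarray] = []
        self.perr: list[np.ndarray] = []
        self.off: list[np.ndarray] = []
        self.lens: list[np.ndarray] = []
        for reads in mates:
            codes = [encode(r.bases) for r in reads]
            flat, off, lens = _concat(codes, np.int8)
            rc = [revcomp_codes(c) for c in codes]
            rc_flat, _, _ = _concat(rc, np.int8)
            q_flat, _, _ = _concat([r.quals for r in reads], np.int64)
            p_flat, _, _ = _concat([r.error_probs for r in reads], np.float64)
            self.codes_fwd.append(flat)
            self.codes_rc.append(rc_flat)
            self.quals.append(q_flat)
            self.perr.append(p_flat)
            self.off.append(off)
            self.lens.append(lens)

    @property
    def min_read_len(self) -> int:
        return int(min(l.min() for l in self.lens))


class RefBank:
    """Concatenated encoded reference/candidate sequences."""

    def __init__(self, records: Iterable[tuple[str, str]]):
        records = list(records)
        if not records:
            raise ValueError("empty reference set")
        self.ids = [rid for rid, _ in records]
        self.seqs = [seq for _, seq in records]
        codes = [encode(s) for s in self.seqs]
        self.codes, self.off, self.lens = _concat(codes, np.int8)
        self.n = len(records)


def build_kmer_index(refs: RefBank, k: int):
    """CSR index over all k-mers of the references (forward strand only;
    reverse-strand placements look up the reverse-complemented read)."""
    if not 1 <= k <= 12:
        raise ValueError("k must be in 1..12")
    vals_all = []
    refs_all = []
    pos_all = []
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    for r in range(refs.n):
        seq = refs.codes[refs.off[r] : refs.off[r + 1]].astype(np.int64)
        if len(seq) < k:
            continue
        win = np.lib.stride_tricks.sliding_window_view(seq, k)
        ok = (win <= 3).all(axis=1)
        vals = win @ powers
        idx = np.flatnonzero(ok)
        vals_all.append(vals[idx])
        refs_all.append(np.full(len(idx), r, dtype=np.int64))
        pos_all.append(idx.astype(np.int64))
    if vals_all:
        vals = np.concatenate(vals_all)
        erefs = np.concatenate(refs_all)
        epos = np.concatenate(pos_all)
    else:
        vals = np.empty(0, np.int64)
        erefs = np.empty(0, np.int64)
        epos = np.empty(0, np.int64)
    order = np.argsort(vals, kind="stable")
    vals, erefs, epos = vals[order], erefs[order], epos[order]
    counts = np.bincount(vals, minlength=4**k)
    bstart = np.zeros(4**k + 1, dtype=np.int64)
    np.cumsum(counts, out=bstart[1:])
    return bstart, erefs, epos


@dataclass
class MappingArrays:
    """Placement records as flat arrays, grouped by read/pair index."""

    pair_idx: np.ndarray
    cand_idx: np.ndarray
    start1: np.ndarray
    strand1: np.ndarray  # int8: 0 forward, 1 reverse
    start2: np.ndarray  # -1 for single-end records
    mm: np.ndarray
    paired: bool

    def __len__(self) -> int:
        return len(self.pair_idx)

    def take(self, sel: np.ndarray) -> "MappingArrays":
        return MappingArrays(
            self.pair_idx[sel], self.cand_idx[sel], self.start1[sel],
            self.strand1[sel], self.start2[sel], self.mm[sel], self.paired,
        )


def _seed_k(policy: MappingPolicy) -> tuple[int, int]:
    n_chunks = policy.max_seed_mismatches + 1
    k = policy.seed_len // n_chunks
    k = max(1, min(12, k))
    return k, n_chunks


def map_arrays(
    bank: ReadBank,
    refs: RefBank,
    policy: MappingPolicy,
) -> MappingArrays:
    """Exhaustive top-stratum mapping; the array-level fast path."""
    if bank.min_read_len < policy.seed_len:
        raise ValueError(
            f"internal mapper requires reads >= seed_len ({policy.seed_len} bp); "
            f"shortest read is {bank.min_read_len} bp"
        )
    k, n_chunks = _seed_k(policy)
    bstart, erefs, epos = build_kmer_index(refs, k)
    cap = max(4 * bank.n, 1024)
    while True:
        out = [np.empty(cap, np.int64) for _ in range(6)]
        if bank.paired:
            lo, hi = policy.insert_bounds
            nrec, err = K.map_pairs_kernel(
                bank.codes_fwd[0], bank.codes_rc[0], bank.quals[0],
                bank.off[0], bank.lens[0],
                bank.codes_fwd[1], bank.codes_rc[1], bank.quals[1],
                bank.off[1], bank.lens[1],
                refs.codes, refs.off, refs.lens,
                bstart, erefs, epos, k, n_chunks,
                policy.seed_len, policy.max_seed_mismatches,
                policy.max_qual_sum_mismatch, lo, hi,
                out[0], out[1], out[2], out[3], out[4], out[5],
            )
        else:
            nrec, err = K.map_singles_kernel(
                bank.codes_fwd[0], bank.codes_rc[0], bank.quals[0],
                bank.off[0], bank.lens[0],
                refs.codes, refs.off, refs.lens,
                bstart, erefs, epos, k, n_chunks,
                policy.seed_len, policy.max_seed_mismatches,
                policy.max_qual_sum_mismatch,
                out[0], out[1], out[2], out[3], out[4],
            )
            out[5] = out[4]  # singles kernel writes mm into slot 4
        if err == K.OVERFLOW:
            raise RuntimeError(
                "internal mapper scratch buffer overflow: reference set too "
                "repetitive for the index mapper at this scale"
            )
        if nrec <= cap:
            break
        cap = nrec
    sel = slice(0, nrec)
    if bank.paired:
        return MappingArrays(
            out[0][sel].copy(), out[1][sel].copy(), out[2][sel].copy(),
            out[3][sel].astype(np.int8), out[4][sel].copy(), out[5][sel].copy(),
            paired=True,
        )
    return MappingArrays(
        out[0][sel].copy(), out[1][sel].copy(), out[2][sel].copy(),
        out[3][sel].astype(np.int8),
        np.full(nrec, -1, dtype=np.int64), out[4][sel].copy(),
        paired=False,
    )


def select_best_single(arrays: MappingArrays, rng: np.random.Generator) -> MappingArrays:
    """Keep one record per read/pair, uniformly at random among its stratum."""
    if len(arrays) == 0:
        return arrays
    # records are grouped by pair index in pair order
    boundaries = np.flatnonzero(np.diff(arrays.pair_idx)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(arrays)]))
    chosen = starts + (rng.random(len(starts)) * (ends - starts)).astype(np.int64)
    return arrays.take(chosen)


def _records_from_arrays(
    arrays: MappingArrays, bank: ReadBank, refs: RefBank
) -> list[MappingRecord]:
    strands = "+-"
    out = []
    for i in range(len(arrays)):
        pi = int(arrays.pair_idx[i])
        st1 = strands[int(arrays.strand1[i])]
        if arrays.paired:
            out.append(
                MappingRecord(
                    read_id=bank.ids[pi],
                    pair_flag="pair",
                    candidate_id=refs.ids[int(arrays.cand_idx[i])],
                    start1=int(arrays.start1[i]),
                    strand1=st1,
                    start2=int(arrays.start2[i]),
                    strand2="+" if st1 == "-" else "-",
                    mismatch_count=int(arrays.mm[i]),
                )
            )
        else:
            out.append(
                MappingRecord(
                    read_id=bank.ids[pi],
                    pair_flag="single",
                    candidate_id=refs.ids[int(arrays.cand_idx[i])],
                    start1=int(arrays.start1[i]),
                    strand1=st1,
                    mismatch_count=int(arrays.mm[i]),
                )
            )
    return out


def map_pairs(
    pairs: Sequence[ReadPair],
    refs: Iterable[tuple[str, str]] | RefBank,
    policy: MappingPolicy,
    seed: int = 0,
) -> list[MappingRecord]:
    """Map read pairs onto candidate sequences under ``policy``.

    Returns the full top stratum per pair, or one seeded-random choice
    from it when ``policy.report_mode == "best_single_random_tie"``.
    Pairs with no valid placement yield no records.
    """
    bank = ReadBank(list(pairs))
    if not bank.paired:
        raise TypeError("map_pairs expects ReadPair items; use map_reads for singles")
    refbank = refs if isinstance(refs, RefBank) else RefBank(refs)
    arrays = map_arrays(bank, refbank, policy)
    if policy.report_mode == "best_single_random_tie":
        arrays = select_best_single(arrays, np.random.default_rng(seed))
    return _records_from_arrays(arrays, bank, refbank)


def map_reads(
    reads: Sequence[Read],
    refs: Iterable[tuple[str, str]] | RefBank,
    policy: MappingPolicy,
    seed: int = 0,
) -> list[MappingRecord]:
    """Single-end variant of :func:`map_pairs` (no insert constraints)."""
    bank = ReadBank(list(reads))
    refbank = refs if isinstance(refs, RefBank) else RefBank(refs)
    arrays = map_arrays(bank, refbank, policy)
    if policy.report_mode == "best_single_random_tie":
        arrays = select_best_single(arrays, np.random.default_rng(seed))
    return _records_from_arrays(arrays, bank, refbank)


def sam_adapter(
    path,
    refs: Iterable[tuple[str, str]] | RefBank,
) -> tuple[list[MappingRecord], dict[str, int]]:
    """Convert SAM/BAM alignments into mapping records.

    Primary and secondary ungapped alignments are converted; alignments
    whose CIGAR contains indels, clips, or skips are dropped and counted
    under ``skipped_gapped`` in the returned statistics.  Paired lines
    are joined on (query name, reference, mate position).  An alignment
    against a reference name absent from ``refs`` raises ``ValueError``.
    """
    import pysam

    refbank = refs if isinstance(refs, RefBank) else RefBank(refs)
    known = {rid: i for i, rid in enumerate(refbank.ids)}
    ref_codes = {
        rid: refbank.codes[refbank.off[i] : refbank.off[i + 1]]
        for i, rid in enumerate(refbank.ids)
    }
    stats = {"converted": 0, "skipped_gapped": 0, "skipped_unmapped": 0,
             "skipped_unpaired": 0}
    # (qname, is_read2) -> list of (ref, pos, reverse, mm, pnext)
    mate_lines: dict[tuple[str, bool], list[tuple[str, int, bool, int, int]]] = {}
    singles: list[MappingRecord] = []

    def _mismatches(aln) -> int:
        if aln.has_tag("NM"):
            return int(aln.get_tag("NM"))
        # SAM stores SEQ already in reference orientation
        codes = encode(aln.query_sequence.upper())
        ref = ref_codes[aln.reference_name]
        seg = ref[aln.reference_start : aln.reference_start + len(codes)]
        return int((codes != seg).sum())

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                stats["skipped_unmapped"] += 1
                continue
            if aln.reference_name not in known:
                raise ValueError(
                    f"alignment reference {aln.reference_name!r} is not a "
                    "known candidate id"
                )
            cig = aln.cigartuples or []
            if any(op != 0 and op not in (7, 8) for op, _ in cig):
                stats["skipped_gapped"] += 1
                continue
            mm = _mismatches(aln)
            if aln.is_paired:
                key = (aln.query_name, aln.is_read2)
                mate_lines.setdefault(key, []).append(
                    (
                        aln.reference_name,
                        aln.reference_start,
                        aln.is_reverse,
                        mm,
                        aln.next_reference_start,
                    )
                )
            else:
                singles.append(
                    MappingRecord(
                        read_id=aln.query_name,
                        pair_flag="single",
                        candidate_id=aln.reference_name,
                        start1=aln.reference_start,
                        strand1="-" if aln.is_reverse else "+",
                        mismatch_count=mm,
                    )
                )
                stats["converted"] += 1

    records = list(singles)
    for (qname, is_read2), lines in mate_lines.items():
        if is_read2:
            continue
        mates2 = mate_lines.get((qname, True), [])
        for ref1, pos1, rev1, mm1, pnext1 in lines:
            matched = False
            for ref2, pos2, rev2, mm2, _ in mates2:
                if ref2 == ref1 and pos2 == pnext1 and rev2 != rev1:
                    records.append(
                        MappingRecord(
                            read_id=qname,
                            pair_flag="pair",
                            candidate_id=ref1,
                            start1=pos1,
                            strand1="-" if rev1 else "+",
                            start2=pos2,
                            strand2="-" if rev2 else "+",
                            mismatch_count=mm1 + mm2,
                        )
                    )
                    stats["converted"] += 1
                    matched = True
                    break
            if not matched:
                stats["skipped_unpaired"] += 1
    return records, stats
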