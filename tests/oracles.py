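"""Independent brute-force reference implementations used as test oracles.

These deliberately share no code with the package: the mapper oracle
scans every (reference, strand, offset) placement with plain Python
loops, and the EM oracle evaluates the posterior/consensus/prior
formulas directly with per-read dictionaries.  They are only feasible
at tiny problem sizes.
"""

from __future__ import annotations

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_BASES = "ACGT"


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def mate_placements(bases, quals, ref, seed_len, max_seed_mm, max_qual_sum):
    """All valid (start, strand, mm) placements of one mate on one reference."""
    L = len(bases)
    out = []
    for strand in "+-":
        if strand == "+":
            oriented = bases
            qual_of = lambda j: quals[j]
            in_seed = lambda j: j < seed_len
        else:
            oriented = rc(bases)
            qual_of = lambda j: quals[L - 1 - j]
            in_seed = lambda j: j >= L - seed_len
        for start in range(0, len(ref) - L + 1):
            mm = seed_mm = qsum = 0
            for j in range(L):
                if oriented[j] != ref[start + j]:
                    mm += 1
                    qsum += int(qual_of(j))
                    if in_seed(j):
                        seed_mm += 1
            if seed_mm <= max_seed_mm and qsum <= max_qual_sum:
                out.append((start, strand, mm))
    return out


def map_pairs_brute(pairs, refs, policy):
    """Exhaustive paired mapping; returns the top stratum per pair as a set of
    (pair_index, ref_id, start1, strand1, start2, total_mm) tuples."""
    lo, hi = policy.insert_bounds
    result = set()
    for pi, pair in enumerate(pairs):
        combos = []
        for rid, ref in refs:
            h1 = mate_placements(
                pair.read1.bases, pair.read1.quals, ref,
                policy.seed_len, policy.max_seed_mismatches,
                policy.max_qual_sum_mismatch,
            )
            h2 = mate_placements(
                pair.read2.bases, pair.read2.quals, ref,
                policy.seed_len, policy.max_seed_mismatches,
                policy.max_qual_sum_mismatch,
            )
            L1, L2 = len(pair.read1.bases), len(pair.read2.bases)
            for s1, st1, m1 in h1:
                for s2, st2, m2 in h2:
                    if st1 == st2:
                        continue
                    if st1 == "+":
                        if s2 < s1:
                            continue
                        ins = s2 + L2 - s1
                    else:
                        if s2 > s1:
                            continue
                        ins = s1 + L1 - s2
                    if lo <= ins <= hi:
                        combos.append((rid, s1, st1, s2, m1 + m2))
        if not combos:
            continue
        best = min(c[-1] for c in combos)
        for rid, s1, st1, s2, mm in combos:
            if mm == best:
                result.add((pi, rid, s1, st1, s2, mm))
    return result


def map_singles_brute(reads, refs, policy):
    """Single-end variant; set of (read_index, ref_id, start, strand, mm)."""
    result = set()
    for i, read in enumerate(reads):
        hits = []
        for rid, ref in refs:
            for s, st, mm in mate_placements(
                read.bases, read.quals, ref,
                policy.seed_len, policy.max_seed_mismatches,
                policy.max_qual_sum_mismatch,
            ):
                hits.append((rid, s, st, mm))
        if not hits:
            continue
        best = min(h[-1] for h in hits)
        for rid, s, st, mm in hits:
            if mm == best:
                result.add((i, rid, s, st, mm))
    return result


# ---------------------------------------------------------------------------
# EM oracle: direct evaluation of the posterior / prior / consensus formulas


def emission(b, p, dist):
    """sum_n Pr(b|n) Pr(n) with Pr(b|n) = 1-p on match, p/3 otherwise."""
    total = 0.0
    for ni, n in enumerate(_BASES):
        pr_b_given_n = (1.0 - p) if b == n else p / 3.0
        total += pr_b_given_n * dist[ni]
    return total


def _aligned_bases(pair_or_read, record):
    """Yield (ref_position, base, error_prob) for every mapped position."""
    if hasattr(pair_or_read, "read1"):
        mates = [
            (pair_or_read.read1, record["start1"], record["strand1"]),
            (pair_or_read.read2, record["start2"], record["strand2"]),
        ]
    else:
        mates = [(pair_or_read, record["start1"], record["strand1"])]
    for read, start, strand in mates:
        bases = read.bases
        perr = list(read.error_probs)
        if strand == "-":
            bases = rc(bases)
            perr = perr[::-1]
        for j, b in enumerate(bases):
            yield start + j, b, perr[j]


def likelihood(pair_or_read, record, base_probs):
    """Pr(r|s): plain product over all mapped positions (tiny reads only)."""
    prod = 1.0
    for pos, b, p in _aligned_bases(pair_or_read, record):
        prod *= emission(b, p, base_probs[pos])
    return prod


def em_iteration(items, candidates, records, priors):
    """One E-step plus M-step evaluated directly from the formulas.

    items: reads or pairs; candidates: {cid: L x 4 list of rows};
    records: list of dicts with read_index, cand_id, start1/strand1
    (+ start2/strand2 for pairs); priors: {cid: p}.

    Returns (posteriors per record, new priors, new base_probs,
    new consensus strings).  Consensus ties break to the previous
    consensus base (argmax of the old row), then alphabetically.
    """
    lik = [
        likelihood(items[r["read_index"]], r, candidates[r["cand_id"]])
        for r in records
    ]
    # posteriors, normalized per read over its mapped candidates
    by_read = {}
    for ri, r in enumerate(records):
        by_read.setdefault(r["read_index"], []).append(ri)
    post = [0.0] * len(records)
    for ri_list in by_read.values():
        z = sum(lik[i] * priors[records[i]["cand_id"]] for i in ri_list)
        for i in ri_list:
            post[i] = lik[i] * priors[records[i]["cand_id"]] / z
    # priors: posterior mass / J
    J = len(by_read)
    new_priors = {cid: 0.0 for cid in candidates}
    for i, r in enumerate(records):
        new_priors[r["cand_id"]] += post[i]
    new_priors = {cid: m / J for cid, m in new_priors.items()}
    # consensus correction
    new_probs = {}
    new_cons = {}
    for cid, rows in candidates.items():
        L = len(rows)
        acc = [[0.0] * 4 for _ in range(L)]
        cov = [0] * L
        for i, r in enumerate(records):
            if r["cand_id"] != cid:
                continue
            for pos, b, p in _aligned_bases(items[r["read_index"]], r):
                for ni, n in enumerate(_BASES):
                    ind = 1.0 if b == n else 0.0
                    acc[pos][ni] += post[i] * (
                        ind * (1.0 - p) + (1.0 - ind) * (p / 3.0)
                    )
                cov[pos] += 1
        out_rows = []
        cons = []
        for pos in range(L):
            old = rows[pos]
            if cov[pos] == 0 or sum(acc[pos]) == 0.0:
                row = list(old)
            else:
                z = sum(acc[pos])
                row = [v / z for v in acc[pos]]
            out_rows.append(row)
            prev_base = max(range(4), key=lambda ni: (old[ni], -ni))
            best = max(row)
            if row[prev_base] >= best:
                choice = prev_base
            else:
                choice = row.index(best)  # first max = alphabetical
            cons.append(_BASES[choice])
        new_probs[cid] = out_rows
        new_cons[cid] = "".join(cons)
    return post, new_priors, new_probs, new_cons
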