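"""Numba kernels for the internal ungapped paired-end mapper.

Seeding is pigeonhole-exact: a valid placement may have at most
``max_seed_mm`` mismatches inside the seed region (the first
``seed_len`` stored bases of the mate), so splitting the seed region
into ``max_seed_mm + 1`` disjoint k-mers guarantees that at least one
k-mer matches the reference exactly.  Every exact k-mer hit proposes a
diagonal (reference, start) which is then verified against the full
validity rules, making the index mapper exhaustive over valid
placements while staying far cheaper than a full scan.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# scratch sizes; overflow is reported back to the caller as an error code
_MAX_DIAGS = 1 << 14
_MAX_HITS = 1 << 12

OVERFLOW = -2


@njit(cache=True, inline="always")
def _verify(
    oc, ostart, L, quals, qstart, refc, rstart,
    seed_at_end, seed_len, max_seed_mm, max_qual_sum,
):
    """Check one placement; return mismatch count, or -1 if invalid.

    ``oc`` holds the mate in reference orientation starting at ``ostart``;
    ``quals`` holds stored-orientation qualities starting at ``qstart``.
    The scan starts from the seed side so seed/quality caps exit early.
    """
    mm = 0
    qs = 0
    smm = 0
    if not seed_at_end:
        for j in range(L):
            if oc[ostart + j] != refc[rstart + j]:
                mm += 1
                qs += quals[qstart + j]
                if j < seed_len:
                    smm += 1
                    if smm > max_seed_mm:
                        return -1
                if qs > max_qual_sum:
                    return -1
    else:
        # reverse-strand placement: stored base j sits at oriented L-1-j
        for jj in range(L):
            j = L - 1 - jj
            if oc[ostart + j] != refc[rstart + j]:
                mm += 1
                qs += quals[qstart + jj]
                if j >= L - seed_len:
                    smm += 1
                    if smm > max_seed_mm:
                        return -1
                if qs > max_qual_sum:
                    return -1
    return mm


@njit(cache=True)
def _collect_hits(
    oc, ooff, quals, qoff, L, seed_at_end,
    refc, roff, rlen,
    bstart, eref, epos, k, n_chunks,
    seed_len, max_seed_mm, max_qual_sum,
    diag_buf, hit_ref, hit_start, hit_mm,
):
    """Find all valid placements of one oriented mate; return count or OVERFLOW."""
    nd = 0
    for t in range(n_chunks):
        c = t * k  # chunk start in stored coordinates
        if c + k > seed_len or c + k > L:
            break
        if seed_at_end:
            os_ = L - c - k
        else:
            os_ = c
        v = 0
        ok = True
        for j in range(k):
            code = oc[ooff + os_ + j]
            if code > 3:
                ok = False
                break
            v = v * 4 + code
        if not ok:
            continue
        for e in range(bstart[v], bstart[v + 1]):
            r = eref[e]
            start = epos[e] - os_
            if start < 0 or start + L > rlen[r]:
                continue
            if nd >= _MAX_DIAGS:
                return OVERFLOW
            diag_buf[nd] = r * np.int64(1 << 32) + start
            nd += 1
    if nd == 0:
        return 0
    diags = np.sort(diag_buf[:nd])
    nh = 0
    prev = np.int64(-1)
    for i in range(nd):
        d = diags[i]
        if d == prev:
            continue
        prev = d
        r = np.int64(d >> 32)
        start = np.int64(d & np.int64(0xFFFFFFFF))
        mm = _verify(
            oc, ooff, L, quals, qoff, refc, roff[r] + start,
            seed_at_end, seed_len, max_seed_mm, max_qual_sum,
        )
        if mm >= 0:
            if nh >= _MAX_HITS:
                return OVERFLOW
            hit_ref[nh] = r
            hit_start[nh] = start
            hit_mm[nh] = mm
            nh += 1
    return nh


@njit(cache=True)
def map_pairs_kernel(
    c1f, c1r, q1, off1, len1,
    c2f, c2r, q2, off2, len2,
    refc, roff, rlen,
    bstart, eref, epos, k, n_chunks,
    seed_len, max_seed_mm, max_qual_sum,
    min_ins, max_ins,
    out_pair, out_ref, out_s1, out_st1, out_s2, out_mm,
):
    """Map every pair; write top-stratum records while they fit.

    Returns (records_needed, error_flag).  error_flag is OVERFLOW when a
    scratch buffer overflowed (instance too repetitive for the internal
    mapper), else 0.  Records are grouped by pair in pair order.  A pair
    is valid when both mates pass the per-mate rules on the same
    reference in forward-reverse orientation with the insert length
    inside [min_ins, max_ins]; only combinations with the minimal total
    mismatch count are reported.
    """
    n = len(len1)
    cap = out_pair.shape[0]
    diag_buf = np.empty(_MAX_DIAGS, np.int64)
    h1p_r = np.empty(_MAX_HITS, np.int64)
    h1p_s = np.empty(_MAX_HITS, np.int64)
    h1p_m = np.empty(_MAX_HITS, np.int64)
    h1m_r = np.empty(_MAX_HITS, np.int64)
    h1m_s = np.empty(_MAX_HITS, np.int64)
    h1m_m = np.empty(_MAX_HITS, np.int64)
    h2p_r = np.empty(_MAX_HITS, np.int64)
    h2p_s = np.empty(_MAX_HITS, np.int64)
    h2p_m = np.empty(_MAX_HITS, np.int64)
    h2m_r = np.empty(_MAX_HITS, np.int64)
    h2m_s = np.empty(_MAX_HITS, np.int64)
    h2m_m = np.empty(_MAX_HITS, np.int64)
    nrec = 0
    for i in range(n):
        L1 = len1[i]
        L2 = len2[i]
        n1p = _collect_hits(
            c1f, off1[i], q1, off1[i], L1, False, refc, roff, rlen,
            bstart, eref, epos, k, n_chunks, seed_len, max_seed_mm,
            max_qual_sum, diag_buf, h1p_r, h1p_s, h1p_m,
        )
        n1m = _collect_hits(
            c1r, off1[i], q1, off1[i], L1, True, refc, roff, rlen,
            bstart, eref, epos, k, n_chunks, seed_len, max_seed_mm,
            max_qual_sum, diag_buf, h1m_r, h1m_s, h1m_m,
        )
        n2p = _collect_hits(
            c2f, off2[i], q2, off2[i], L2, False, refc, roff, rlen,
            bstart, eref, epos, k, n_chunks, seed_len, max_seed_mm,
            max_qual_sum, diag_buf, h2p_r, h2p_s, h2p_m,
        )
        n2m = _collect_hits(
            c2r, off2[i], q2, off2[i], L2, True, refc, roff, rlen,
            bstart, eref, epos, k, n_chunks, seed_len, max_seed_mm,
            max_qual_sum, diag_buf, h2m_r, h2m_s, h2m_m,
        )
        if n1p == OVERFLOW or n1m == OVERFLOW or n2p == OVERFLOW or n2m == OVERFLOW:
            return nrec, OVERFLOW
        # pass 1: minimal total mismatch count over valid FR combinations
        best = np.int64(1 << 60)
        for a in range(n1p):  # mate1 forward (left), mate2 reverse (right)
            for b in range(n2m):
                if h1p_r[a] != h2m_r[b]:
                    continue
                ins = h2m_s[b] + L2 - h1p_s[a]
                if h2m_s[b] < h1p_s[a] or ins < min_ins or ins > max_ins:
                    continue
                t = h1p_m[a] + h2m_m[b]
                if t < best:
                    best = t
        for a in range(n1m):  # mate1 reverse (right), mate2 forward (left)
            for b in range(n2p):
                if h1m_r[a] != h2p_r[b]:
                    continue
                ins = h1m_s[a] + L1 - h2p_s[b]
                if h2p_s[b] > h1m_s[a] or ins < min_ins or ins > max_ins:
                    continue
                t = h1m_m[a] + h2p_m[b]
                if t < best:
                    best = t
        if best == 1 << 60:
            continue
        # pass 2: emit the top stratum
        for a in range(n1p):
            for b in range(n2m):
                if h1p_r[a] != h2m_r[b]:
                    continue
                ins = h2m_s[b] + L2 - h1p_s[a]
                if h2m_s[b] < h1p_s[a] or ins < min_ins or ins > max_ins:
                    continue
                if h1p_m[a] + h2m_m[b] == best:
                    if nrec < cap:
                        out_pair[nrec] = i
                        out_ref[nrec] = h1p_r[a]
                        out_s1[nrec] = h1p_s[a]
                        out_st1[nrec] = 0
                        out_s2[nrec] = h2m_s[b]
                        out_mm[nrec] = best
                    nrec += 1
        for a in range(n1m):
            for b in range(n2p):
                if h1m_r[a] != h2p_r[b]:
                    continue
                ins = h1m_s[a] + L1 - h2p_s[b]
                if h2p_s[b] > h1m_s[a] or ins < min_ins or ins > max_ins:
                    continue
                if h1m_m[a] + h2p_m[b] == best:
                    if nrec < cap:
                        out_pair[nrec] = i
                        out_ref[nrec] = h1m_r[a]
                        out_s1[nrec] = h1m_s[a]
                        out_st1[nrec] = 1
                        out_s2[nrec] = h2p_s[b]
                        out_mm[nrec] = best
                    nrec += 1
    return nrec, 0


@njit(cache=True)
def map_singles_kernel(
    cf, cr, q, off, lens,
    refc, roff, rlen,
    bstart, eref, epos, k, n_chunks,
    seed_len, max_seed_mm, max_qual_sum,
    out_read, out_ref, out_s1, out_st1, out_mm,
):
    """Single-end variant: top stratum over both strands, no insert rules."""
    n = len(lens)
    cap = out_read.shape[0]
    diag_buf = np.empty(_MAX_DIAGS, np.int64)
    hp_r = np.empty(_MAX_HITS, np.int64)
    hp_s = np.empty(_MAX_HITS, np.int64)
    hp_m = np.empty(_MAX_HITS, np.int64)
    hm_r = np.empty(_MAX_HITS, np.int64)
    hm_s = np.empty(_MAX_HITS, np.int64)
    hm_m = np.empty(_MAX_HITS, np.int64)
    nrec = 0
    for i in range(n):
        L = lens[i]
        np_ = _collect_hits(
            cf, off[i], q, off[i], L, False, refc, roff, rlen,
            bstart, eref, epos, k, n_chunks, seed_len, max_seed_mm,
            max_qual_sum, diag_buf, hp_r, hp_s, hp_m,
        )
        nm_ = _collect_hits(
            cr, off[i], q, off[i], L, True, refc, roff, rlen,
            bstart, eref, epos, k, n_chunks, seed_len, max_seed_mm,
            max_qual_sum, diag_buf, hm_r, hm_s, hm_m,
        )
        if np_ == OVERFLOW or nm_ == OVERFLOW:
            return nrec, OVERFLOW
        best = np.int64(1 << 60)
        for a in range(np_):
            if hp_m[a] < best:
                best = hp_m[a]
        for a in range(nm_):
            if hm_m[a] < best:
                best = hm_m[a]
        if best == 1 << 60:
            continue
        for a in range(np_):
            if hp_m[a] == best:
                if nrec < cap:
                    out_read[nrec] = i
                    out_ref[nrec] = hp_r[a]
                    out_s1[nrec] = hp_s[a]
                    out_st1[nrec] = 0
                    out_mm[nrec] = best
                nrec += 1
        for a in range(nm_):
            if hm_m[a] == best:
                if nrec < cap:
                    out_read[nrec] = i
                    out_ref[nrec] = hm_r[a]
                    out_s1[nrec] = hm_s[a]
                    out_st1[nrec] = 1
                    out_mm[nrec] = best
                nrec += 1
    return nrec, 0
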