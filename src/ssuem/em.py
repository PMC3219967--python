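"""Expectation-maximization reconstruction of SSU sequences and abundances.

The model: a community is a mixture of unknown full-length gene
sequences ``s`` with mixture weights (priors) ``Pr(s)``; each read ``r``
was generated from one of them.  Each candidate sequence is represented
probabilistically as an L x 4 matrix of per-position base probabilities
``Pr(n)`` whose per-position argmax is the consensus used for mapping.

E-step: for every read with reported mappings,
``Pr(s|r) = Pr(r|s) Pr(s) / sum_i Pr(r|s_i) Pr(s_i)``, with the
likelihood a product over mapped positions of
``sum_n Pr(b_k|n) Pr(n)`` where ``Pr(b_k|n) = 1-p_k`` on a match and
``p_k/3`` otherwise (``p_k`` the called base's error probability).
Candidates with no reported mapping for a read have exactly zero
posterior.  Paired mates are treated as one longer read (positions of
both mates multiply into one likelihood).

M-step: per-position base probabilities are re-estimated as the
posterior-weighted, quality-adjusted base counts over all aligned reads;
priors as the posterior mass per candidate divided by the number J of
reads with mappings.  Candidates that converge to the same sequence are
merged (> merge_id ungapped-column identity); candidates showing
evidence of two strains (second-most-probable base above ``minor_prob``
at more than ``site_frac`` of positions) are split in two.

All likelihood math is in log space with log-sum-exp normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .align import decode, edit_distance, encode, identity_ungapped, revcomp_codes
from .mapper import (
    MappingArrays,
    MappingPolicy,
    MappingRecord,
    ReadBank,
    RefBank,
    map_arrays,
    select_best_single,
)
from .reads import Read, ReadPair, write_fasta

__all__ = [
    "CandidateSequence",
    "PosteriorTable",
    "EMState",
    "RunResult",
    "base_emission_prob",
    "read_likelihood",
    "e_step",
    "m_step_priors",
    "m_step_consensus",
    "merge_pass",
    "split_pass",
    "initialize",
    "run",
    "total_log_likelihood",
]

_BASES = "ACGT"
_SPLIT_EPS = 0.01  # delta-like row sharpness for newly split twins


# ---------------------------------------------------------------------------
# data types


@dataclass
class CandidateSequence:
    """A candidate gene: per-position base probabilities plus a prior."""

    id: str
    base_probs: np.ndarray  # (L, 4) rows summing to 1
    prior: float = 0.0
    coverage: np.ndarray | None = None  # reads informing the last update

    def __post_init__(self) -> None:
        self.base_probs = np.asarray(self.base_probs, dtype=np.float64)
        if self.base_probs.ndim != 2 or self.base_probs.shape[1] != 4:
            raise ValueError("base_probs must be (L, 4)")
        if self.coverage is None:
            self.coverage = np.zeros(len(self), dtype=np.int64)
        if not hasattr(self, "_cons_codes") or self._cons_codes is None:
            self._cons_codes = np.argmax(self.base_probs, axis=1).astype(np.int8)

    @classmethod
    def from_sequence(cls, rid: str, seq: str, prior: float = 0.0) -> "CandidateSequence":
        codes = encode(seq)
        if codes.max(initial=0) > 3:
            raise ValueError(f"candidate {rid!r} contains non-ACGT characters")
        probs = np.zeros((len(codes), 4), dtype=np.float64)
        probs[np.arange(len(codes)), codes] = 1.0
        obj = cls(rid, probs, prior)
        obj._cons_codes = codes.astype(np.int8)
        return obj

    def __len__(self) -> int:
        return self.base_probs.shape[0]

    @property
    def consensus(self) -> str:
        """Per-position argmax bases (ties resolved at update time)."""
        return decode(self._cons_codes)


class PosteriorTable:
    """Sparse read-candidate posterior probabilities Pr(s|r).

    Entries exist only for (read, candidate) pairs with at least one
    reported mapping; all other pairs are exactly zero.
    """

    def __init__(
        self,
        read_ids: list[str],
        cand_ids: list[str],
        pair_idx: np.ndarray,
        cand_idx: np.ndarray,
        probs: np.ndarray,
    ):
        self.read_ids = read_ids
        self.cand_ids = cand_ids
        self.pair_idx = pair_idx
        self.cand_idx = cand_idx
        self.probs = probs

    def __len__(self) -> int:
        return len(self.probs)

    def get(self, read_id: str, cand_id: str) -> float:
        try:
            pi = self.read_ids.index(read_id)
            ci = self.cand_ids.index(cand_id)
        except ValueError:
            return 0.0
        sel = (self.pair_idx == pi) & (self.cand_idx == ci)
        return float(self.probs[sel].sum())

    def rows(self):
        """Yield (read_id, {candidate_id: prob}) for reads with entries."""
        order = np.argsort(self.pair_idx, kind="stable")
        cur = None
        row: dict[str, float] = {}
        for i in order:
            pi = int(self.pair_idx[i])
            if pi != cur:
                if cur is not None:
                    yield self.read_ids[cur], row
                cur, row = pi, {}
            cid = self.cand_ids[int(self.cand_idx[i])]
            row[cid] = row.get(cid, 0.0) + float(self.probs[i])
        if cur is not None:
            yield self.read_ids[cur], row

    def row_sums(self) -> np.ndarray:
        return np.bincount(self.pair_idx, weights=self.probs)[
            np.unique(self.pair_idx)
        ]


@dataclass
class EMState:
    """The full state of one reconstruction run."""

    candidates: list[CandidateSequence]
    bank: ReadBank
    J: int = 0
    iteration: int = 0
    nt_changes_last_iter: int = -1
    underflow_reads: int = 0
    # current mapping / posterior arrays (records grouped by read index)
    mappings: MappingArrays | None = None
    posterior_probs: np.ndarray | None = None
    _split_counter: int = 0

    @property
    def priors(self) -> np.ndarray:
        return np.array([c.prior for c in self.candidates])

    @property
    def posteriors(self) -> PosteriorTable | None:
        if self.mappings is None or self.posterior_probs is None:
            return None
        return PosteriorTable(
            self.bank.ids,
            [c.id for c in self.candidates],
            self.mappings.pair_idx,
            self.mappings.cand_idx,
            self.posterior_probs,
        )

    def check_invariants(self, tol: float = 1e-9) -> None:
        """Assert the normalization invariants of the model."""
        if self.posterior_probs is not None and len(self.posterior_probs):
            sums = np.bincount(
                self.mappings.pair_idx, weights=self.posterior_probs
            )
            sums = sums[np.unique(self.mappings.pair_idx)]
            if np.abs(sums - 1.0).max() > tol:
                raise AssertionError("posterior rows do not sum to 1")
        if self.candidates:
            if abs(sum(c.prior for c in self.candidates) - 1.0) > tol:
                raise AssertionError("priors do not sum to 1")
            for c in self.candidates:
                dev = np.abs(c.base_probs.sum(axis=1) - 1.0).max()
                if dev > tol:
                    raise AssertionError(
                        f"base probability rows of {c.id} do not sum to 1"
                    )


# ---------------------------------------------------------------------------
# scalar operations (reference path; the engine uses the vectorized path)


def base_emission_prob(read_base: str, error_prob: float, ref_base_dist) -> float:
    """Pr(b_k) = sum_n Pr(b_k|n) Pr(n) for one read base against one row.

    Pr(b_k|n) is ``1 - p`` when the called base equals ``n`` and ``p/3``
    otherwise.  For an ``N`` call with its conventional ``p = 3/4`` this
    evaluates to 1/4 regardless of the reference distribution.
    """
    dist = np.asarray(ref_base_dist, dtype=np.float64)
    code = _BASES.find(read_base)
    q = dist[code] if code >= 0 else 0.0
    p = float(error_prob)
    return (1.0 - p) * q + (p / 3.0) * (1.0 - q)


def read_likelihood(
    read_or_pair: Read | ReadPair,
    mapping: MappingRecord,
    candidate: CandidateSequence,
) -> float:
    """log Pr(r|s): sum of log emission probabilities over mapped positions.

    Paired mates contribute as if they were one longer read.
    """
    if isinstance(read_or_pair, ReadPair):
        mates = [
            (read_or_pair.read1, mapping.start1, mapping.strand1),
            (read_or_pair.read2, mapping.start2, mapping.strand2),
        ]
    else:
        mates = [(read_or_pair, mapping.start1, mapping.strand1)]
    total = 0.0
    for read, start, strand in mates:
        bases = read.bases
        perr = read.error_probs
        if strand == "-":
            bases = decode(revcomp_codes(encode(bases)))
            perr = perr[::-1]
        for j, (b, p) in enumerate(zip(bases, perr)):
            total += np.log(
                base_emission_prob(b, p, candidate.base_probs[start + j])
            )
    return float(total)


# ---------------------------------------------------------------------------
# vectorized engine internals


def _cand_concat(cands: list[CandidateSequence]):
    lens = np.array([len(c) for c in cands], dtype=np.int64)
    off = np.zeros(len(cands) + 1, dtype=np.int64)
    np.cumsum(lens, out=off[1:])
    P = np.concatenate([c.base_probs for c in cands], axis=0)
    return off, P


def _group_bounds(pair_idx: np.ndarray):
    b = np.flatnonzero(np.diff(pair_idx)) + 1
    starts = np.concatenate(([0], b))
    ends = np.concatenate((b, [len(pair_idx)]))
    return starts, ends


def _mate_layout(bank: ReadBank, m: MappingArrays, mate: int):
    """Per-record (start, strand) for one mate of each mapping record."""
    if mate == 0:
        return m.start1, m.strand1
    return m.start2, (1 - m.strand1).astype(np.int8)


def _iter_mate_groups(bank: ReadBank, m: MappingArrays):
    """Yield (record_sel, mate, ref positions, read codes, perr, mask)."""
    n_mates = 2 if m.paired else 1
    for mate in range(n_mates):
        starts, strands = _mate_layout(bank, m, mate)
        lens_all = bank.lens[mate][m.pair_idx]
        for strand_val in (0, 1):
            sel = np.flatnonzero(strands == strand_val)
            if len(sel) == 0:
                continue
            L = lens_all[sel]
            Lmax = int(L.max())
            Jg = np.arange(Lmax)
            mask = Jg[None, :] < L[:, None]
            ref_pos = starts[sel][:, None] + Jg[None, :]
            ro = bank.off[mate][m.pair_idx[sel]]
            if strand_val == 0:
                ridx = ro[:, None] + Jg[None, :]
                codes_src = bank.codes_fwd[mate]
                pidx = ridx
            else:
                ridx = ro[:, None] + Jg[None, :]
                codes_src = bank.codes_rc[mate]
                pidx = ro[:, None] + (L[:, None] - 1 - Jg[None, :])
            ridx = np.where(mask, ridx, 0)
            pidx = np.where(mask, pidx, 0)
            codes = codes_src[ridx]
            perr = bank.perr[mate][pidx]
            yield sel, ref_pos, codes, perr, mask


def _records_loglik(bank: ReadBank, m: MappingArrays, cands) -> np.ndarray:
    off, P = _cand_concat(cands)
    ll = np.zeros(len(m), dtype=np.float64)
    for sel, ref_pos, codes, perr, mask in _iter_mate_groups(bank, m):
        gpos = off[m.cand_idx[sel]][:, None] + ref_pos
        gpos = np.where(mask, gpos, 0)
        q = P[gpos, np.minimum(codes, 3)]
        term = (1.0 - perr) * q + (perr / 3.0) * (1.0 - q)
        contrib = np.where(mask, np.log(term), 0.0)
        ll[sel] += contrib.sum(axis=1)
    return ll


def e_step(state: EMState, mappings: MappingArrays | None = None) -> PosteriorTable:
    """Compute Pr(s|r) over mapped candidates: likelihood x prior, normalized."""
    if mappings is not None:
        state.mappings = mappings
    m = state.mappings
    if m is None or len(m) == 0:
        raise RuntimeError("no mappings available for the E-step")
    priors = state.priors
    if np.any(priors <= 0):
        raise RuntimeError("E-step requires strictly positive priors")
    ll = _records_loglik(state.bank, m, state.candidates)
    logpost = ll + np.log(priors)[m.cand_idx]
    starts, ends = _group_bounds(m.pair_idx)
    seg = np.repeat(np.arange(len(starts)), ends - starts)
    gmax = np.maximum.reduceat(logpost, starts)
    bad = ~np.isfinite(gmax)
    if bad.any():
        state.underflow_reads += int(bad.sum())
        warnings.warn(
            f"{int(bad.sum())} read(s) underflowed; using uniform posteriors"
        )
        logpost = np.where(np.isfinite(gmax)[seg], logpost, 0.0)
        gmax = np.where(bad, 0.0, gmax)
    e = np.exp(logpost - gmax[seg])
    s = np.add.reduceat(e, starts)
    probs = e / s[seg]
    state.posterior_probs = probs
    state.J = len(starts)
    return state.posteriors


def m_step_priors(state: EMState) -> np.ndarray:
    """Pr(s) = (1/J) sum_j Pr(s|r_j); candidates at exactly zero are pruned."""
    m = state.mappings
    if m is None or state.posterior_probs is None:
        raise RuntimeError("run the E-step first")
    if state.J == 0:
        raise RuntimeError("no reads mapped")
    mass = np.bincount(
        m.cand_idx, weights=state.posterior_probs, minlength=len(state.candidates)
    )
    priors = mass / state.J
    keep = priors > 0.0
    if not keep.all():
        new_idx = np.cumsum(keep) - 1
        rec_keep = keep[m.cand_idx]
        state.mappings = m.take(np.flatnonzero(rec_keep))
        state.mappings.cand_idx = new_idx[state.mappings.cand_idx]
        state.posterior_probs = state.posterior_probs[rec_keep]
        state.candidates = [c for c, k in zip(state.candidates, keep) if k]
        priors = priors[keep]
    # guard against floating drift; the deviation is asserted elsewhere
    priors = priors / priors.sum()
    for c, p in zip(state.candidates, priors):
        c.prior = float(p)
    return priors


def m_step_consensus(state: EMState) -> int:
    """Re-estimate base probabilities and consensus; return nt changes.

    Positions with at least one aligned read base get the
    posterior-weighted, quality-adjusted base distribution; positions
    with zero coverage retain their previous row.  Consensus ties are
    broken by the previous consensus base, then alphabetically.
    """
    m = state.mappings
    if m is None or state.posterior_probs is None:
        raise RuntimeError("run the E-step first")
    cands = state.candidates
    off, P = _cand_concat(cands)
    total_len = int(off[-1])
    delta = np.zeros(total_len * 4, dtype=np.float64)
    uni = np.zeros(total_len, dtype=np.float64)
    cov = np.zeros(total_len, dtype=np.int64)
    w = state.posterior_probs
    for sel, ref_pos, codes, perr, mask in _iter_mate_groups(state.bank, m):
        gpos = off[m.cand_idx[sel]][:, None] + ref_pos
        gpos = np.where(mask, gpos, 0)
        flat = gpos[mask]
        wsel = np.broadcast_to(w[sel][:, None], mask.shape)[mask]
        pm = perr[mask]
        cm = np.minimum(codes, 3)[mask]
        uni += np.bincount(flat, weights=wsel * pm / 3.0, minlength=total_len)
        delta += np.bincount(
            flat * 4 + cm,
            weights=wsel * (1.0 - 4.0 * pm / 3.0),
            minlength=total_len * 4,
        )
        cov += np.bincount(flat, minlength=total_len)
    M = delta.reshape(-1, 4) + uni[:, None]
    rowsum = M.sum(axis=1)
    covered = (cov > 0) & (rowsum > 0)
    newP = P.copy()
    newP[covered] = M[covered] / rowsum[covered, None]
    changes = 0
    for i, c in enumerate(cands):
        rows = newP[off[i] : off[i + 1]]
        prev = c._cons_codes
        rmax = rows.max(axis=1)
        cons = np.argmax(rows, axis=1).astype(np.int8)  # first max = alphabetical
        tie_prev = rows[np.arange(len(rows)), prev] >= rmax
        cons = np.where(tie_prev, prev, cons).astype(np.int8)
        changes += int((cons != prev).sum())
        c.base_probs = rows.copy()
        c.coverage = cov[off[i] : off[i + 1]].copy()
        c._cons_codes = cons
    return changes


def merge_pass(state: EMState, merge_id: float = 0.97) -> int:
    """Absorb pairs of candidates above ``merge_id`` ungapped identity.

    Pairs are examined highest-prior-first; the lower-prior member is
    absorbed (priors summed, survivor keeps its base probabilities) and
    chains are handled by re-checking after every merge.  Returns the
    number of consensus nucleotides removed from the active set, as an
    edit-distance proxy for the sequence change a merge represents.
    """
    changes = 0
    merged = True
    while merged and len(state.candidates) > 1:
        merged = False
        order = sorted(
            range(len(state.candidates)),
            key=lambda i: -state.candidates[i].prior,
        )
        for ai in range(len(order)):
            for bi in range(ai + 1, len(order)):
                a = state.candidates[order[ai]]
                b = state.candidates[order[bi]]
                if identity_ungapped(a.consensus, b.consensus) > merge_id:
                    changes += edit_distance(a.consensus, b.consensus)
                    a.prior += b.prior
                    _drop_candidate(state, order[bi])
                    merged = True
                    break
            if merged:
                break
    return changes


def _drop_candidate(state: EMState, idx: int) -> None:
    state.candidates.pop(idx)
    m = state.mappings
    if m is not None:
        keep = m.cand_idx != idx
        state.mappings = m.take(np.flatnonzero(keep))
        state.mappings.cand_idx = np.where(
            state.mappings.cand_idx > idx,
            state.mappings.cand_idx - 1,
            state.mappings.cand_idx,
        )
        if state.posterior_probs is not None:
            state.posterior_probs = state.posterior_probs[keep]


def split_pass(
    state: EMState, minor_prob: float = 0.10, site_frac: float = 0.04
) -> int:
    """Duplicate candidates that show evidence of two strains.

    A candidate splits when strictly more than ``site_frac`` of its
    positions have a second-most-probable base with probability strictly
    greater than ``minor_prob``.  The twin takes the minor base at those
    positions with near-certain (delta-like) rows there, and the prior
    is divided in proportion to the mean major/minor probabilities over
    the variant positions.  Returns nucleotides changed (the twin's
    variant positions).
    """
    changes = 0
    new_cands: list[CandidateSequence] = []
    for c in state.candidates:
        P = c.base_probs
        part = np.partition(P, 2, axis=1)
        second = part[:, 2]  # second-highest value per row
        variant = second > minor_prob
        n_var = int(variant.sum())
        if n_var == 0 or n_var / len(c) <= site_frac:
            continue
        order = np.argsort(P, axis=1)
        major = c._cons_codes
        minor = order[:, 2].astype(np.int8)
        # where the tie-broken consensus is not the literal argmax, the
        # "second" base is the argmax itself
        minor = np.where(minor == major, order[:, 3].astype(np.int8), minor)
        twin_codes = major.copy()
        twin_codes[variant] = minor[variant]
        twinP = P.copy()
        rows = np.full((n_var, 4), _SPLIT_EPS / 3.0)
        rows[np.arange(n_var), twin_codes[variant]] = 1.0 - _SPLIT_EPS
        twinP[variant] = rows
        w_major = float(P[variant, major[variant]].mean())
        w_minor = float(P[variant, minor[variant]].mean())
        share = w_minor / (w_major + w_minor)
        state._split_counter += 1
        twin = CandidateSequence(
            f"{c.id}|s{state._split_counter}", twinP, prior=c.prior * share
        )
        twin._cons_codes = twin_codes
        twin.coverage = c.coverage.copy()
        c.prior *= 1.0 - share
        new_cands.append(twin)
        changes += n_var
    state.candidates.extend(new_cands)
    return changes


def total_log_likelihood(state: EMState) -> float:
    """Observed-data log likelihood sum_r log sum_s Pr(r|s) Pr(s) under the
    current mapping set (absent candidates contribute exactly zero)."""
    m = state.mappings
    ll = _records_loglik(state.bank, m, state.candidates)
    logpost = ll + np.log(state.priors)[m.cand_idx]
    starts, ends = _group_bounds(m.pair_idx)
    seg = np.repeat(np.arange(len(starts)), ends - starts)
    gmax = np.maximum.reduceat(logpost, starts)
    s = np.add.reduceat(np.exp(logpost - gmax[seg]), starts)
    return float((gmax + np.log(s)).sum())


# ---------------------------------------------------------------------------
# initialization and the outer loop


def initialize(
    pairs,
    refs,
    policy: MappingPolicy,
    seed: int = 0,
) -> EMState:
    """Hard-assign each read to its single best reference and run one M-step.

    Equal-best placements are resolved uniformly at random (seeded); the
    chosen candidate gets posterior 1 for that read.  References with no
    assigned reads are dropped.
    """
    bank = pairs if isinstance(pairs, ReadBank) else ReadBank(list(pairs))
    refbank = refs if isinstance(refs, RefBank) else RefBank(refs)
    rng = np.random.default_rng(seed)
    arrays = map_arrays(bank, refbank, policy)
    arrays = select_best_single(arrays, rng)
    if len(arrays) == 0:
        raise RuntimeError("no reads mapped to the reference database")
    active = np.unique(arrays.cand_idx)
    new_idx = np.full(refbank.n, -1, dtype=np.int64)
    new_idx[active] = np.arange(len(active))
    arrays.cand_idx = new_idx[arrays.cand_idx]
    cands = [
        CandidateSequence.from_sequence(refbank.ids[a], refbank.seqs[a])
        for a in active
    ]
    state = EMState(candidates=cands, bank=bank)
    state.mappings = arrays
    state.posterior_probs = np.ones(len(arrays), dtype=np.float64)
    state.J = len(np.unique(arrays.pair_idx))
    m_step_priors(state)
    m_step_consensus(state)
    return state


@dataclass
class RunResult:
    """Converged (or iteration-capped) reconstruction output."""

    state: EMState
    iterations: list[dict]
    converged: bool
    report_threshold: float = 0.0

    @property
    def candidates(self) -> list[CandidateSequence]:
        return sorted(self.state.candidates, key=lambda c: -c.prior)

    def reported(self) -> list[CandidateSequence]:
        return [c for c in self.candidates if c.prior >= self.report_threshold]

    def write_fasta(self, path) -> None:
        recs = [
            (f"ssuem_{k} prior={c.prior:.6f} length={len(c)}", c.consensus)
            for k, c in enumerate(self.reported(), 1)
        ]
        write_fasta(recs, path)

    def prior_trajectory(self):
        """Per-iteration prior table (iteration x candidate id)."""
        import pandas as pd

        rows = {}
        for it in self.iterations:
            rows[it["iteration"]] = it["priors"]
        return pd.DataFrame(rows).T.fillna(0.0)

    def nt_change_trajectory(self) -> list[int]:
        return [it["nt_changes"] for it in self.iterations]

    def probability_track(self, candidate_id: str):
        """Per-position base probabilities of one candidate (4-column frame)."""
        import pandas as pd

        for c in self.state.candidates:
            if c.id == candidate_id:
                return pd.DataFrame(c.base_probs, columns=list(_BASES))
        raise KeyError(candidate_id)


def run(
    pairs,
    refs,
    policy: MappingPolicy,
    max_iter: int = 40,
    report_threshold: float = 0.0,
    merge_id: float = 0.97,
    split_minor_prob: float = 0.10,
    split_site_frac: float = 0.04,
    seed: int = 0,
    check_invariants: bool = False,
    initial_mappings: MappingArrays | None = None,
    progress: bool = False,
) -> RunResult:
    """Iterate map -> E-step -> M-step -> merge -> split until no consensus
    base changes, or ``max_iter`` iterations.

    ``initial_mappings`` substitutes the initialization mapping (e.g.
    converted from an external mapper's SAM); subsequent iterations
    always remap internally against the updated consensus sequences.
    """
    bank = pairs if isinstance(pairs, ReadBank) else ReadBank(list(pairs))
    refbank = refs if isinstance(refs, RefBank) else RefBank(refs)
    if initial_mappings is not None:
        state = _initialize_from_mappings(bank, refbank, initial_mappings, seed)
    else:
        state = initialize(bank, refbank, policy, seed=seed)
    iter_policy = (
        policy
        if policy.report_mode == "all_top_stratum"
        else MappingPolicy(
            **{**policy.__dict__, "report_mode": "all_top_stratum"}
        )
    )
    log: list[dict] = []
    converged = False
    for it in range(1, max_iter + 1):
        state.iteration = it
        iter_refs = RefBank([(c.id, c.consensus) for c in state.candidates])
        mappings = map_arrays(bank, iter_refs, iter_policy)
        if len(mappings) == 0:
            raise RuntimeError("no reads mapped")
        e_step(state, mappings)
        m_step_priors(state)
        changes = m_step_consensus(state)
        changes += merge_pass(state, merge_id)
        changes += split_pass(state, split_minor_prob, split_site_frac)
        state.nt_changes_last_iter = changes
        if check_invariants:
            state.check_invariants()
        log.append(
            {
                "iteration": it,
                "nt_changes": changes,
                "J": state.J,
                "n_candidates": len(state.candidates),
                "priors": {c.id: c.prior for c in state.candidates},
            }
        )
        if progress:
            print(
                f"iteration {it}: {changes} nt changes, "
                f"{len(state.candidates)} candidates, J={state.J}"
            )
        if changes == 0:
            converged = True
            break
    return RunResult(state, log, converged, report_threshold)


def _initialize_from_mappings(
    bank: ReadBank, refbank: RefBank, arrays: MappingArrays, seed: int
) -> EMState:
    """Initialization from externally supplied placements (SAM adapter)."""
    order = np.argsort(arrays.pair_idx, kind="stable")
    arrays = arrays.take(order)
    arrays = select_best_single(arrays, np.random.default_rng(seed))
    if len(arrays) == 0:
        raise RuntimeError("no reads mapped to the reference database")
    active = np.unique(arrays.cand_idx)
    new_idx = np.full(refbank.n, -1, dtype=np.int64)
    new_idx[active] = np.arange(len(active))
    arrays.cand_idx = new_idx[arrays.cand_idx]
    cands = [
        CandidateSequence.from_sequence(refbank.ids[a], refbank.seqs[a])
        for a in active
    ]
    state = EMState(candidates=cands, bank=bank)
    state.mappings = arrays
    state.posterior_probs = np.ones(len(arrays), dtype=np.float64)
    state.J = len(np.unique(arrays.pair_idx))
    m_step_priors(state)
    m_step_consensus(state)
    return state
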