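"""EM core: emission model, E-step, M-step, merge/split, convergence."""

import numpy as np
import pytest

from ssuem import (
    CandidateSequence,
    EMState,
    MappingPolicy,
    MappingRecord,
    base_emission_prob,
    e_step,
    initialize,
    m_step_consensus,
    m_step_priors,
    merge_pass,
    read_likelihood,
    run,
    simulate_reads,
    split_pass,
    total_log_likelihood,
)
from ssuem.align import identity_ungapped, revcomp
from ssuem.mapper import MappingArrays, ReadBank, RefBank, map_arrays
from ssuem.refdb import ReferenceSet, mutate_db

import oracles
from conftest import make_pair, make_read, mutate_seq, random_seq


def delta(base: str) -> np.ndarray:
    row = np.zeros(4)
    row["ACGT".index(base)] = 1.0
    return row


def build_state(items, candidates, records, priors):
    """Assemble an EMState from explicit components.

    ``records``: list of dicts with read_index, cand_index, start1,
    strand1 ('+'/'-'), and optionally start2 (strand2 implied opposite).
    Must be grouped by read_index.
    """
    bank = ReadBank(items)
    for c, p in zip(candidates, priors):
        c.prior = p
    strands = {"+": 0, "-": 1}
    state = EMState(candidates=list(candidates), bank=bank)
    state.mappings = MappingArrays(
        pair_idx=np.array([r["read_index"] for r in records], dtype=np.int64),
        cand_idx=np.array([r["cand_index"] for r in records], dtype=np.int64),
        start1=np.array([r["start1"] for r in records], dtype=np.int64),
        strand1=np.array([strands[r.get("strand1", "+")] for r in records], dtype=np.int8),
        start2=np.array([r.get("start2", -1) for r in records], dtype=np.int64),
        mm=np.zeros(len(records), dtype=np.int64),
        paired=bank.paired,
    )
    return state


class TestEmissionModel:
    def test_match_against_certain_reference(self):
        assert base_emission_prob("A", 0.3, delta("A")) == pytest.approx(0.7)

    def test_mismatch_splits_error_three_ways(self):
        assert base_emission_prob("C", 0.3, delta("A")) == pytest.approx(0.1)

    def test_mixture_reference_row(self):
        dist = np.array([0.5, 0.5, 0.0, 0.0])
        assert base_emission_prob("A", 0.3, dist) == pytest.approx(0.4)

    def test_n_base_is_uniform_quarter(self):
        for dist in (delta("A"), np.array([0.1, 0.2, 0.3, 0.4])):
            assert base_emission_prob("N", 0.75, dist) == pytest.approx(0.25)


class TestReadLikelihood:
    def test_two_base_product(self):
        # p = (0.1, 0.01): both matching -> 0.9 * 0.99
        read = make_read("AC", quals=[10, 20])
        cand = CandidateSequence("c", np.array([delta("A"), delta("C")]))
        rec = MappingRecord("r1", "single", "c", 0, "+", 0)
        ll = read_likelihood(read, rec, cand)
        assert np.exp(ll) == pytest.approx(0.9 * 0.99, rel=1e-12)

    def test_perfect_match_limit(self):
        read = make_read("ACGT", quals=93)  # p ~ 5e-10
        cand = CandidateSequence("c", np.array([delta(b) for b in "ACGT"]))
        rec = MappingRecord("r1", "single", "c", 0, "+", 0)
        assert np.exp(read_likelihood(read, rec, cand)) == pytest.approx(1.0, abs=1e-8)

    def test_pair_likelihood_is_product_of_mates(self):
        seq = "ACGTACGTAC"
        cand = CandidateSequence.from_sequence("c", seq)
        pair = make_pair(seq[:4], revcomp(seq[6:]), quals=15)
        prec = MappingRecord("p1", "pair", "c", 0, "+", 0, start2=6, strand2="-")
        ll_pair = read_likelihood(pair, prec, cand)
        ll1 = read_likelihood(pair.read1, MappingRecord("a", "single", "c", 0, "+", 0), cand)
        r2 = make_read(revcomp(pair.read2.bases), quals=pair.read2.quals[::-1])
        ll2 = read_likelihood(r2, MappingRecord("b", "single", "c", 6, "+", 0), cand)
        assert ll_pair == pytest.approx(ll1 + ll2, rel=1e-12)


class TestEStep:
    def _one_base_state(self, priors):
        # read 'A' (Q=5): lik vs delta(A) = 1-p, vs delta(C) = p/3
        read = make_read("A", quals=5)
        cands = [
            CandidateSequence("X", delta("A")[None, :]),
            CandidateSequence("Y", delta("C")[None, :]),
        ]
        records = [
            {"read_index": 0, "cand_index": 0, "start1": 0},
            {"read_index": 0, "cand_index": 1, "start1": 0},
        ]
        return build_state([read], cands, records, priors)

    def test_uniform_prior_posterior_is_likelihood_ratio(self):
        state = self._one_base_state([0.5, 0.5])
        table = e_step(state)
        p = 10 ** -0.5
        expected_x = (1 - p) / ((1 - p) + p / 3)
        assert state.posterior_probs[0] == pytest.approx(expected_x, rel=1e-12)
        assert state.posterior_probs.sum() == pytest.approx(1.0)
        assert table.get("r1", "X") == pytest.approx(expected_x, rel=1e-12)

    def test_informative_prior_reweights(self):
        state = self._one_base_state([0.8, 0.2])
        e_step(state)
        p = 10 ** -0.5
        num = 0.8 * (1 - p)
        expected_x = num / (num + 0.2 * p / 3)
        assert state.posterior_probs[0] == pytest.approx(expected_x, rel=1e-12)

    def test_single_mapping_read_has_posterior_one(self):
        read = make_read("A", quals=5)
        cands = [CandidateSequence("X", delta("A")[None, :])]
        state = build_state(
            [read], cands, [{"read_index": 0, "cand_index": 0, "start1": 0}], [1.0]
        )
        e_step(state)
        assert state.posterior_probs[0] == 1.0

    def test_absent_pairs_are_exactly_zero(self):
        state = self._one_base_state([0.5, 0.5])
        table = e_step(state)
        assert table.get("r1", "nonexistent") == 0.0
        assert table.get("ghost_read", "X") == 0.0


class TestMStep:
    def test_priors_hard_assignment(self):
        reads = [make_read("A", quals=20, rid=f"r{i}") for i in range(4)]
        cands = [CandidateSequence("X", delta("A")[None, :])]
        records = [
            {"read_index": i, "cand_index": 0, "start1": 0} for i in range(4)
        ]
        state = build_state(reads, cands, records, [1.0])
        e_step(state)
        priors = m_step_priors(state)
        assert priors[0] == pytest.approx(1.0)

    def test_priors_from_given_posteriors(self):
        # reads {1.0 on X} and {0.25 X, 0.75 Y} -> (0.625, 0.375)
        reads = [make_read("A", quals=20, rid=f"r{i}") for i in range(2)]
        cands = [
            CandidateSequence("X", delta("A")[None, :]),
            CandidateSequence("Y", delta("A")[None, :]),
        ]
        records = [
            {"read_index": 0, "cand_index": 0, "start1": 0},
            {"read_index": 1, "cand_index": 0, "start1": 0},
            {"read_index": 1, "cand_index": 1, "start1": 0},
        ]
        state = build_state(reads, cands, records, [0.5, 0.5])
        state.posterior_probs = np.array([1.0, 0.25, 0.75])
        state.J = 2
        priors = m_step_priors(state)
        assert priors == pytest.approx([0.625, 0.375])

    def test_priors_symmetric_split(self):
        reads = [make_read("A", quals=20, rid=f"r{i}") for i in range(2)]
        cands = [
            CandidateSequence("X", delta("A")[None, :]),
            CandidateSequence("Y", delta("A")[None, :]),
        ]
        records = [
            {"read_index": i, "cand_index": c, "start1": 0}
            for i in range(2)
            for c in range(2)
        ]
        state = build_state(reads, cands, records, [0.5, 0.5])
        e_step(state)
        priors = m_step_priors(state)
        assert priors == pytest.approx([0.5, 0.5])

    def test_zero_mass_candidate_is_pruned(self):
        reads = [make_read("A", quals=20)]
        cands = [
            CandidateSequence("X", delta("A")[None, :]),
            CandidateSequence("Y", delta("C")[None, :]),
        ]
        records = [{"read_index": 0, "cand_index": 0, "start1": 0}]
        state = build_state(reads, cands, records, [0.5, 0.5])
        e_step(state)
        m_step_priors(state)
        assert [c.id for c in state.candidates] == ["X"]
        assert state.candidates[0].prior == 1.0

    def test_consensus_single_read_quality_weighted(self):
        # one read, posterior 1, base A with p = 0.01 -> Pr(A) = 0.99
        read = make_read("A", quals=20)
        cands = [CandidateSequence("X", delta("C")[None, :])]
        state = build_state(
            [read], cands, [{"read_index": 0, "cand_index": 0, "start1": 0}], [1.0]
        )
        e_step(state)
        m_step_priors(state)
        changes = m_step_consensus(state)
        row = state.candidates[0].base_probs[0]
        assert row[0] == pytest.approx(0.99, rel=1e-12)
        assert row[1:] == pytest.approx([0.01 / 3] * 3, rel=1e-12)
        assert state.candidates[0].consensus == "A"
        assert changes == 1

    def test_consensus_tie_breaks_to_previous_base(self):
        # two reads, equal quality, bases A and C; previous consensus C wins
        reads = [make_read("A", quals=20, rid="r0"), make_read("C", quals=20, rid="r1")]
        cands = [CandidateSequence("X", delta("C")[None, :])]
        records = [
            {"read_index": 0, "cand_index": 0, "start1": 0},
            {"read_index": 1, "cand_index": 0, "start1": 0},
        ]
        state = build_state(reads, cands, records, [1.0])
        e_step(state)
        m_step_priors(state)
        changes = m_step_consensus(state)
        row = state.candidates[0].base_probs[0]
        assert row[0] == pytest.approx(row[1])
        assert state.candidates[0].consensus == "C"
        assert changes == 0

    def test_zero_coverage_positions_retain_previous_row(self):
        read = make_read("A", quals=20)
        probs = np.array([delta("C"), np.array([0.1, 0.2, 0.3, 0.4])])
        cands = [CandidateSequence("X", probs.copy())]
        state = build_state(
            [read], cands, [{"read_index": 0, "cand_index": 0, "start1": 0}], [1.0]
        )
        e_step(state)
        m_step_priors(state)
        m_step_consensus(state)
        assert state.candidates[0].base_probs[1] == pytest.approx([0.1, 0.2, 0.3, 0.4])
        assert state.candidates[0].coverage[0] == 1
        assert state.candidates[0].coverage[1] == 0


class TestMergeSplit:
    def _state_with(self, seqs_priors):
        cands = [
            CandidateSequence.from_sequence(f"c{i}", s)
            for i, (s, _) in enumerate(seqs_priors)
        ]
        for c, (_, p) in zip(cands, seqs_priors):
            c.prior = p
        bank = ReadBank([make_read("A" * 20)])
        return EMState(candidates=cands, bank=bank)

    def test_identical_candidates_merge_and_sum_priors(self, rng):
        seq = random_seq(rng, 1500)
        state = self._state_with([(seq, 0.7), (seq, 0.3)])
        merge_pass(state)
        assert len(state.candidates) == 1
        assert state.candidates[0].prior == pytest.approx(1.0)
        assert state.candidates[0].id == "c0"  # higher prior survives

    def test_96_percent_identity_is_not_merged(self, rng):
        a = random_seq(rng, 1500)
        b = mutate_seq(a, 60, rng)  # 96.0%: not greater than 97%
        state = self._state_with([(a, 0.6), (b, 0.4)])
        merge_pass(state)
        assert len(state.candidates) == 2

    def test_98_percent_identity_is_merged(self, rng):
        a = random_seq(rng, 1500)
        b = mutate_seq(a, 30, rng)  # 98.0% > 97%
        state = self._state_with([(a, 0.6), (b, 0.4)])
        changes = merge_pass(state)
        assert len(state.candidates) == 1
        assert state.candidates[0].prior == pytest.approx(1.0)
        assert changes == 30

    def test_transitive_chain_merges(self, rng):
        # b sits between a and c (98% to each, a-c only ~96%); with b as
        # the highest-prior survivor the chain collapses to one candidate
        a = random_seq(rng, 1000)
        b = mutate_seq(a, 20, rng)
        c = mutate_seq(b, 20, rng)
        state = self._state_with([(a, 0.3), (b, 0.5), (c, 0.2)])
        merge_pass(state)
        assert len(state.candidates) == 1
        assert state.candidates[0].id == "c1"
        assert state.candidates[0].prior == pytest.approx(1.0)

    def _ambiguous_candidate(self, L=100, n_variant=5, minor=0.2):
        probs = np.tile(delta("A"), (L, 1))
        for i in range(n_variant):
            probs[i] = [1 - minor, minor, 0.0, 0.0]
        c = CandidateSequence("amb", probs)
        c.prior = 1.0
        return c

    def test_split_above_site_fraction(self):
        state = EMState([self._ambiguous_candidate(n_variant=5)],
                        ReadBank([make_read("A" * 20)]))
        changed = split_pass(state, minor_prob=0.10, site_frac=0.04)
        assert len(state.candidates) == 2
        assert changed == 5
        twin = state.candidates[1]
        assert twin.consensus[:5] == "C" * 5
        assert twin.consensus[5:] == "A" * 95
        # prior divided by mean major/minor ratio: 0.8 / 0.2
        assert state.candidates[0].prior == pytest.approx(0.8)
        assert twin.prior == pytest.approx(0.2)
        # twin rows are delta-like at variant positions
        assert twin.base_probs[0, 1] == pytest.approx(0.99)

    def test_exactly_at_site_fraction_does_not_split(self):
        state = EMState([self._ambiguous_candidate(n_variant=4)],
                        ReadBank([make_read("A" * 20)]))
        split_pass(state, minor_prob=0.10, site_frac=0.04)
        assert len(state.candidates) == 1

    def test_delta_rows_never_split(self, rng):
        c = CandidateSequence.from_sequence("pure", random_seq(rng, 200))
        c.prior = 1.0
        state = EMState([c], ReadBank([make_read("A" * 20)]))
        split_pass(state)
        assert len(state.candidates) == 1

    def test_split_then_merge_returns_prior_mass(self):
        # 2 variant positions on L=100: split at site_frac 0.01, the twin
        # is 98% identical, so a 0.97 merge recovers the original mass
        state = EMState([self._ambiguous_candidate(n_variant=2)],
                        ReadBank([make_read("A" * 20)]))
        split_pass(state, minor_prob=0.10, site_frac=0.01)
        assert len(state.candidates) == 2
        merge_pass(state, merge_id=0.97)
        assert len(state.candidates) == 1
        assert state.candidates[0].prior == pytest.approx(1.0, abs=1e-9)


class TestOracleEquivalence:
    """One full E+M iteration against direct evaluation of the formulas."""

    def _random_instance(self, seed, paired):
        rng = np.random.default_rng(seed)
        n_cands, L = 3, 60
        cands = []
        for ci in range(n_cands):
            probs = rng.dirichlet(np.ones(4) * 2, size=L)
            cands.append(CandidateSequence(f"c{ci}", probs))
        read_len = 12
        items, records = [], []
        n_items = 15 if paired else 30
        for i in range(n_items):
            if paired:
                b1 = "".join(rng.choice(list("ACGT"), read_len))
                b2 = "".join(rng.choice(list("ACGT"), read_len))
                items.append(make_pair(b1, b2, quals=list(rng.integers(3, 40, read_len)),
                                       rid=f"p{i}"))
            else:
                bases = "".join(rng.choice(list("ACGT"), read_len))
                items.append(make_read(bases, quals=list(rng.integers(3, 40, read_len)),
                                       rid=f"r{i}"))
            for ci in sorted(rng.choice(n_cands, size=rng.integers(1, 4), replace=False)):
                rec = {
                    "read_index": i,
                    "cand_index": int(ci),
                    "cand_id": f"c{ci}",
                    "start1": int(rng.integers(0, L - read_len + 1)),
                    "strand1": "+-"[rng.integers(2)],
                }
                if paired:
                    rec["start2"] = int(rng.integers(0, L - read_len + 1))
                    rec["strand2"] = "-" if rec["strand1"] == "+" else "+"
                records.append(rec)
        priors = rng.dirichlet(np.ones(n_cands))
        return items, cands, records, priors

    @pytest.mark.parametrize("paired", [False, True], ids=["single", "paired"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_e_and_m_step_match_brute_force(self, seed, paired):
        items, cands, records, priors = self._random_instance(seed, paired)
        state = build_state(items, cands, records, list(priors))
        e_step(state)
        oracle_post, oracle_priors, oracle_probs, oracle_cons = oracles.em_iteration(
            items,
            {c.id: c.base_probs.tolist() for c in cands},
            records,
            {f"c{i}": priors[i] for i in range(len(cands))},
        )
        np.testing.assert_allclose(state.posterior_probs, oracle_post, atol=1e-9)
        m_step_priors(state)
        got_priors = {c.id: c.prior for c in state.candidates}
        for cid, p in oracle_priors.items():
            assert got_priors.get(cid, 0.0) == pytest.approx(p, abs=1e-9)
        m_step_consensus(state)
        for c in state.candidates:
            np.testing.assert_allclose(
                c.base_probs, oracle_probs[c.id], atol=1e-9
            )
            assert c.consensus == oracle_cons[c.id]


class TestConvergenceProperties:
    def test_frozen_mapping_log_likelihood_is_monotone(self, small_community):
        sim = simulate_reads(
            small_community, n_pairs=400, read_len=40,
            insert_mean=120, insert_sd=10, seed=9,
        )
        refs = [(m.name, m.sequence) for m in small_community]
        db, _ = mutate_db(ReferenceSet(refs), fraction=0.05, seed=1)
        policy = MappingPolicy(insert_median=120, insert_sd=10)
        bank = ReadBank(sim.pairs)
        state = initialize(bank, RefBank(list(db)), policy, seed=3)
        mappings = map_arrays(
            bank, RefBank([(c.id, c.consensus) for c in state.candidates]), policy
        )
        e_step(state, mappings)
        prev = None
        for _ in range(6):
            ll = total_log_likelihood(state)
            if prev is not None:
                assert ll >= prev - 1e-9
            prev = ll
            e_step(state)
            m_step_priors(state)
            m_step_consensus(state)

    def test_initialize_single_reference(self, rng):
        ref = random_seq(rng, 400)
        other = random_seq(rng, 400)
        pairs = [
            make_pair(ref[s : s + 40], revcomp(ref[s + 80 : s + 120]), rid=f"p{i}")
            for i, s in enumerate(range(0, 280, 10))
        ]
        policy = MappingPolicy(insert_median=120, insert_sd=10)
        state = initialize(pairs, [("truth", ref), ("decoy", other)], policy, seed=0)
        assert [c.id for c in state.candidates] == ["truth"]
        assert state.candidates[0].prior == pytest.approx(1.0)

    def test_initial_priors_are_assignment_fractions(self, rng):
        a, b = random_seq(rng, 400), random_seq(rng, 400)
        pairs = []
        for i in range(6):
            s = 10 * i
            pairs.append(make_pair(a[s : s + 40], revcomp(a[s + 80 : s + 120]), rid=f"pa{i}"))
        for i in range(2):
            s = 10 * i
            pairs.append(make_pair(b[s : s + 40], revcomp(b[s + 80 : s + 120]), rid=f"pb{i}"))
        policy = MappingPolicy(insert_median=120, insert_sd=10)
        state = initialize(pairs, [("A", a), ("B", b)], policy, seed=0)
        priors = {c.id: c.prior for c in state.candidates}
        assert priors["A"] == pytest.approx(6 / 8)
        assert priors["B"] == pytest.approx(2 / 8)

    def test_initialize_deterministic(self, small_community):
        sim = simulate_reads(
            small_community, n_pairs=200, read_len=40,
            insert_mean=120, insert_sd=10, seed=21,
        )
        refs = [(m.name, m.sequence) for m in small_community]
        policy = MappingPolicy(insert_median=120, insert_sd=10)
        s1 = initialize(sim.pairs, refs, policy, seed=5)
        s2 = initialize(sim.pairs, refs, policy, seed=5)
        assert [c.id for c in s1.candidates] == [c.id for c in s2.candidates]
        for c1, c2 in zip(s1.candidates, s2.candidates):
            assert c1.prior == c2.prior
            assert c1.consensus == c2.consensus

    def test_run_recovers_single_reference(self, rng):
        ref = random_seq(rng, 400)
        member_pairs = [
            make_pair(ref[s : s + 40], revcomp(ref[s + 80 : s + 120]), rid=f"p{i}")
            for i, s in enumerate(list(range(0, 281, 2)) * 3)
        ]
        policy = MappingPolicy(insert_median=120, insert_sd=10)
        result = run(member_pairs, [("db", ref)], policy, seed=1)
        assert result.converged
        assert result.candidates[0].prior == pytest.approx(1.0)
        assert result.candidates[0].consensus == ref

    def test_run_corrects_mutated_database(self, small_community):
        """Reads from the truth against a 10%-mutated database: the final
        consensus must be far closer to the truth than the 90% start."""
        sim = simulate_reads(
            small_community, n_pairs=2500, read_len=50,
            insert_mean=130, insert_sd=10, seed=31,
        )
        refs = ReferenceSet([(m.name, m.sequence) for m in small_community])
        db, _ = mutate_db(refs, fraction=0.10, seed=8)
        policy = MappingPolicy(insert_median=130, insert_sd=10)
        result = run(sim.pairs, list(db), policy, seed=2, check_invariants=True)
        assert result.converged
        truth = {m.name: m.sequence for m in small_community}
        for member in small_community:
            best = max(
                identity_ungapped(c.consensus, truth[member.name])
                for c in result.candidates
            )
            assert best > 0.97  # far above the 0.90 identity of the start

    def test_nt_changes_reach_zero(self, small_community):
        sim = simulate_reads(
            small_community, n_pairs=1200, read_len=50,
            insert_mean=130, insert_sd=10, seed=41,
        )
        refs = ReferenceSet([(m.name, m.sequence) for m in small_community])
        db, _ = mutate_db(refs, fraction=0.05, seed=9)
        policy = MappingPolicy(insert_median=130, insert_sd=10)
        result = run(sim.pairs, list(db), policy, seed=3)
        traj = result.nt_change_trajectory()
        assert result.converged
        assert traj[-1] == 0
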