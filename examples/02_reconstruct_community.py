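"""Reconstruct SSU genes and abundances from reads with a corrupted database.

The search database is the community's own genes with 10% of sites
randomly mutated — the reconstruction must therefore correct roughly
one site in ten while estimating abundances.  Prints the per-iteration
convergence log and the recovered abundances next to the truth.
"""

from ssuem import (
    MappingPolicy,
    ReferenceSet,
    expected_ssu_abundance,
    match_and_correlate,
    mutate_db,
    random_community,
    run,
    simulate_reads,
    trim_and_filter,
)

members = random_community(
    [0.5, 0.3, 0.2], gene_len=1500, divergence=0.05, seed=11
)
truth = expected_ssu_abundance(members)

db = ReferenceSet([(m.name, m.sequence) for m in members])
mutated, log = mutate_db(db, fraction=0.10, seed=12)
print(f"database corrupted at {len(log)} sites "
      f"({len(log) / sum(len(s) for _, s in db):.0%} of all positions)")

sim = simulate_reads(
    members, n_pairs=10_000, read_len=76, insert_mean=200, insert_sd=25,
    seed=13, pad_len=1000,
)
pairs = list(trim_and_filter(sim.pairs))

policy = MappingPolicy(insert_median=200, insert_sd=25)
result = run(pairs, list(mutated), policy, seed=14, progress=True)

print(f"\nconverged: {result.converged} "
      f"({len(result.iterations)} iterations)")
comparison = match_and_correlate(
    truth,
    {m.name: m.sequence for m in members},
    [(c.id, c.consensus, c.prior) for c in result.candidates],
)
print(comparison.pairs[["truth_name", "truth_abund", "estimated_prior", "identity"]]
      .to_string(index=False))
print(f"\nPearson r between estimated and true abundances: "
      f"{comparison.pearson_r:.4f}")
# identity ~1.0 means the 10% database corruption was corrected away;
# estimated_prior is the model's abundance estimate for each member.
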