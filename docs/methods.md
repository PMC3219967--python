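# Methods

## Model and procedure

`ssuem` treats a metagenomic read set as draws from a finite mixture of
unknown SSU gene sequences. Each mixture component (candidate) is a
probabilistic sequence — an L×4 matrix whose row k is Pr(n), the
probability that the true base at position k is n — together with a
mixture weight Pr(s), the candidate's relative abundance among
SSU-derived reads. Candidates are initialized from a reference
database, so the database supplies starting points rather than fixed
truths; every base probability is free to move as evidence accumulates.

One iteration consists of:

1. **Mapping.** Reads are placed on the current consensus sequences
   (per-position argmax bases) by the internal ungapped paired-end
   mapper. A placement is valid when each mate has at most
   `max_seed_mismatches` (3) mismatches within its first `seed_len`
   (20) stored bases, the summed Phred qualities of mismatched bases
   per mate are at most `max_qual_sum_mismatch` (300), and the pair is
   forward–reverse with an insert within `insert_tolerance_sds` (3)
   standard deviations of the expected median. All placements with the
   minimal total mismatch count (the top stratum) are reported.
2. **E-step.** Posteriors Pr(s|r) ∝ Pr(r|s)·Pr(s) over the candidates
   with reported mappings for r; all other candidates get exactly
   zero. The likelihood is a product over mapped positions of
   Σₙ Pr(bₖ|n)Pr(n), with Pr(bₖ|n)=1−pₖ on a match and pₖ/3 otherwise;
   mates multiply into one likelihood (positional independence is a
   deliberate simplification). Computation is in log space with
   per-read log-sum-exp normalization; a read whose maximum log score
   is non-finite would fall back to a uniform posterior with a counted
   warning (with pₖ ∈ (0,1] this cannot normally trigger).
3. **M-step.** Priors: Pr(s) = (1/J)·Σⱼ Pr(s|rⱼ) with J the number of
   reads (pairs) with mappings; candidates whose mass is exactly zero
   are pruned. Base probabilities: each covered position gets the
   posterior-weighted, quality-adjusted base distribution
   Σⱼ Pr(s|rⱼ)·[I·(1−pₖⱼ) + (1−I)·pₖⱼ/3], normalized over the four
   bases; positions with no aligned base retain their previous row, so
   database information persists where no reads land.
4. **Merge.** Two candidates whose consensuses exceed `merge_id`
   (0.97) identity over the non-gap columns of a global alignment are
   the same OTU: the lower-prior one is absorbed (priors summed; the
   survivor keeps its base probabilities). Pairs are examined
   highest-prior-first and re-checked after every merge so chains
   collapse through their intermediate.
5. **Split.** A candidate whose second-most-probable base exceeds
   `split_minor_prob` (0.10) at strictly more than `split_site_frac`
   (0.04) of positions carries evidence of two strains. A twin is
   created with the minor base (δ-like rows, 1−ε with ε=0.01) at those
   positions; the prior is divided in proportion to the mean
   major/minor probabilities there. Both inequalities are strict.

Initialization assigns each read to its single best placement (ties
broken uniformly at random from one seeded generator owned by the
run), sets that posterior to 1, and runs one M-step; candidates with
no assigned reads are dropped. The loop terminates when no consensus
base changes anywhere (counting merge edits and split variant
positions as changes, so a merge or split always forces another
iteration), or after `max_iter` (40) iterations. A reporting threshold
filters output only — the active set is never truncated by it.

## Internal mapper

The mapper exists so the EM loop is self-contained and deterministic.
Seeding is pigeonhole-exact: since a valid placement allows at most 3
mismatches inside the 20-bp seed region, the seed region is cut into 4
disjoint 5-mers, at least one of which must match the reference
exactly; every exact 5-mer hit proposes a diagonal that is then
verified against the full rules. The index mapper is therefore
*exhaustive* over valid placements (the test suite checks it against a
brute-force scan over all offsets and strands). Reverse-strand
placements are supported (databases contain reverse-complemented
genes); mate 2 is reverse-complemented internally and all indicators
are computed in candidate coordinates. Reads shorter than the seed
length are not supported. Alignments from an external mapper can be
supplied as SAM for the *initial* assignment (gapped or clipped
records are skipped and counted — the model is ungapped); later
iterations remap internally because the consensus changes each round.

## Read handling

Qualities are Phred+33; offset-64 input is rejected rather than
guessed. Error probabilities are 10^(−Q/10); `N` calls get p = 3/4,
which makes their emission exactly 1/4 regardless of the reference row
— present but uninformative. 3′ trimming removes the maximal trailing
run of bases with Q ≤ 2 (interior low-quality bases are kept, matching
end-degradation rather than mid-read dips); pairs are kept when both
mates are ≥ 60 bp after trimming. Short-read data sets can disable
trimming (`no_trim`).

## Reference database preparation

Full-length filtering keeps sequences of 1200–1900 bp. Clustering is
greedy, longest-first, first-fit centroid clustering at 97% identity,
with identity = matching columns / alignment columns excluding
terminal gap runs (internal gaps count against identity); alignments
come from edlib's Needleman–Wunsch path. U and lowercase are
normalized; other ambiguity codes are replaced by a seeded random
concrete base. `mutate_db` mutates exactly round(fraction·L) distinct
positions per sequence (banker's rounding) to a uniformly chosen
different base and logs every change, giving controlled
database-corruption experiments.

## Synthetic data

The simulator reproduces a wgsim-style protocol: the source member of
each fragment is drawn from the expected SSU abundance profile
(copy-number × genome-abundance, normalized), the fragment length is
round(Normal(insert_mean, insert_sd)) clamped to the read length, and
mates are the fragment ends with mate 2 reverse-complemented. Genes
may be padded with uniform random flanks (1000 bp in the benchmark) so
that, as with genomic fragments, many fragments fall partly or wholly
outside the gene. Errors are substitutions injected per base with
probability 10^(−Q/10) under an assigned quality vector; indels are
not simulated (the mapper and model are ungapped). Quality vectors
come either from real FASTQ (sampled at random) or from a parametric
Illumina-like profile: mean Q declining linearly 38→25 along the read,
Gaussian noise (sd 3), clamped to [2, 40], with 10% of reads receiving
a geometric-length Q=2 tail (mean 5 bp) mimicking degenerate base-call
tails. The parametric profile makes tests self-contained; it does not
reproduce instrument-specific cycle artifacts, GC bias, chimeric
fragments or indel errors, so passing tests demonstrate correctness of
the algorithm under its stated error model, not robustness to every
real-data pathology.

## Benchmark scenario

`ssuem.benchmark` fixes the package's validation conditions: nine
synthetic 1500-bp genes radiating from one ancestor at 5% divergence
(~10% pairwise — distinct at the 97% OTU level), expected abundances
(26.1, 18.5, 15.0, 11.5, 9.0, 7.0, 5.6, 5.0, 2.3)%, database mutated
at 10% of sites, 50,000 76-bp pairs at insert 200±25 from the padded
genes (roughly 20,000 pairs lie fully within the genes and map; about
250× coverage). Reconstructions are matched 1:1 to truth genes by
best global identity with a 97% floor (below-floor reconstructions are
"novel"); Pearson r is computed over all truth members with unmatched
members at 0. Because a converged run stops as soon as no consensus
base changes (typically 2–4 iterations at this depth), prior stability
is verified by running two additional full iterations at convergence
and taking the maximum per-candidate prior change across that
three-point window; iteration-capped runs use the last three logged
iterations instead.

## Numerical and design choices

* Likelihood math is float64 throughout; one E+M iteration matches a
  brute-force evaluation of the formulas to 1e-9 in the tests.
* Consensus ties break to the previous consensus base, then
  alphabetically — determinism and convergence stability.
* Normalization invariants (posterior rows, priors, base-probability
  rows each sum to 1 ± 1e-9) can be asserted after every iteration
  (`check_invariants=True`); priors are defensively renormalized by
  their sum to stop drift from accumulating across many iterations.
* With the mapping set frozen, the observed-data log likelihood is
  non-decreasing across EM iterations (standard guarantee; remapping
  and merge/split steps are exempt and the tests respect that).
* A read with several top-stratum placements on the *same* candidate
  contributes one record per placement; posteriors are summed per
  (read, candidate) when the table is queried.
* Weighted UniFrac is the branch-length-weighted sum of absolute
  subtree mass differences on a user-supplied rooted tree (tree
  building is out of scope); the normalized variant divides by the
  abundance-weighted maximum Σᵢ(Aᵢ+Bᵢ)·depthᵢ, and both variants are
  available because published runs do not always state which was used.
  Significance is a seeded leaf-label permutation test.

## Known limitations

Indels are invisible to the mapper and the correction model, so small
indel errors can persist in reconstructions (and homopolymer-error
platforms are out of scope). Chimeric database sequences can carry
through if reads map across the junction; database pre-screening is
assumed. SSU copy number confounds abundance at the organism level —
priors estimate gene abundance, not cell abundance. The greedy
clustering and merge rules use a single global identity cutoff; very
recently diverged strains below that cutoff are reported as one OTU
unless the split rule separates them.
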