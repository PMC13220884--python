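# Methods

`phagetrace` reconstructs the genotype-level history of a bacteriophage
population from longitudinal shotgun metagenomes, given only per-sample
allele depths at SNP positions.  This note documents the models, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## The inference problem

Short reads cannot phase SNPs that sit on different reads, so a phage
population's haplotype structure is not directly observable.  Two features
of a longitudinal serial-transfer design substitute for physical linkage:

1. **Near-clonal samples.**  A sample in which every catalogued site has
   frequency > 0.97 or < 0.03 is treated as carrying a single dominant
   genotype; its binary haplotype is read off directly (1 where the
   frequency is above the high threshold).  An all-zero haplotype is the
   reference genotype.
2. **Trajectory linkage.**  SNPs that reside on the same genome rise and
   fall together across samples.  Conversely, in a single sample where k
   variants each exceed frequency f_i, at least `max(0, Σf_i − (k−1))` of
   the population must carry all of them simultaneously (inclusion–
   exclusion; "pigeonhole linking").  We use the pairwise form (any two
   variants above 0.8 must co-occur) to propose genotypes from
   high-frequency non-clonal samples and report the k-wise bound, which is
   uninformative (0) for large marker sets.

Mixed samples are assumed to be mixtures of genotypes derived from clonal
and high-frequency evidence — the minimal-scenario assumption.  No latent
genotype search is performed; a mixed sample that cannot be explained this
way shows up as residual in the decomposition, not as a new genotype.

## Variant filtering

A sample qualifies for variant analysis when ≥ 30% of the phage genome is
covered by ≥ 10 reads.  A variant enters the catalog iff, in at least one
qualifying sample, its frequency alt/(ref+alt) is ≥ 0.10 **and** it is
supported by ≥ 4 alt reads.  All boundaries are inclusive.  Frequencies in
non-qualifying samples and at zero-depth sites are missing, not zero.
Variants whose mean site depth deviates from the genome-wide mean by more
than 5× in either direction are flagged for manual review (irregular
coverage), never removed automatically.

## Linkage groups

Variants are partitioned by complete-linkage agglomeration on the distance
`d(u,v) = max over co-observed samples |f_u − f_v|`, cut at the coupling
tolerance δ = 0.10.  Complete linkage guarantees every pair inside a group
stays within δ on co-observed samples; variant pairs with fewer than two
co-observed samples are never merged.  The max metric is deliberately
conservative for *merging*: one discordant sample separates two variants.

## Decomposition into genotype abundances

Two modes, both returning an exact probability simplex:

* **`simplex_lsq`** — non-negative least squares of f ≈ Hᵀa with a soft
  sum-to-one row (weight 100) followed by exact renormalisation, where H
  is the genotype × variant alt-allele matrix.  On consistent noise-free
  input this recovers the generating mixture to < 1e−6.
* **`paper_averaging`** — the published recipe: each non-reference
  genotype's abundance is the mean frequency of the markers exclusive to
  it *among the genotypes present in the sample*; the reference genotype
  absorbs 1 − Σ(others).  Presence is decided by exclusive markers
  exceeding δ and re-evaluated iteratively, so a marker shared by two
  genotypes is attributed to whichever is present in that time window.
  When a present genotype has no exclusive marker the sharing is ambiguous
  and the mode falls back to `simplex_lsq`.  A complement below −0.05
  raises a warning before clipping.

## Recombination detection

Within each mesocosm, an event is emitted for a pair of linkage groups at
the first sampled week where their trajectory gap exceeds the decoupling
threshold Δ = 0.30, provided at some earlier week both groups were
simultaneously segregating (each frequency inside (δ, 1−δ)) and not yet
decoupled — the signature that both parental genotypes coexisted before
their marker trajectories diverged.  Δ = 0.30 is chosen to clear binomial
sampling noise at ~100× depth by a wide margin.  The child haplotype is
proposed by rounding the frequencies at the event week.  Decoupling of the
same child haplotype in several mesocosms is reported once as a *primary*
event (earliest week); later occurrences are arrivals of an existing
genotype by migration and are flagged non-primary.

## Novel-mutation blocks

Variants that are undetected in every founding (week-0) and closed-regime
sample — "detected" requiring both frequency ≥ 0.03 and ≥ 4 supporting
reads, so a stray error read in a shallow baseline sample does not mask
novelty — yet later reach ≥ 0.10 are clustered by trajectory.  Each
cluster is compared against every genotype's abundance trajectory
(computed by `simplex_lsq` on the non-candidate backbone variants),
restricted to samples from the block's first appearance onward: the
carrier typically emerges at the same time as its block, so earlier
samples carry no signal, and the carrier may have no exclusive backbone
marker (its markers can be shared with a founder), which rules out raw
marker-trajectory comparison.  Attribution uses the *mean* absolute
trajectory distance (≤ δ): at the ~100× depth floor, the max metric is
dominated by single-sample binomial noise (sd ≈ 0.05), whereas the mean
averages it out.  Clusters matching no genotype found a new genotype of
provenance "mutational".

## Synthetic serial-transfer metacommunity

The generator emulates the experimental design end-to-end: 10 founding
communities of two compositional types (type A carries the phage natively,
type B does not), each split into a closed mesocosm and an open mesocosm;
2-week transfer cycles with 1/20 dilution over 48 weeks; sampling at weeks
0, 2, 4, 6, 8, 20, 32, 40, 48; and an MGE cocktail pooled in equal volumes
from all open mesocosms, 0.2-µm filtered (phage only, no cells), added to
every open mesocosm at 1/20 of the new volume.  Two founder genotypes
differ at 9 marker SNPs (the catalogued marker positions by default).

Within each cycle (densities are dimensionless, carrying capacity 1):

1. hosts regrow logistically, `H ← H e^g / (1 + H(e^g − 1))` with g = 6;
2. phage adsorb to the susceptible fraction σ of hosts,
   `I = σH(1 − e^{−aP})` with a = 5, partitioned among genotypes by
   abundance; each infection yields burst size β = 100 virions and removes
   the host cell; free virions persist;
3. programmed events fire: a **recombination** converts a fraction
   (default 0.5) of each parent population into a crossover child that
   carries a per-transfer fitness advantage (default 2×), optionally only
   in one community type — this is how a recombinant sweeps its home type
   while remaining a minority elsewhere; a **novel block** instantaneously
   replaces its carrier with a derived genotype carrying extra alt alleles
   at positions drawn uniformly in a configured interval (the mechanistic
   stand-in for recombination with a rare, unassembled virus);
4. sampling snapshots the grown culture; then 1/20 of cells + virions
   carries over and open mesocosms receive the cocktail.

σ = 1.0 in type A and 0.1 in type B, so the phage invades type B at
roughly an order of magnitude lower read fraction, as in the study system.

**Observation model.**  The true phage read fraction is
`P·g_p / (P·g_p + (H + B)·g_b)` with phage genome 63,535 bp, host genome
4 Mb and a non-host bacterial background B = 1.  Per-SNP depth is
Poisson(λ) with λ = `mean_depth_at_peak × fraction/peak_fraction`
(peak taken over mesocosm samples; the nearly pure-phage cocktail is
excluded from the normalisation); alt counts are
Binomial(depth, f(1−ε) + (1−f)ε) with sequencing error ε = 0.001.
Coverage breadths are computed from the Poisson model analytically
(`breadth_at_d = P(Poisson(λ) ≥ d)`), exactly consistent with the depth
model and avoiding 63,535 per-position draws per sample.
`mean_depth_at_peak` defaults to 1000× (outbreak samples in this kind of
dataset are sequenced very deeply).  Genus counts for community typing are
Dirichlet-multinomial draws around two type-specific mean profiles
(*Rhodanobacter*/*Nitrosomonas*- vs *Cellvibrio*/*Azospirillum*-dominated).

**What the generator does not emulate:** within-host coinfection and lysis
inhibition, sequence-level reads (no mapping artifacts, no GC bias),
host–phage coevolution (resistance evolution), compositional coupling
between phage load and genus counts, and real outbreak kinetics (the
dynamical parameters are illustrative, not calibrated).  Passing recovery
tests therefore demonstrate correctness of the inference given the stated
observation model, not robustness to mapping or extraction biases.

## Recovery guarantees and problem sizes

The recovery evaluation (`phagetrace.validation.evaluate_recovery`)
derives genotypes and scores abundances on qualifying samples with mean
phage depth ≥ 100× — the depth regime the guarantees address — while
event detection uses every breadth-qualifying sample, because the evidence
of early genotype coexistence often sits in moderately covered samples.
On the default scenario (20 mesocosms + cocktail, 184 samples, 70 SNPs)
it verifies, across seeds: exact reconstruction of all four study-like
genotypes, clonal haplotypes always matching a true genotype, abundance
RMSE < 0.05, programmed recombination weeks recovered within one transfer,
and ≥ 95% of novel-block SNPs attributed to the true carrier.  One full
simulate-plus-inference run takes under a second on one CPU.

## Sequence-level checks

* **DTR**: longest k with min_len ≤ k ≤ ⌊L/2⌋ whose k-bp prefix equals
  the k-bp suffix, exact matching only; the L/2 cap keeps the two copies
  disjoint (an all-A sequence of length 100 has a 50-bp DTR, not 99).
* **Circular permutation**: equal length and substring-of-doubled test.
* **Identity**: `100 × (1 − editDistance/max(len))` under global unit-cost
  alignment.  This definition is *unique* for a sequence pair — the
  matches-over-columns ratio differs between co-optimal alignments and is
  therefore not well defined.  The rotation-invariant option anchors
  candidate rotations with exact seed k-mers sampled along the first
  sequence and returns the best identity among them.
* **Rank demarcation** follows the ICTV intergenomic-similarity thresholds
  for this phage family — species ≥ 95%, genus ≥ 70%, subfamily ≥ 40%,
  inclusive — with anything lower reported as a new-subfamily candidate.
  The similarity computation itself (VIRIDIC-style) is out of scope; the
  rule consumes externally supplied percentages.

## Community profiling

Genus counts are CLR-transformed (`log(c+1)` centred per sample).
Community typing projects samples onto PC1, averages per mesocosm, and
splits at the midpoint of the largest gap between consecutive means.  The
partition is flagged unstable when that gap is below 0.7 of the PC1 span:
with genuine two-cluster structure the between-cluster gap consumes most
of the span, while the largest of n−1 gaps among unstructured means stays
well under two thirds.  Labels "A"/"B" are deterministic but arbitrary —
compare partitions, not labels.  The outbreak-resilience check compares
Bray-Curtis dissimilarities across outbreak windows with same-span windows
in mesocosms without outbreaks and reports the two distributions with a
descriptive rank statistic (no p-value machinery).

## Plausibility arithmetic

A phage read fraction f implies a phage-to-bacterium genome-copy ratio
`f/(1−f) × g_b/g_p` under the first-order assumption that all non-phage
reads are bacterial; if only a fraction h of bacteria are hosts, each
host-lineage cell must account for ratio/h virion genome copies.  For
f = 0.74, g_p = 63,535 bp, g_b = 4 Mb this gives ≈ 179.2 genome copies per
bacterium and ≈ 1792 virions per host cell at h = 0.1.  The implementation
always reports these algebraic values.

## Known limitations

* Pigeonhole proposals from samples whose dominant genotype sits near the
  0.8 linkage threshold can yield spurious partial haplotypes; they are
  retained (provenance "pigeonhole") and typically absorb negligible
  abundance in the decomposition, but downstream users should prefer
  clonal-derived genotypes where available.
* The max-metric linkage clustering fragments groups when shallow
  (≈ 10–30×) samples qualify; fragmentation is cosmetic for event
  detection but inflates the group count.
* Decoupling detection reports the first *sampled* week past the
  threshold; with sparse late sampling the reported week can lag the true
  event by the sampling interval.
* The simulator's event mechanism confers fitness advantages by fiat;
  detected sweeps validate the inference, not any evolutionary model.
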