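# Methods

## Coordinates and data model

All genomic intervals are 1-based and inclusive (`length = end − start + 1`),
the convention in which CNV loci are conventionally printed
(e.g. `Chr6:67058287–67111682`).  BED input/output converts from 0-based
half-open at the boundary, so an internal interval's length equals the BED
`end − start`.  Only autosomes 1–22 are modelled; rows on sex chromosomes
are dropped at read time with a logged count, mirroring genotyping panels
that exclude sex-chromosome SNPs.  The two caller dialects are documented
TSVs, not vendor exports: caller A carries a log-Bayes-factor-like
confidence column, caller B reports copy number only (whether the second
caller's confidence was ever thresholded upstream is unknowable from our
inputs, so the dialect simply omits it).

## Consensus calling

A dual-confirmed CNV requires, per sample and chromosome: concordant
direction (copy number ≤ 1 deletion, ≥ 3 amplification; 2 is neutral and
never enters consensus — conflicting copy numbers *within* a direction,
e.g. 0 vs 1, still match); an overlap strictly exceeding
`min_overlap_fraction` (default 0.5) of **each** call's length; and an
overlapped section of 1 kb – 3 Mb inclusive.  The reciprocal reading of
"overlap exceeds 50% in length" is the field-standard symmetric choice when
no denominator is named; `overlap_denominator` also offers "either" and
"union".

Where several calls could pair, a one-to-one matching **maximising total
overlapped length** is computed with the Hungarian algorithm
(`scipy.optimize.linear_sum_assignment`).  A greedy descending-overlap pass
was considered and rejected: with reciprocal-overlap-admissible pairs one
can construct two A-calls and two B-calls where the single heaviest pair
blocks a strictly heavier two-pair matching, so greedy would not satisfy
the exhaustive-search equivalence this module promises (and the test suite
enforces against a brute-force oracle).  The assignment solution is
deterministic for fixed inputs.

Sample QC excludes a sample when **either** caller reports more than 35 raw
calls (strict inequality); `qc_callers` can restrict the rule to one
caller.  Events overlapping a centromere interval by ≥ 1 bp are dropped —
centromeric SNP coverage is too sparse for reliable calls — and an event on
a chromosome absent from the centromere track is an error rather than a
silent pass.

## CNVR construction

Events sharing ≥ 1 bp, directly or transitively, form one CNVR (per-chrom
single-linkage via a sorted sweep); the CNVR span is the **union** of its
members.  The union (rather than intersection) reading of "maximum region
shared among all individuals carrying a CNV at the same locus" is forced by
arithmetic: reported mean CNVR length exceeds mean CNV length, which an
intersection cannot produce.  No minimum cross-sample overlap is imposed
beyond 1 bp.  Ids are assigned by (chromosome, start) after clustering, so
the result is independent of input order (property-tested by shuffling, and
against a per-base coverage bitmap).

Frequencies: the overall denominator defaults to the number of CNV-carrier
individuals, the scale on which a 1-carrier region in a 1964-carrier cohort
has frequency 0.00051; `all_samples` mode divides by panel/population size
and is the default for per-population "common CNVR" thresholds (> 1%),
since it is not decidable from the source material which denominator the
> 1% filters used — both are supported, neither asserted.  Sharing is
partitioned Venn-style (private / each pair / all) plus carrier-count
strata (2, 3, …, 10, > 10) with the fraction private / two-population /
three-population per stratum.  Pearson correlation of common-CNVR
frequencies selects CNVRs above `min_freq` in the *selection* population
and correlates that fixed set's frequencies across the two populations
(scipy `pearsonr`, two-sided p).

## Population statistics

Summary tables store full-precision values and round only in `report()`
(percent 1 dp, ratios 2 dp).  Length contrast is a two-sided Mann-Whitney U
(scipy).  Annotation overlap uses merged interval trees (`intervaltree`)
and is bitmap-oracle-tested.  Segmental-duplication relations are
classified three ways: overlapping an SD, inside the gap between two SDs
closer than `hotspot_span` (default 10 Mb; published hotspot lists are not
reproducible, so the gap rule stands in), or outside.

The gene-content enrichment test replaces an under-specified regression
with SNP-density covariate by a fully specified randomization: each event
is re-placed on its own chromosome in a 1 Mb bin drawn from bins of the
same genome-wide SNP-density tercile (probe density confounds gene content
on SNP arrays), and p is the fraction of null mean gene counts ≥ observed.
Because the null redraws the position conditional on the observed stratum,
p is uniform under uniform placement — verified by a KS check across
generator seeds.

Zone densities anchor 10 Mb peri-telomeric zones at the most distal SNPs
and 10 Mb sub-centromeric zones at the SNPs nearest the centromere on each
side, clipped to the SNP-mapped extent (warning when an arm is shorter than
the zone); peri-telomeric assignment takes precedence where zones collide,
and events are assigned by midpoint (the straddling-event rule is otherwise
arbitrary).  The SNP-density contrast inside/outside CNVRs uses a
length-preserving permutation of CNVR placements (1000 reps, seeded,
add-one two-sided p).

## Kinship and the carrier test

Kinship follows the classic recursion (see README) in topological pedigree
order; an individual with one recorded parent is treated as having an
unrelated unknown second parent.  Validation: gene-dropping Monte Carlo
(10^6 drops) on named relationships and random pedigrees, symmetry, and
positive semi-definiteness of twice the matrix.

The carrier statistic uses **M_n(M_n−1)/2** distinct pairs for K_n — the
"non-redundant collection of all pairwise coefficients" — and a one-sided
Welch t-test (carriers *more* related; `alternative="two-sided"` restores
the symmetric test).  K_pop retains carrier pairs, exactly as the permuted
sub-collections are drawn from it.  Degenerate cases are defined so that
observed and permuted statistics are always computed identically (which is
all the permutation adjustment needs): with a single carrier pair or a
zero-variance K_n the vanishing variance term is dropped (df from K_pop),
and when both collections are constant p = 1 if mean(K_n) ≤ mean(K_pop)
else 0.  p_nadj = #{p_perm ≤ p_n}/n_perm; an adjusted p of 0 is displayed
as `< 1/n_perm`.  Batch runs derive per-(CNVR, population) sub-seeds by
CRC32 of `(seed, cnvr_id, population)`, so results are reproducible and
independent of iteration order.

Calibration caveat: p_nadj = F_perm(p_n) is uniform under the null only
where the statistic's distribution is effectively continuous.  In a
population of mutually unrelated families, most random carrier draws give
the identical all-zero K_n and the adjusted p concentrates near 1 (the test
is then conservative, never anticonservative).  The calibration suite
therefore uses what the test is built for — a deeply intermarried isolate
pedigree with pervasive kinship (generated with a low `immigrant_rate`) —
where tie classes are negligible and the KS check against U(0,1) passes.

## The synthetic-data generator

What it emulates: several isolate populations built from founder couples
grown over `family_depth` generations, children marrying either a new
unrelated founder (probability `immigrant_rate`) or a non-sibling of their
own generation; a CNV allele catalogue that is mostly population-private
and rare (private founder carrier frequencies largely 0.5–4%), with a
minority of shared alleles and a couple of co-located deletion/
amplification pairs (the recurrent-mutation source of gain-and-loss
regions); dominant presence/absence Mendelian transmission (each carrier
parent transmits independently with probability 1/2) — the pipeline only
ever observes carrier status, so a diploid genotype model is a non-goal;
and two caller outputs with independent 2.6% miss rates (the measured false
-negative rate of an LBF-10 caller on pseudo-deletions), 5 kb boundary
jitter (the mechanism behind non-equivalent boundaries across carriers),
and a false-positive load of 0.19 spurious calls per true call per caller,
set so that ≈ 18% of one caller's calls lack a partner in the other's —
matching the observed 82% inter-caller overlap.  A caller's true
false-positive rate on real data is not quantifiable from our sources; 0.19
is a calibration choice and is flagged as such.

The reduced genome model (4 autosomes, 570 Mb, mid-chromosome centromeres,
110 SNPs/Mb) keeps desk-scale runs fast while preserving everything the
pipeline is sensitive to: arm structure, centromere filtering, SNP-anchored
zones.  Everything is deterministic under a fixed seed (sub-seeds spawned
via `SeedSequence`).

What it does **not** emulate — and hence what passing tests cannot show
about real data: coalescent/demographic realism, linkage between CNV
alleles and SNP haplotypes, signal-level (LRR/BAF) noise, copy-number
dosage beyond carrier status, genome-build coordinates, and real annotation
tracks (gene, SD and reported-CNV tracks in tests are synthetic).

## Problem sizes used in the validation suite

Gene-dropping oracle: 10^6 drops (named relationships), 3×10^5 on random
pedigrees.  Null calibration: 500 replicates × 1000 permutations on a
~830-member isolate, carriers drawn 8 at a time.  Power: ~30 rare-allele
CNVRs segregating through the same pedigree, threshold 70% significant.
Oracle equivalence: 1000 random small call fixtures (≤ 5 calls per caller)
against exhaustive matching enumeration and per-base bitmaps.  Recall:
10^4 true events across 2000 samples at the 2.6% per-caller miss rate.

## Known limitations

* CNVR numbering of any external study is not reproducible and not
  attempted; ids are positional.
* The gene-content regression family of the original analyses is unknown;
  only the randomization replacement is provided.
* G+C analyses are out of scope (they need a reference sequence).
* The carrier test assumes the pedigree is correct and complete; genotype-
  based (marker) kinship is a non-goal.
* With `n_perm` permutations, p_nadj has resolution 1/n_perm; studies
  needing finer adjusted p-values must raise `n_perm`.
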