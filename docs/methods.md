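# Methods

This note documents the models and conventions behind labstrain, the
defaults of the synthetic-data generator, and the limits of what the tests
show about real data.

## Repeat detection

All coordinates are 0-based half-open. `N` bases break arrays: an
ambiguous base cannot support a repeat claim.

**Mononucleotide repeats (MNR).** Maximal single-base runs of length
≥ 6 bp ("longer than 5 bp", read strictly).

**Perfect SSRs.** Maximal exact tandem arrays with a primitive motif of
length 3–500 bp and at least three full copies ("repeated more than
twice"); a trailing partial copy extends the span and makes the copy
number fractional. Arrays are reported once, at their primitive period and
leftmost phase, so `(ACGACG)ₖ` is never double-reported as `(ACG)₂ₖ`. The
500 bp ceiling covers motifs up to the largest typing locus used in
practice (480 bp).

**Non-perfect SSRs (NP-SSR).** An array of c ≥ 3 consecutive motif-length
windows is valid when every window is *strictly more than* 70 % identical
(ungapped) to the column-wise majority consensus of the array (ties in the
consensus resolve alphabetically). The reported motif is the consensus and
the period must be primitive; `purity` is the mean copy identity. Among
valid arrays of one period, only those maximal under interval containment
are reported, and fully perfect arrays are left to the perfect finder.
Similarity is measured per copy against the consensus without gaps — the
tools this mirrors do not publish their internal scoring, so the simplest
defensible definition was chosen and is enforced by brute-force
equivalence tests.

Two consequences of this definition are worth knowing. First, random DNA
genuinely contains many short arrays that clear a 70 % bar (measured
≈ 35 per kb at the defaults, mostly 4–11 bp motifs at exactly 3 copies);
they are true detections under the definition, not bugs, and downstream
locus selection should rank by copy number and kind, as
`select_typing_loci` does. Second, phase-shifted overlapping NP arrays can
both be maximal, so NP loci — unlike perfect loci — may overlap.

**Locus selection.** The n loci with the largest copy number win; ties go
to the larger motif, then genome position. Regions to exclude (e.g. phage
or prophage spans) are supplied as a BED-style interval mask, not derived
by annotation.

## In-silico tRFLP

Primer matching tolerates ≤ 2 mismatches, requires an exact 3′-terminal
base (the anchor that makes a species-specific primer specific), accepts
IUPAC degeneracy in the primer and searches both strands. The terminal
fragment is measured from the 5′ end of the forward-primer site to the
first cut downstream on the labeled strand, with the cut `cut_offset`
bases into the recognition site (MspI `C^CGG` ⇒ offset 1). Amplicons with
no site are reported at full amplicon length and flagged `uncut` — such
peaks are real in tRFLP traces, so users decide whether to drop them. When
a reverse primer is supplied, its reverse complement delimits the
amplicon; otherwise the template end does.

Peaks are assigned to the nearest reference fragment within ± 2 bp
(typical capillary sizing error); relative abundance is peak area over the
*total* area of all peaks, so assigned plus unassigned mass is exactly 1.
The 8-level display matrix uses equal-width bins on [0, 1] with the top
bin closed. Group testing is per-peak one-way ANOVA: the study design this
mirrors analyzed each of the four species peaks separately and reports
single F values, so the multivariate variant is deliberately out of scope.

## Genotypes, diversity and sequence types

Measured fragment sizes round to integer bp (ties up). A failed
amplification is the null allele; it participates in binary encoding and
in the diversity index as a category of its own, because the underlying
scoring counts it as "an additional allele". Locus diversity is
D = 1 − ΣPⱼ², the probability that two randomly drawn strains differ at
the locus; D ≤ 1 − 1/k for k alleles with equality at equifrequency.

Sequence types are equivalence classes of identical gene sequences; the
null allele is one ST, and length variants (e.g. a 903 bp deletion) are
automatically distinct STs. The combined MLST type is the tuple of
per-gene STs. SNP counting works on pre-aligned, equal-length sequence
sets (alignment of real divergent data is a pluggable pre-step): a column
is polymorphic when ≥ 2 residues occur among non-missing entries, with
gaps/N treated as missing and null sequences skipped; deletion-variant
positions therefore do not inflate the count. Strains with no product at
*any* gene are excluded from MLST (and listed), strains with partial data
stay in as all-missing blocks in the concatenated alignment.

## Distances, UPGMA, bootstrap

The association distance on 0/1 allele-presence rows is Nei–Li / Dice:
with a shared 1s and b, c private 1s, S = 2a/(2a + b + c), d = 1 − S.
Shared absences carry no information about relatedness of dominant
markers, which is why Dice rather than simple matching is the default (the
simple-matching alternative is exposed as an option, and the choice is
recorded in run manifests). A strain pair with no alleles at all has
distance 1, with a warning. Dice on presence/absence saturates: once two
genotypes share no allele at any locus, d = 1 regardless of how far apart
the allele sizes are — visible in synthetic cohorts as between-cluster
means ≈ 1.0. The sequence branch uses p-distance with pairwise deletion; a
pair with zero comparable columns is an error naming the pair.

UPGMA is size-weighted average linkage; node height is half the merge
distance, so cophenetic distances are on the input scale. Ties merge the
lexicographically smallest index pair, making runs fully deterministic.
Bootstrap resamples encoded allele columns (SSR branch) or alignment
columns (MLST branch) with replacement; a node's support is the percentage
of replicate trees containing its leaf bipartition, matched on
bipartitions rather than node identity so tie-driven topology changes do
not zero supports. Columns are put in a canonical order before resampling,
which makes supports exactly invariant to column permutation of the input.
Flat clusters come from undoing the k−1 highest merges (warning when merge
heights tie at the boundary) or from a height cutoff. Cluster summaries
report mean ± sample standard deviation over all within pairs and all
member/non-member pairs.

## Synthetic-data generator

The generator emulates a host-specificity study at desk scale; all
randomness flows from one seed and identical configurations reproduce
identical files byte for byte.

**Genome.** 50 kb of i.i.d. uniform background with 12 planted repeats:
eleven typing loci shaped like the study's Table-2 set — motif sizes 480,
90, 66, 27, 18, 12, 9, 6, 6, 3 bp plus an 11 bp mononucleotide tract —
and one non-perfect array (15 bp motif, 4 copies, purity 0.8). Background
positions that happen to form perfect/MNR arrays of their own are broken
by single-base edits so that the screen recovers exactly the planted
perfect/MNR catalog; NP-SSR background is left in place because it is a
genuine feature of random sequence (see above), and the planted NP locus
is verified to be recovered at its exact span. Guard bases prevent arrays
from extending into their flanks; an attempt that cannot be cleaned is
retried deterministically.

**Strain population.** 3 host groups × 13 strains + 8 singletons = 47
strains at 11 SSR loci. Allele evolution is the standard stepwise
abstraction: founders sit 6 copy-number steps apart per locus, members
take a symmetric ±1 random walk with Poisson(0.2) steps, singletons are
per-locus mosaics of the founder lattice (so they sit roughly equidistant
from every cluster and spread out in the tree). Allele size is
flank + motif·copies for sized loci and the tract length itself for the
MNR locus; null alleles appear at rate 0.05 per locus per strain,
modeling locus-specific primer-site failure. These defaults were
calibrated so the per-locus allele counts land in the study's 2–10 span
for ≥ 90 % of loci; synthetic cohorts end up slightly *more*
discriminating than the real data (most strains are unique SSR types,
where the study found 29 types among 47 strains with many identical
isolates). Three genes of 1113, 522 and 286 bp descend from one root:
each founder-level draw (hosts and singletons alike, 11 draws) mutates
1 % of sites, members add Poisson(0.0003·L) private mutations; with 11
draws the union of mutated columns puts the realized polymorphic-site
fraction at ≈ 12 %, the study's scale, and per-gene sequence-type counts
at ≈ 14–22.

**tRFLP cohort.** 50 samples over four species peaks at 74/181/189/566 bp
with Dirichlet(5, 1, 2, 2) base abundances: one dominant species, one
rare, two intermediate. In the affected host group (*Rodentia*-like)
concentration mass is moved from the dominant to the rare species by a
factor e^(group_effect), keeping the pair total constant — by the
aggregation property of the Dirichlet this leaves every other species'
marginal distribution exactly unchanged, so the "unaffected" species is
genuinely null at the abundance level. Peak sizes jitter within ± 1 bp and
areas carry multiplicative lognormal noise (σ = 0.2). The noise makes the
*realized* relative abundance of unshifted species weakly group-dependent
(their denominator composition differs), a real feature of compositional
peak data; the exact-null property test therefore runs at zero area noise,
and the default-noise test only bounds the inflation.

**What passing tests do not show.** The generator has no coalescent
structure, no homoplasy between founders, no sequencing or
peak-calling error model, no chimeras, and its clusters are far better
separated than degraded real data may be; recovery results (ARI ≈ 1 at
defaults) demonstrate correctness of the pipeline, not expected field
performance.

## Problem sizes and numerics

Cluster-recovery acceptance runs 100 cohorts of 47 strains; ANOVA
calibration runs 500 null cohorts of 20 samples; oracle equivalence runs
≥ 1000 random strings of ≤ 60 bp against exhaustive scanners and 200
random ≤ 7-leaf matrices against a naive UPGMA. Window-identity
thresholds are compared in integer match counts (with a 1e-9 slack when
converting fractional thresholds), distances are clipped to [0, 1] after
symmetrization, and bootstrap seeds feed a single PCG64 generator per run.
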