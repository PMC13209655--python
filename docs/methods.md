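# Methods

This note documents the models and procedures the package implements, the
defaults that matter, what the synthetic generators do and do not emulate,
and the design choices made where the methodology was genuinely open.

## Replication architecture

**Model.** A circular chromosome replicated bidirectionally from one origin
accumulates opposite strand biases on its two replichores. The windowed GC
skew (G − C)/(G + C) therefore changes sign at *oriC* and *dif*, and the
cumulative skew (running sum of per-window skew from an arbitrary
linearization point) has one maximum and one minimum at those loci. The
skew alone does not say which extremum is the origin — that depends on the
sign convention and on which strand is leading — so the caller defines the
*ori* extremum operationally as whichever cumulative extremum the DnaA-box
cluster corroborates, and *dif* as the opposite one.

**Evidence combination.** The *oriC* position is the midpoint of the
densest window of TTATCCACA matches (both strands, ≤ `max_mismatch`
mismatches, default 1 — "variants" of the canonical box). A call is
*confident* when the cluster holds at least 7 boxes (the
Alphaproteobacteria-type clustering criterion) and lies within
`skew_tolerance` (default 50 kb) of a cumulative-skew extremum. AT-rich
islands (windows of 100 bp whose AT fraction exceeds the genome AT by
≥ 0.10, merged into maximal runs) within 2 kb, and
*dnaA/dnaN/recF/gyrB* annotations within 5 kb, are reported as additional
evidence but do not gate the call; absent annotations mark that evidence
unavailable rather than failed. The *dif* call considers every exact
GTTN{6}AAC match — the consensus is its own reverse complement, so a
single-strand scan covers both orientations — and returns the one closest
(circular distance, smaller coordinate on ties) to the terminus extremum,
flagging *xerC/xerD* within 10 kb. On a megabase genome the consensus has
thousands of chance matches, which is why selection is anchored to the
skew extremum rather than to the motif alone.

**Windowing defaults.** `window=1000`, `step=100`. The window suppresses
composition noise (per-window skew standard error ≈ 1/√(window·GC) ≈ 0.04
at GC 0.58, an order below the replichore signal), while the step resolves
extrema to ~100 bp. These are package defaults, not published constants;
positions are reported 1-based inclusive to match GenBank coordinates.

**N50/L50.** N50 is the smallest member of the minimal set of largest
contigs whose cumulative length reaches half the total; L50 is that set's
size. Ties and single-contig assemblies follow directly from the
definition.

## Synthetic replicons

Background sequence is i.i.d. with a stated GC fraction (default 0.578,
the focal chromosome's composition); the skew signal is produced by
splitting the G/C probability asymmetrically, G = (GC/2)(1 ± a) with the
sign flipping at the planted ori and dif, where a is the `skew_amplitude`
(default 0.3). Planted features — the DnaA boxes within ±500 bp of the
origin, one dif consensus instance, the AT-rich island (85% AT) —
overwrite background bases, and overlapping planted features raise an
error rather than silently shifting. Marker genes (*dnaA/dnaN/recF/gyrB*
near ori, *xerC/xerD* near dif) are emitted as GFF3 annotation only.

What the generator does **not** emulate: real oriC fine structure (phased
box spacings, IHF/FIS sites), codon-structured coding sequence, repeats,
or GC-content heterogeneity along the replicon. Recovery tests on these
simulations therefore validate the evidence logic and coordinate
arithmetic, not performance on atypical real genomes (e.g., multipartite
genomes or ori regions with degenerate box clusters).

## MGE screening and rate ratios

Keyword lists per class ship as configurable defaults (transposase:
"transposase", "insertion sequence", "IS family"; integrase: "integrase";
phage: "phage", "prophage", "capsid", "terminase", "portal", "tail
protein"; recombinase: "recombinase", "resolvase", "site-specific
recombination"; repeat: "repeat"); matching is case-insensitive substring
search, and precedence transposase > integrase > phage > recombinase >
repeat assigns each feature to at most one class (most specific mobile
function first — a "phage integrase" is counted as integrase). Manual
curation of misannotations is out of scope; the lists are the interface
for it.

The two-group Poisson model with log effective genome size (total ungapped
assembly length) as offset has closed-form MLE
RR = (y_f/s_f)/(Σy_c/Σs_c); the implementation uses the closed form, and
the test suite cross-checks it against an independently fitted GLM.
Intervals are Wald on the log scale with SE = √(1/y_f + 1/Σy_c); zero
counts on either side get a 0.5 continuity correction and a flag rather
than an exception. Overdispersion is Pearson χ² of the comparator counts
under their pooled rate, divided by n − 1; with single-assembly
observations this is a diagnostic, not a license for inference, and the
repeat class is excluded from inferential output entirely. Simulation at a
true rate ratio of 1 with genome-scale counts shows ~95% CI coverage
(small-count settings run a little below nominal, as expected for Wald
intervals).

## COG profiles

Expansion counts every letter of a multi-letter assignment independently;
"S", "-", empty and missing entries accrue to the "unknown function"
bucket. Category R (general function prediction only) stays distinct by
default — the merge rule targets S plus unassigned — with a `merge_r`
switch for the broader "poorly characterized" grouping. Percentages are
computed at full precision and sum to 100 by construction; the difference
table reports both the full-precision percentage-point difference and the
difference of 2-decimal-rounded percentages, because the two can disagree
in the last digit and published tables may print either.

## SNP consequences

Frame handling trims 3′ columns until the reference's ungapped length is a
codon multiple; internal reference gap runs not divisible by three flag
the gene as frameshifted and exclude it. SNPs are called per strain at
columns where both rows are unambiguous bases; gap/ambiguity columns are
skipped and the assessable-site count is the SNPs/nt denominator (a rate
over compared sites, not raw CDS length). All of a strain's substitutions
within one codon are applied jointly before classification under
translation table 11 (stop→stop counts synonymous). Each SNP contributes
to SNPs/nt and Ti/Tv; each variable codon counts once in the
nonsynonymous-fraction denominator. Ti/Tv with zero transversions is
undefined (excluded from summaries with counts reported) rather than
infinite. Group summaries pool per-(gene, strain) values within each
mechanism × lineage cell; the shipped panel maps the sentinel genes to
mechanisms (acetate metabolism: *acsA ackA pta aarC mqo acnA*; efflux:
*oprM_1*; chaperone: *groEL dnaK*; ROS detoxification: *srpA*) and the
strains to isolation sources (Beer: LMG1625, LMG1608, R-82820, R-82821,
R-82823, R-83281; Vinegar: LMG1545; the reference belongs to no group).
Note the vinegar lineage has a single strain, so its "median" summarizes
genes within one strain.

Synthetic panels plant at most one SNP per codon (keeping classes clean),
draw the transition indicator Bernoulli(Ti/Tv target ÷ (1 + target)) and
the synonymous/nonsynonymous class Bernoulli(nonsynonymous target), and
realize each draw exactly by searching codon positions admitting it; only
sense↔sense changes are planted. Realized Ti/Tv at 10,000 draws has
binomial standard error ≈ 0.04 around 2.0. The generator emits ungapped
alignments; liftover and gap handling are exercised by dedicated tests
with constructed gapped alignments instead.

## Pan-genome content

Frequency classes follow the Roary ladder on the fraction of genomes
carrying a cluster: core ≥ 0.99, soft-core ≥ 0.95, shell ≥ 0.15, cloud
below. With eight genomes soft-core is structurally empty (0.95 × 8 > 7).
The accessory matrix drops core and soft-core rows. Genome-content
distances default to Jaccard on accessory profiles (Hamming available);
the tree is classical neighbor joining on that distance matrix, with
negative branch lengths clamped to zero. The published analysis used a
tree tool on the binary matrix without naming the distance; NJ-on-binary
distance is this package's stand-in, so sister-group expectations on real
data are qualitative. On additive matrices NJ reproduces every tip-to-tip
distance exactly, which is the correctness check used.

## Problem sizes and determinism

All simulation-based checks run at desk scale by choice: 100-kb replicons
(100 seeds for recovery rates), 500 × 8 presence–absence matrices, 10,000
planted SNPs, 500 Poisson datasets. Every generator is deterministic given
its integer seed; the acceptance script derives all sub-seeds from one
`--seed` argument.

## Known limitations

* Keyword screening inherits the annotation vocabulary; products labelled
  outside the phrase conventions (or in other languages of annotation) are
  uncounted, and no sequence-level IS/prophage detection is attempted.
* The oriC caller assumes a single origin and a dominant box cluster; it
  will not resolve multipartite or atypical replicons.
* Wald intervals on single-assembly counts are exploratory; overdispersion
  is reported but not modelled (no negative-binomial fallback).
* The accessory tree is a distance summary of gene content, not a
  phylogeny of sequence divergence.
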