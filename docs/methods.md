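# Methods

`tpghallmarks` re-implements, as a tested library, a statistical
characterization of translocation partner genes (TPGs) in hematological
cancer.  A reciprocal chromosomal translocation fuses the upstream part of a
5' partner gene (promoter, 5' coding sequence) to the downstream part of a
3' partner (3' coding sequence and 3'-UTR).  The package asks which genomic
features distinguish partner genes and partner *pairs* from the rest of the
genome: expression and promoter activity, 3'-UTR regulatory load, the
functional classes of protein domains retained in the fusion protein,
nuclear position measured by Hi-C contact frequency, replication timing,
and clinical recurrence.

## Coordinate and data conventions

Genomic intervals are 0-based half-open (BED); transcript and protein
coordinates are 1-based, protein intervals inclusive.  The TSS is
`tx_start` on the plus strand and `tx_end` on the minus strand.  Overlap
everywhere means >= 1 bp intersection of half-open intervals.  Hi-C
"distance" is reported as contact frequency throughout (higher = closer);
no geometric conversion is attempted.  Only interchromosomal (trans)
contacts enter pair statistics; cis entries of the contact matrix are
masked wherever a matrix row is consumed.

## Domain retention and functional categories

A breakpoint given as a 1-based transcript nucleotide position is converted
to an amino-acid position as `aa = floor((bp - cds_start)/3) + 1`;
breakpoints upstream of the CDS clamp to aa 0 and are flagged (under the 3'
retention rule such a partner keeps everything).  A domain is retained only
when it lies entirely on the contributed side: `aa_end < bp_aa` for the 5'
partner, `aa_start > bp_aa` for the 3' partner.  Breakpoint-spanning
domains are lost on both sides, which preserves the accounting identity
retained + lost = all annotations.

Retained domains map to five categories — DNA-binding (D), protein
interaction (P), histone modification (H), kinase (K), other (O) — via a
curated category table supplied as input; N encodes a side retaining
nothing categorizable.  Partners with at least one retained D/P/H/K domain
are type 1, otherwise type 2.  Protein interaction interfaces (PIIs)
participate in retention counts and the interactor network but not in
categorization: the category table covers domains, and a PII without a
mapped domain does not set the P bit.  This is an interpretation choice and
is stated here deliberately.

## Co-occurrence permutation test

For translocations deduplicated to unique (gene pair, domain composition),
the 6x6 count matrix assigns each translocation to every cell (c5, c3) with
c5 in its 5' category set and c3 in its 3' set.  The null permutes the 3'
category sets across translocations with the 5' sets fixed, preserving both
marginal multisets; shuffling whole 3' genes would induce the same law on
this statistic.  Per cell: fold = observed / mean permuted count; p is the
add-one empirical two-sided p (doubled smaller tail, capped at 1, never
exactly zero from finite permutations); Benjamini-Hochberg q-values at
q = 0.10 are computed across all cells with any observed or permuted
support, excluding structurally empty cells so they do not dilute the FDR.
The default permutation count is 10^6 (the headline analysis scale);
tests and the acceptance script pass smaller counts, stated below.

Type dependence between the 5' and 3' partner (type 1 vs type 2) uses a
two-sided Fisher exact test on the 2x2 table, plus the type2-type2 fraction
compared against the same permutation null.

## Bernoulli-mixture clustering of functional profiles

Each fusion is a 10-bit profile (5' side D/P/H/K/O, then 3' side).  A
mixture of independent per-bit Bernoulli components is fitted by EM with
component probabilities clamped to [1e-4, 1-1e-4] (so held-out profiles
never score -inf), 10 random restarts keeping the best training
likelihood, and convergence tolerance 1e-7 on the relative log-likelihood.
The number of components is selected by 10-fold cross-validation: k grows
from 1 while the mean held-out log-likelihood improves by more than a
floating-point tolerance; the first non-improving k stops the search.  With
identical profiles this selects k = 1; the number of clusters on any real
dataset is a data-dependent outcome, not a contract.

## Spatial statistics

Genes map to bins by gene-body midpoint (a TSS anchor is available behind a
switch).  The pair-proximity statistic is the mean trans contact over
pairs, compared against four permutation schemes: `shuffle` permutes the 3'
genes across pairs (same-chromosome combinations arising in a permutation
are excluded from that permutation's mean); `replace5`/`replace3`
substitute one side with uniform draws from a gene universe, and `random`
replaces both (cis draws are redrawn, keeping the pair count constant).
p per scheme is the add-one fraction of permuted means >= the observed
mean, i.e. small p means the observed pairs are closer than that null.

The central/peripheral partition applies 2-means to rows of the
trans-contact profile, with cis entries imputed by each bin's own mean
trans contact so chromosome identity carries no signal; the cluster with
the higher mean trans contact is labelled central.  Locus centrality is the
mean trans contact of a gene's bin.  Lineage contrasts compute per-pair
log2(a + eps) - log2(b + eps) between two cell-line matrices with
eps = 1 read-equivalent (zeros policy), Wilcoxon signed-rank within
lineage, Mann-Whitney between lineages, and Spearman correlation of the
pair values.  Chromosome-pair closeness is the full distribution of
bin-pair trans values between two chromosomes.

## Replication timing

Profiles are on the normalized early/late scale (nominal -1.5..1.5,
positive = early).  Smoothing is LOESS — tricube-weighted degree-1 local
regression, default span 0.3, evaluated at the input positions; the
statsmodels `lowess` implementation provides it.  Gene RT is linear
interpolation at the gene midpoint; genes with RT strictly > 0.5 are early.
Enrichment of a gene set among early replicators is the ratio of early
percentages against a background set, with an exact binomial tail p using
the background percentage as the success probability.  The exact transform
behind the published -1.5..1.5 normalization is not specified anywhere we
could rely on, so input profiles are assumed pre-normalized; an optional
linear rescale mapping the gene-level 1st/99th percentiles to +/-1.5 is
available and recorded in output metadata when used.

## Other statistical conventions

Empirical p-values use the add-one (permutation-inclusive) convention.
Z-normalization uses the population SD — it is applied to a full gene
universe, not a sample.  The "fold" of the binomial enrichment is the ratio
of percentages, matching how such enrichments are reported alongside
binomial p-values; a true sample odds ratio is emitted separately where a
2x2 table exists.  Promoter windows are [TSS - 3 kb, TSS + 3 kb), clipped
at the chromosome start.  Promoter "Pol2 occupancy" used in the fusion gain
statistic is the unnormalized peak-frequency proportion (an interpretation,
flagged as such).  Signal meta-profiles use log2(x + 1) to handle zeros.
Paired comparisons use Wilcoxon signed-rank (undefined all-tie inputs are
reported as p = 1 with a flag), unpaired group comparisons Mann-Whitney,
and the gain statistics a two-tailed Welch t-test.

## The synthetic-data generator

The generator emulates the statistical structure of the study's inputs so
every stage runs and is verified without downloads.  Defaults: 5
chromosomes, 1,000 genes, 500 one-megabase bins, 300 translocations.
Genes (2-9 kb transcripts) carry Poisson(3.5) domain annotations with
category frequencies D 0.30, P 0.30, H 0.10, K 0.10, O 0.20 — D/P most
frequent, K/H rarer, as in curated annotation — with density chosen so that
planted pairwise category effects at the study scale are statistically
recoverable, which is the module's core contract; 40% of genes carry 1-2
PIIs with 1-3 partners.  Lymphoid/myeloid lineage labels are drawn at the
177:201 proportions of the study frame.  Report counts are Zipf(2.0),
capped at 1,000.

Planted co-occurrence: the achievable retained-category sets per side are
enumerated from the catalog (8 random CDS breakpoints per gene), and
translocations are drawn from a joint law over set pairs whose planted
cells sit at the target fold *relative to its own marginals*.  A naive
exponential tilt of the independent joint cannot do this (it inflates the
marginals; a single-cell odds-ratio tilt caps well below fold 3 at these
frequencies), so the per-cell 2x2 membership law is driven to a target that
keeps both category marginals at their base values and places
fold x m5 x m3 mass on the joint cell; a damped fixed point handles
interacting cells, and infeasible targets raise configuration errors.
This exact construction replaces rejection sampling: it samples the same
target law without a rejection loop and keeps marginal frequencies
interpretable.

The contact matrix plants a central compartment as contiguous ~10-bin
segments covering 20% of bins (real central regions are megabase blocks;
contiguity also lets locally smoothed profiles see the compartment).
Trans values are base x (1 + 5 x central_i x central_j) x lognormal(0.2)
noise; cis values follow a 20/(d+1)^1 distance decay and are flagged.  The
second cell-line matrix shares the compartment with independent noise.  RT
is rho x (normal scores of bin-centrality rank) + sqrt(1 - rho^2) x
spatially correlated noise with rho = 0.9, rescaled so the 1st/99th
percentiles sit at -/+1.5; the rank-based coupling keeps the configured
monotone association even though boosted centrality is nearly bimodal.
Expression (log2 scale, baseline N(6, 1.5), sample noise N(0, 0.5); 3
lineages x 4 tissues x 3 donors plus two cell-line samples) plants a +1
log2 shift for 5' TPGs in hematopoietic samples.  Pol2 peaks appear at
promoters with probability 0.3 (0.8 for 5' TPGs in hematopoietic cell
lines); 3' TPG 3'-UTRs are shortened to 0.5 of their length with
regulatory-element counts proportional to length.  5' partner genes are
drawn with 3x weight from central bins (3' partners unweighted), matching
the asymmetric nuclear-position pattern the pipeline is designed to detect.

What the generator does **not** emulate: real chromosome lengths or gene
names, splicing (transcripts are unspliced), probe-level microarray noise,
Hi-C bias structure, or any coupling between recurrence and gene features
(report counts are independent of everything else by default).  Passing
tests therefore demonstrate that the machinery recovers known structure of
these kinds at these scales — not that any particular biological claim
holds in real data.

## Problem sizes and numerical choices in tests

The test suite and `scripts/acceptance.py` run the analyses at reduced
permutation counts — 2,000-5,000 for co-occurrence calibration/power
replicates, 10^5 for the enumeration cross-check, 10^3-10^4 per spatial
scheme — and genome sizes of 200-1,000 genes; these sizes give Monte-Carlo
error comfortably inside the asserted tolerances while keeping runs quick.
Library defaults keep the headline scales (10^6 domain permutations, 10^5
spatial).  Determinism: all randomness flows from caller-supplied seeds
through numpy Generators (spawned per stage in the bundle generator);
writers sort records and format numbers deterministically, so identical
configurations produce byte-identical outputs.

## Known limitations

- The permutation null for co-occurrence shuffles category sets, not
  genes; the two coincide for this statistic but not for statistics that
  would depend on gene identity.
- The Bernoulli mixture assumes bit independence within components.
- K-means on trans profiles assumes two compartments; a supplied
  three-cluster labelling can be compared but is not computed here.
- Breakpoints in UTRs (upstream of the CDS) are clamped to aa 0 and
  flagged; domain comparison treats such 3' partners as retaining all
  domains.
- Pairs absent from the report-count table default to one report, with a
  warning: in a registry, absence of extra reports is not evidence of zero.
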