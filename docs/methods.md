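# Methods

This note documents the models, conventions and numerical choices behind
`polyte`, and what the synthetic-genome tests do and do not demonstrate
about real data.

## Coordinates and formats

All internal coordinates are 0-based half-open `[start, end)`; GFF3 I/O
converts to and from the 1-based inclusive convention at the boundary.
Every sort is stable with ties broken by `(chrom, start, end, id)`. The
subgenome of a chromosome is inferred from the final character of its
name (`1A` ... `7D` style), with an explicit override map available for
non-conforming assemblies.

## Insertion dating of full-length LTR retrotransposons

An LTR retrotransposon inserts with two identical long terminal repeats
that subsequently diverge neutrally. The 5' and 3' LTRs are aligned
globally (match +1, mismatch −1, gap open −8, gap extend −1; all
configurable) and divergence is corrected with the Kimura 2-parameter
model,

    d = −1/2 ln(1 − 2P − Q) − 1/4 ln(1 − 2Q),

where P and Q are the transition and transversion fractions over
ungapped columns (pairwise deletion: gap columns are excluded from both
numerator and denominator). Insertion age is `d / (2 µ)` with
µ = 1.3 × 10⁻⁸ substitutions · site⁻¹ · year⁻¹, the rate commonly used
for grass LTR retrotransposons; it is a parameter everywhere. Distances
in the saturated regime (log arguments ≤ 0) are flagged rather than
extrapolated.

The dating error is dominated by binomial sampling of substitutions
over the LTR length: for an LTR of length L at age t the relative error
scales as `1/sqrt(2 µ t L)`, so young elements and short LTRs date
noisily no matter the estimator. With 500–2000 bp LTRs and ages up to
3 Myr the median relative error measured on simulations is ≈ 12%.

## Canonical-element filter

Candidates (an LTRharvest-shaped table plus protein-domain hits) are
retained only if all seven criteria hold: (1) at least one
retrotransposon domain (GAG/PROT/INT/RT/RH hits counted via RT, RH,
INT, GAG); (2) consistent domain order — no repeated core domain
(INT/RT/RH) and the core order embeds as a subsequence into INT-RT-RH
or RH-RT-INT; (3) no gene-related domain; (4) all domain strands equal
to the candidate strand; (5) exact tandem-repeat content < 25%;
(6) each LTR ≤ 25% of the element length; (7) N content < 5%.

The "inconsistent domain" rule is stated operationally because only an
example of a violation (a duplicated core-domain series) is available
from the literature on which the criteria are modeled; the subsequence
rule reproduces that example and is declared, not inferred. The
tandem-repeat detector is an exact-period scan (unit sizes 2–12 bp, at
least 3 units); a precomputed fraction column can be supplied instead.

Superfamily classification uses the same subsequence rule: core order
embedding only in INT-RT-RH → RLC (Copia), only in RH-RT-INT → RLG
(Gypsy), anything ambiguous (e.g. a lone RT) or contradictory → RLX.

## Clustering and subgenome specificity

Elements are clustered at 95/95, 90/90 and 80/80
(identity over mutual length coverage) by single linkage: two elements
are linked when the global-alignment identity (matches over all
alignment columns, gaps included) reaches the identity threshold and
the aligned span (columns where both sequences hold a residue) covers
the required fraction of *both* sequence lengths. Single linkage is an
assumption — the seed-and-extend cluster tools this emulates do not
document their exact linkage — and is stated as such. A length-ratio
prefilter (min/max length below the threshold bound) skips provably
unlinkable pairs. Cluster ids are deterministic (smallest member id),
so reruns and permuted inputs give identical partitions.

Cluster subgenome specificity follows a three-rule decision tree
applied in order: (1) one subgenome holds ≥ 90% of members → that
subgenome; (2) exactly one subgenome holds < 10% → the other two
(e.g. AB); (3) otherwise ABD-common. Rule 2 is deliberately restricted
to *exactly one* low subgenome: a table like 85/8/7 fails rule 1 and
would match "members from one subgenome < 10%" twice, so it falls
through to ABD rather than being assigned arbitrarily.

## Age statistics

Subfamily lifespan is the (5th, 95th) percentile interval of member
ages, with linear interpolation between order statistics
(h = q·(n−1)); clusters with fewer than two dated members are flagged
undefined. The persistence curve is a histogram of ages in consecutive
10,000-year bins from zero (optional centered moving average, off by
default — whether published persistence curves are smoothed is not
documented, so raw counts are the default). Density tracks use 4-Mb
windows stepped by 0.8 Mb; an element belongs to a window when its
start lies inside, and the final partial window is kept.

## Copy phylogenies

Cluster trees are built by neighbor joining on the pairwise Kimura
distance matrix and midpoint-rooted; this replaces progressive
multiple-alignment trees, which are out of scope at desk scale, while
preserving the topology-level statistic of interest. Tree imbalance is
the normalized Colless index, Σ|L−R| over internal nodes divided by
(n−1)(n−2)/2: 1 for a caterpillar (serial "master copy" amplification),
0 for a perfectly balanced tree ("transposon" mode).

## TE landscape

Family/superfamily proportions are merged-bp coverage per subgenome
(overlaps within a family never double-count) alongside copy counts.
Between-subgenome ratios are bp-based, with copy counts also reported
because published abundance tables do not state their basis. A family
is *balanced* when all pairwise ratios lie within 2-fold and *strong*
when any reaches 3-fold; families below 0.1% of the total genome are
excluded from strong calls. k-mer coverage counts canonical
(strand-collapsed) k-mers, skips windows containing N, and reports the
fraction of positions covered by any window whose k-mer occurs at least
τ times; it is verified against a naive positional oracle.

## Gene-vicinity analytics

The closest flanking TE on each strand-aware side of a gene is found by
edge-distance (overlap → 0 bp; the convention for overlaps is ours, the
source material does not define one). Promoters are the 2 kb upstream
of the TSS, truncated at chromosome ends; a TE counts if it overlaps by
≥ 1 bp, once, regardless of extent. Promoter enrichment is computed per
subgenome on copy counts: `log2(%fam_promoter / %fam_subgenome)`, with
families under 500 genome-wide copies dropped. Expression-module
enrichment compares closest-upstream-family percentages per module
against all genes, skipping modules under 1000 genes; unexpressed genes
form their own pseudo-module, and genes lacking any upstream TE are
excluded from foreground and background alike. Homeolog triplets are
categorized by their three upstream flanking families (`all_same` =
CNS candidate, `two_same`, `all_different`).

## Homeolog spacing conservation

Neighbor distances are edge-to-edge gaps from a gene to its downstream
neighbor; under the inversion-aware policy a B/D gene oriented opposite
to its A homeolog uses the preceding gene instead, and under the
stringent policy triplets with any orientation mismatch are dropped
(the two policies coincide on inversion-free genomes). Negative gaps
(overlapping gene models) clamp to 1 bp and are flagged. Per triplet,
the three pairwise distance ratios are log2-transformed and histogrammed
in 0.2-log2-unit bins centered on zero.

The randomized control redraws as many positions per chromosome as
there are genes, uniformly, sorts them, and reassigns the original gene
ids top-to-bottom — preserving gene count, identity, order and length
while randomizing spacings; the construction (sorted anchors in the
free space plus cumulative gene lengths) cannot produce overlaps.

The significance test is a Pearson chi-square (df = 1, no continuity
correction) on the 2×2 table of in-peak vs out-of-peak counts for
observed and randomized log-ratios. Two deliberate design points:

- The test runs **per subgenome pair** (A/B as the headline, all three
  reported). The three ratios of one triplet satisfy A/D = A/B · B/D,
  so pooling them would feed functionally dependent values into a test
  that assumes independent observations and inflate the statistic.
- The peak bin is the modal bin of the **combined**
  observed + randomized histogram, not of the observed sample alone.
  Selecting the observed argmax conditions on upward noise in the
  observed in-peak count; under the null, measured type-I error at
  α = 0.01 was ≈ 6% with observed-only peak selection and returns to
  nominal with the combined mode, which treats the two samples
  symmetrically (given the bin totals, the observed/randomized split is
  unbiased). Power under full conservation is unaffected because the
  conserved ratios dominate the combined mode.

## Synthetic genome generator

The generator emulates, at desk scale, the features the pipeline
measures in a hexaploid genome:

- **Three subgenomes** (default one chromosome each, 1.2 Mb; every
  size is configurable) sharing TE families in conserved per-subgenome
  bp fractions, with family-typical copy lengths (MITEs/SINEs
  150–400 bp, CACTAs/LINEs ~1 kb).
- **flLTR-RTs** built as LTR–internal–LTR from a family ancestor, each
  LTR independently accumulating `µ·t` expected substitutions per site
  so the expected pair divergence is `2µt`; transitions occur at twice
  the transversion rate (K2P-compatible), indels are off by default and
  available as a fraction of the substitution rate for robustness
  tests. Ages are uniform on [0, 3 Myr] by default. Subfamily structure
  uses nested identity tiers — members ~97% identical within a
  subfamily, subfamily consensi ~85% identical within a family — and
  subfamilies cycle through home subgenomes (A, B, D, shared) to
  exercise the specificity rules. Canonical domain layouts are
  GAG-INT-RT-RH (RLC) and GAG-RH-RT-INT (RLG).
- **Filter violators**: seven extra candidates, each violating exactly
  one canonical-filter criterion, recorded in a truth table for exact
  filter testing.
- **Promoter enrichment planting**: each family receives a copy budget
  from its genome fraction; a family with fold f takes a promoter copy
  share of f times its genome-wide share (deterministically rounded),
  remaining promoter mass spread over unspecified families. Background
  copies are placed uniformly in intergenic space *outside* promoter
  windows so planted folds are not diluted by accidental promoter
  overlaps; all copies are non-overlapping (no nesting — nested
  insertions are out of scope).
- **Homeolog triplets** with controllable spacing conservation: the
  A-subgenome layout places genes by sorted uniform anchors; for a
  conserved fraction of triplets the B/D downstream gap copies the A
  gap with ±5% multiplicative noise, non-conserved gaps come from an
  independent uniform layout. This matches the randomization's
  generative law, so with conservation 0 the observed and control ratio
  distributions coincide and the test is calibrated by construction. A
  configurable fraction of B genes is inverted relative to A.
- **Planted CNS triplets**: a dedicated-family copy is placed 60 bp
  upstream of all three homeolog TSSs for a configurable triplet
  fraction; 60 bp is below the minimum TE length, so no later placement
  can become the closer upstream neighbor.
- **Expression modules** by weighted sampling without replacement
  (optional per-module family folds); leftover genes form the
  unexpressed pseudo-module.

Identical config + seed give byte-identical outputs; a single
`numpy.random.Generator` threads through the whole simulation.

### What the generator does not emulate

No nested insertions, solo-LTR formation or deletion via unequal
recombination, no sequence homology between TE annotations and the
random background (except embedded flLTR-RT sequences), no gene
structure below the gene feature, no recombination-rate or
compartment gradients along chromosomes, and no expression values
(module labels are categorical). Tests passing on this substrate
demonstrate the *algorithms* recover planted signal under the stated
noise model; they do not validate biological conclusions on real
assemblies, whose artifacts (assembly gaps, fragmented TEs, annotation
error) are absent here.

## Problem sizes

Simulated studies are scaled so the full suite completes comfortably on
one CPU: clustering instances of ~50 sequences at 450–600 bp (the
brute-force oracle is quadratic in both), 500 elements for dating
recovery, ~20,000 planted copies for enrichment recovery (≥ 2000 per
tested family), 2001 genes per subgenome and 100 replicates for the
spacing-test calibration, and a ~2.7-Mb three-chromosome genome for the
end-to-end determinism run. These sizes are choices of the test design,
stated here so they can be scaled up when more compute is available.
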