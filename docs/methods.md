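# Methods

This note documents the models, conventions and design choices behind
`methyldyn`, in the spirit of a statistical methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinates, contexts and the weighted level

All internal coordinates are 0-based half-open; file dialects are
converted at the I/O boundary (cytosine reports are 1-based on disk,
GFF3 is 1-based closed, BED is passed through). Strand is retained per
cytosine and symmetric CG sites are never collapsed at parse time;
aggregation happens downstream, where both strands are pooled.

The methylation level of a region is *weighted*: summed methylated calls
over summed total calls for all cytosines of one context in the region.
This weights deeply covered sites more than shallow ones and is the
standard WGBS convention. A region with zero observations has an
undefined (NaN) level — it is never silently reported as 0.

## Read filters

* **Clonal removal.** Reads sharing (chromosome, alignment start, strand)
  are presumed PCR duplicates; only the read with the maximal quality
  scalar survives, ties keeping the first in input order. Mate-pair
  awareness is out of scope; the key is the single-end one.
* **Consecutive-CHH filter.** Genuine CHH methylation is sparse, so a
  read on which three successive CHH cytosines all read as methylated is
  far more likely an unconverted molecule than a methylated one; such
  reads are dropped wholesale. "Successive" defaults to read order among
  CHH calls (interleaved CG/CHG cytosines are ignored), which matches the
  filter's purpose of flagging conversion failure along the molecule; a
  strict-adjacency variant (any cytosine interrupts the run) is available
  via `adjacency="strict"`.

## DMR calling

Windows are non-overlapping 100-bp tiles anchored at coordinate 0.
Eligibility requires at least 20 cytosine *observations* (read-level
calls) of the tested context in **both** samples; an alternative
"positions" mode counts distinct sites instead
(`AnalysisConfig.min_obs_mode`). Thresholds — 0.5 for CG, 0.3 for CHG —
are inclusive; a small epsilon (1e-9) guards the comparison against float
representation noise. CHH has no canonical threshold and must be set
explicitly (`delta_chh`). Hyper- and hypo-DMRs are called in one pass and
separated by the sign of level_B − level_A.

conDMR merging joins DMR windows that are adjacent or separated by
exactly one window; the merged span includes gap windows. When filtered
for length (default ≥ 500 bp) and gene overlap, each conDMR is annotated
with the overlapping feature of largest overlap (ties broken by
lexicographically smallest feature id) and inherits its strand as the
orientation.

No p-values are attached: the windowed rule is a deterministic threshold,
and statistical DMR testing (Fisher, beta-binomial) is deliberately not
part of this toolkit.

## Spreading centroid

Per-cytosine level mᵢ is the read ratio methᵢ/totalᵢ (not a binary call);
relative position xᵢ = (posᵢ − start + 0.5)/length, reflected for
minus-orientation regions so x runs 5′→3′ along the gene. The centroid
Σxᵢmᵢ/Σmᵢ is undefined when Σmᵢ = 0. The across-plant correlation between
mean conDMR level and centroid uses Pearson's r by default (Spearman
available); it is undefined with fewer than three plants or when either
variable's spread is below 1e-9 (treated as zero variance — near-constant
centroids otherwise produce numerically meaningless r).

## Gene-level dynamics

Gain calls use level < 0.1 in the reference and ≥ 0.1 (inclusive) in the
alternative; features with an undefined level in either sample are
excluded. For the cross-line association, each line's top-N features by
methylation increase (Δ weighted level; ties broken by feature id) are
selected from the universe G of features defined in every line, and the
expected number shared by exactly k lines assumes independent selection:
G·C(L,k)·pᵏ(1−p)^(L−k), p = N/G. Exactly-fixed-size selection is
hypergeometric rather than Bernoulli per gene, but for N ≪ G the binomial
form is accurate; a Monte-Carlo mode draws fixed-size selections and is
used as the cross-check oracle in the tests.

The acceleration logic: if per-generation increments are equal or shrink
(saturation), the first of n steps carries ≥ 1/n of the total increase —
`equal_increment_bound(8)` = 1/8 for the eight self-pollinations between
generations 1 and 9. The linear extrapolation B + (B−A)×factor (default
7) is exact on arithmetic progressions and is reported unclamped even
when it exceeds 1.

## epiRIL analyses

Target probes are those with HMM status M in the WT parent and U in the
*ddm1* parent. The global hypomethylation index is the probe-level mean of
{M→0, I→0.5, U→1} over targets — by construction 0 for the WT parent and
1 for the *ddm1* parent. Haplotype inference labels the interval between
concordant consecutive markers with their shared parental state and the
interval between discordant markers (which must contain a crossover) as
unknown; regions beyond terminal markers are uncovered. Features are
assigned a haplotype only when fully contained in a labelled segment —
a conservative convention that never imputes across breakpoints. The
local-vs-global correlation takes the per-line local change as a plain
input column, so it works identically for MeDIP signal or WGBS levels;
p-values come from the t-distribution with n−2 degrees of freedom.

## ChIP enrichment

Density is the count of reads overlapping the query interval (any
overlap) divided by interval width; RPM mode scales by 10⁶/total reads.
The baseline draws n (default 100,000) 100-bp windows uniformly over the
concatenated genome (windows may overlap each other); z = (d − mean)/SD.
A seed is mandatory for the baseline so scores are reproducible. z-scores
are invariant to raw-vs-RPM scaling when baseline and query use the same
scaling. Oriented profiles average per-bin z-scores across regions after
reversing minus-orientation regions.

## Synthetic data generator

The generator is *phenomenological*: it plants the statistical signatures
of the biology — it does not model the underlying chromatin feedback
mechanism.

**Genome.** Default two 500-kb chromosomes: a pericentromeric
heterochromatin block (10% of the chromosome), dispersed 2-kb TE
insertions, TE genes inside the pericentromere, and arm genes of 4 kb in
5-kb slots. A configurable fraction of arm genes (default 0.4) carries a
300-bp heterochromatic seed immediately 3′ of the gene. All
heterochromatin boundaries snap to the 100-bp analysis grid so that every
planted DMR window is unambiguously heterochromatic or not — a deliberate
simplification that makes precision/recall against planted truth exact
rather than edge-blurred. Cytosines occur with geometric spacing (mean
6 bp per strand) and context probabilities CG/CHG/CHH = 0.25/0.25/0.5,
roughly Arabidopsis-like densities at desk scale.

**Methylation surfaces.** Wild type: heterochromatin CG/CHG/CHH =
0.90/0.65/0.20; euchromatic non-CG 0.01; gene-body CG up to 0.35 in a
30% subset of genes. Mutant generations: immediate heterochromatic
collapse to 0.10/0.05/0.03 from generation 1; progressive CG loss in
euchromatin at 5% per generation; and for seeded genes, non-CG
methylation extends upstream from the 3′ seed by d(g) = d₀·r^(g−1) bp
(d₀ = 50, r = 1.6) to plateau levels CHG 0.4 / CHH 0.15, with per-line
lognormal jitter (σ = 0.3) on the front. Genes are 4 kb so the
generation-9 front (≈ 2.1 kb) rarely saturates a gene, keeping the
level-centroid relationship informative across plants. A `linear` growth
mode (d(g) = d₀·g) and a `uniform` gain mode (same magnitude schedule,
spatially uniform) provide the contrast cases for the acceleration and
spreading analyses. Counts are binomial draws at Poisson(20) coverage.

**Reads.** Uniform 90-nt read starts at the sample's coverage; calls are
Bernoulli in the true site level. Planted artifacts: 5% of reads get a
clonal duplicate (same start/strand/calls, fresh quality) and 5% are
conversion failures with every call methylated. Conversion-failure reads
that happen to cover fewer than three CHH sites survive the filter, and a
small number of genuinely methylated heterochromatic reads are lost to
it — both are properties of the real filter, so recovered elimination
rates sit near, not exactly at, the planted rate.

**epiRILs.** 123 lines, markers every 10 kb, haplotype state switching
between consecutive markers with probability 0.02 (≈ 1 crossover per
chromosome), true breakpoints uniform within the marker gap. Probes tile
heterochromatin every 1 kb (targets) plus sparser euchromatic non-target
probes. A line's target-probe status follows its true haplotype, with a
2% chance of an intermediate (I) status standing in for partial
remethylation; the planted "ddm1 fraction" is defined over target probes,
so with remethylation noise at 0 the index recovers it exactly. Trans
loci receive a local change 0.4·f + N(0, 0.04) in every line (f = the
line's ddm1 fraction) and binary gains with logistic probability in f —
on both haplotypes, by design.

**ChIP.** Poisson read starts at rate λ₀(1 + fold·h(x)) with λ₀ =
0.02/bp, fold = 9, read length 75. With heterochromatin at ~13% of the
genome this puts planted heterochromatic windows well above 2 baseline
SDs. Note the z of a het window saturates near √((1−q)/q) for het
fraction q: enrichment contrast, not the fold, is the limiting factor.

**What the generator does not emulate.** Real sequence composition and
context landscape, mappability and coverage biases, partial/stochastic
per-molecule methylation patterns, TE families beyond labels,
chromosome-scale methylation clines, or the mechanistic feedback between
histone marks and non-CG methylation. Passing recovery tests therefore
demonstrates correctness of the *computations* under the planted
statistical structure, not power or calibration on real libraries.

## Problem sizes and determinism

Default runs use a 1-Mb genome (≈ 330 k cytosines) at coverage 20 with
13 samples; spreading cohorts use 1.6 Mb with ~260 seeded genes so that
well over 200 genic conDMRs of ≥ 500 bp are available, the cohort size at
which the r histogram's shape is stable. These sizes keep a full pipeline
run under a minute while leaving all planted-recovery margins wide. Every
generator and every randomized analysis (ChIP baseline) is driven by an
explicit integer seed and is bit-reproducible under it.

## Known limitations

* The association null is closed-form binomial (see above); for top_n
  approaching G the hypergeometric correction would matter.
* Haplotype inference places no breakpoint, only an unknown interval;
  resolution is bounded by marker spacing.
* CHH DMR calling is supported but has no default threshold; analyses of
  CHH dynamics here go through levels and gain calls instead.
* Terminal chromosome windows shorter than 100 bp are retained when
  eligible; on real genomes this affects a negligible window fraction.
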