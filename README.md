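# methyldyn

Analysis toolkit for **transgenerational DNA-methylation dynamics** in
*Arabidopsis* chromatin-remodelling mutants (*ddm1*) and the epigenetic
recombinant inbred lines (epiRILs) derived from them. It is aimed at plant
epigenomics researchers who work with whole-genome bisulfite sequencing
(WGBS), MeDIP-chip HMM methylation states, and ChIP-seq, and who want a
tested, scriptable re-implementation of the classic windowed-DMR /
spreading / epiRIL analyses rather than one-off scripts.

## What it computes

**Read filters.** Two bisulfite-specific read filters precede everything:
clonal reads sharing (chromosome, alignment start, strand) collapse to the
single best-quality read, and any read carrying three consecutive
methylated CHH calls is discarded as a bisulfite-conversion failure.

**Weighted methylation level.** For a region and context c ∈ {CG, CHG,
CHH}, the level is Σᵢ mᵢ / Σᵢ nᵢ over all cytosines i of that context in
the region (mᵢ methylated calls, nᵢ total calls) — counts pooled, not
per-site ratios averaged.

**DMR calling.** The genome is tiled in 100-bp windows anchored at 0. A
window with ≥ 20 observations in both samples is a DMR when
|level_B − level_A| ≥ 0.5 (CG) or ≥ 0.3 (CHG), thresholds inclusive.
Contiguous DMRs (conDMRs) merge runs of DMR windows separated by at most
one non-DMR window.

**Spreading statistic.** Within a conDMR oriented 5′→3′ along its
overlapping gene, the centroid is Σ xᵢ mᵢ / Σ mᵢ with xᵢ the relative
position and mᵢ the per-cytosine level. Across plants, Pearson r between
the conDMR's mean CHG level and its centroid is strongly negative when
methylation spreads in from a 3′ heterochromatic seed: plants with more
methylation carry it further 5′.

**Gene dynamics.** Gain calls (level < 0.1 in the reference and ≥ 0.1 in
the alternative), a cross-line association test of top-1000
largest-increase genes against a binomial null
(expected(k) = G·C(L,k)·pᵏ(1−p)^(L−k), p = 1000/G), and the acceleration
test: the linear extrapolation B + (B−A)×7 from generations 1 and 2
undershoots generation 9 when hypermethylation accelerates, whereas any
equal-or-saturating schedule puts ≥ 1/8 of the total gain into the first
step.

**epiRIL analyses.** Global hypomethylation index = mean of HMM probe
states (M=0, I=0.5, U=1) over probes methylated in the WT parent and
unmethylated in the *ddm1* parent; haplotype mosaics inferred from
parental-state markers; Pearson correlation of local methylation change
against the global index separates *cis* from *trans* effects.

**ChIP enrichment.** Read density of a region z-scored against the mean
and SD of densities in 100,000 random 100-bp genomic windows.

**Synthetic data.** `methyldyn.simulate` generates multi-generation
methylomes, reads with planted clonal/conversion-failure artifacts,
epiRIL probe/marker tables, and ChIP tracks — all with queryable planted
truth, so every stage is testable without any sequencing download.

## Worked example

```python
import numpy as np
import methyldyn as md

samples, truth = md.simulate_generations(seed=17)

# heterochromatic CG loss in the first mutant generation
dmrs = md.call_dmrs(samples["WT"], samples["1G-1"], "CG")
hypo = [d for d in dmrs if d.direction == "hypo"]
print(f"CG hypo-DMRs (WT vs 1G): {len(hypo)}")
tp = len({d.key for d in hypo} & truth.planted_cg_hypo_windows)
print(f"recall vs planted truth: {tp/len(truth.planted_cg_hypo_windows):.3f}")

# 3'->5' CHG spreading into seeded genes between 1G and 9G
chg = md.call_dmrs(samples["1G-1"], samples["9G-1"], "CHG")
cons = md.merge_condmrs(chg, truth.genes(), min_bp=500, require_feature=True)
nine = [samples[f"9G-{i}"] for i in range(1, 5)]
rs = [r for c in cons if (r := md.spread_correlation(nine, c).r) is not None]
print(f"conDMRs (>=500 bp, genic): {len(cons)}")
print(f"median level-centroid r: {np.median(rs):.2f}")
print(f"fraction r <= -0.5: {np.mean(np.array(rs) <= -0.5):.2f}")
```

Output:

```
CG hypo-DMRs (WT vs 1G): 1425
recall vs planted truth: 0.999
conDMRs (>=500 bp, genic): 62
median level-centroid r: -0.99
fraction r <= -0.5: 0.81
```

The 1,425 hypo-DMRs are the simulated pericentromeric/TE windows losing
CG methylation immediately in the mutant (recall 0.999 against the
planted windows). The strongly negative level-centroid correlations are
the signature of CHG methylation spreading from the 3′ seed toward the
5′ end of affected genes as it accumulates over generations.

A command-line interface mirrors the library
(`methyldyn simulate|filter-reads|pileup|levels|dmr|condmr|epiril-index|haplotype|chip-z`);
run `methyldyn --help`.

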