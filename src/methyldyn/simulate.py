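"""Synthetic methylome generator with planted ground truth.

The generator is phenomenological: it plants the statistical signatures of
transgenerational methylation dynamics in a ddm1-like mutant — immediate
heterochromatic loss in the first mutant generation, slow progressive CG
loss in euchromatin, and an accelerating 3'->5' spread of non-CG
methylation into genes carrying a 3' heterochromatic seed — without
modelling the underlying chromatin feedback mechanistically. Every planted
event (DMR window, spreading front, epiRIL haplotype, trans-gain gene) is
recorded in a :class:`SyntheticTruth` so parameter-recovery tests can
score precision and recall against a known answer.

Layout: each chromosome has a pericentromeric heterochromatin block,
dispersed heterochromatic TE insertions, and gene-bearing arms; a
configurable subset of arm genes carries a 300-bp heterochromatic seed
just 3' of the gene from which non-CG methylation spreads upstream by
``d0 * r^(g-1)`` bp at mutant generation g. All heterochromatin boundaries
are aligned to the 100-bp analysis grid so planted DMR windows are
unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .chip import ChipTrack
from .types import (
    CONTEXTS,
    FeatureAnnotation,
    MarkerTable,
    MethylomeSample,
    ProbeStatusTable,
    ReadRecord,
    ReadSet,
)

_GRID = 100  # heterochromatin boundaries snap to the DMR window grid


@dataclass
class SimulationConfig:
    # genome layout
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 500_000, "chr2": 500_000}
    )
    pericentromere_frac: float = 0.10
    slot_bp: int = 5_000
    gene_len: int = 4_000
    seed_len: int = 300
    p_gene: float = 0.85
    p_te: float = 0.08
    te_len: int = 2_000
    teg_len: int = 2_000
    teg_spacing: int = 5_000
    seeded_frac: float = 0.4
    body_cg_frac: float = 0.3
    # cytosine landscape
    cytosine_spacing: float = 6.0  # mean bp between cytosines per strand
    context_probs: tuple[float, float, float] = (0.25, 0.25, 0.5)  # CG, CHG, CHH
    coverage: float = 20.0  # Poisson mean reads per cytosine
    # wild-type methylation by compartment
    het_cg: float = 0.9
    het_chg: float = 0.65
    het_chh: float = 0.2
    eu_cg: float = 0.05
    eu_noncg: float = 0.01
    body_cg_max: float = 0.35
    # mutant dynamics
    ddm1_het_cg: float = 0.1
    ddm1_het_chg: float = 0.05
    ddm1_het_chh: float = 0.03
    cg_loss_rate: float = 0.05  # per-generation CG loss in low-h regions
    spread_d0: float = 50.0
    spread_r: float = 1.6
    spread_growth: str = "geometric"  # or "linear": d(g) = d0 * g
    spread_plateau_chg: float = 0.4
    spread_plateau_chh: float = 0.15
    spread_jitter_sd: float = 0.3  # lognormal sigma on d per (gene, line)
    spread_mode: str = "spreading"  # or "uniform"
    uniform_jitter_sd: float = 0.15
    # cohort
    n_wt: int = 1
    generations: dict[str, int] = field(
        default_factory=lambda: {"1G": 4, "2G": 4, "9G": 4}
    )
    # read simulation
    read_len: int = 90
    duplicate_rate: float = 0.05
    failure_rate: float = 0.05
    # ChIP simulation
    chip_base_rate: float = 0.02  # read starts per bp outside heterochromatin
    chip_fold: float = 9.0  # extra fold inside heterochromatin (lambda = base*(1+fold*h))
    chip_read_len: int = 75
    # epiRIL simulation
    n_epirils: int = 123
    marker_spacing: int = 10_000
    crossover_prob: float = 0.02  # per inter-marker interval
    probe_spacing: int = 1_000
    status_noise: float = 0.02
    n_trans_genes: int = 30
    trans_slope: float = 0.4
    trans_noise_sd: float = 0.04
    trans_logistic_k: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "pericentromere_frac", "p_gene", "p_te", "seeded_frac",
            "body_cg_frac", "het_cg", "het_chg", "het_chh", "eu_cg",
            "eu_noncg", "body_cg_max", "ddm1_het_cg", "ddm1_het_chg",
            "ddm1_het_chh", "cg_loss_rate", "duplicate_rate", "failure_rate",
            "crossover_prob", "status_noise", "spread_plateau_chg",
            "spread_plateau_chh",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(sum(self.context_probs) - 1.0) > 1e-9:
            raise ValueError("context_probs must sum to 1")
        if self.spread_growth not in ("geometric", "linear"):
            raise ValueError("spread_growth must be 'geometric' or 'linear'")
        if self.spread_mode not in ("spreading", "uniform"):
            raise ValueError("spread_mode must be 'spreading' or 'uniform'")
        for chrom, size in self.chrom_sizes.items():
            if size % _GRID:
                raise ValueError(f"{chrom} size must be a multiple of {_GRID}")

    def spread_distance(self, generation: int) -> float:
        """Planted spreading distance (bp) at mutant generation g."""
        if generation < 1:
            return 0.0
        if self.spread_growth == "geometric":
            return self.spread_d0 * self.spread_r ** (generation - 1)
        return self.spread_d0 * generation


def spreading_cohort_config(**overrides) -> SimulationConfig:
    """Preset sized for spreading-statistic cohorts (>= 200 seeded genes):
    larger arms, every gene seeded, one 1G reference and four 9G lines."""
    base = dict(
        chrom_sizes={"chr1": 800_000, "chr2": 800_000},
        seeded_frac=1.0,
        p_gene=0.9,
        p_te=0.04,
        generations={"1G": 1, "9G": 4},
    )
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass
class SyntheticTruth:
    config: SimulationConfig
    seed: int
    chrom_sizes: dict[str, int]
    het: dict[str, np.ndarray]  # bool per bp
    features: list[FeatureAnnotation]
    seeded_genes: list[str]
    body_cg: dict[str, float]
    sites: dict[str, dict[str, np.ndarray]]  # chrom -> pos/strand/context arrays
    planted_cg_hypo_windows: set[tuple[str, int]]
    spread_d: dict[tuple[str, str], float]  # (sample_id, gene_id) -> front bp
    true_levels: dict[str, dict[str, np.ndarray]]  # sample -> chrom -> level/site

    def genes(self) -> list[FeatureAnnotation]:
        return [f for f in self.features if f.kind == "gene"]


def _generation_number(label: str) -> int:
    if label == "WT":
        return 0
    if label.endswith("G"):
        return int(label[:-1])
    raise ValueError(f"cannot parse generation label {label!r}")


def _build_layout(config: SimulationConfig, rng: np.random.Generator):
    het: dict[str, np.ndarray] = {}
    features: list[FeatureAnnotation] = []
    seeded: list[str] = []
    body_cg: dict[str, float] = {}
    families = np.array(["Gypsy", "Copia", "LINE"])
    for chrom, size in config.chrom_sizes.items():
        h = np.zeros(size, dtype=bool)
        peri_len = int(round(size * config.pericentromere_frac / _GRID)) * _GRID
        peri_start = ((size - peri_len) // 2 // _GRID) * _GRID
        peri_end = peri_start + peri_len
        h[peri_start:peri_end] = True
        # TEGs inside the pericentromere
        t = peri_start
        i = 0
        while t + config.teg_len <= peri_end:
            features.append(
                FeatureAnnotation(
                    f"teg_{chrom}_{i}", chrom, t, t + config.teg_len,
                    "+" if rng.random() < 0.5 else "-", "TEG",
                    str(rng.choice(families)),
                )
            )
            t += config.teg_spacing
            i += 1
        # arm slots: gene, TE insertion, or empty
        slots = [
            s for s in range(0, peri_start - config.slot_bp + 1, config.slot_bp)
        ] + [
            s for s in range(peri_end, size - config.slot_bp + 1, config.slot_bp)
        ]
        for j, s in enumerate(slots):
            u = rng.random()
            if u < config.p_gene:
                strand = "+" if rng.random() < 0.5 else "-"
                gstart = s + 400
                gend = gstart + config.gene_len
                gid = f"gene_{chrom}_{j}"
                features.append(
                    FeatureAnnotation(gid, chrom, gstart, gend, strand, "gene")
                )
                if rng.random() < config.body_cg_frac:
                    body_cg[gid] = float(rng.uniform(0.05, config.body_cg_max))
                else:
                    body_cg[gid] = config.eu_cg
                if rng.random() < config.seeded_frac:
                    seeded.append(gid)
                    if strand == "+":
                        h[gend:gend + config.seed_len] = True
                    else:
                        h[gstart - config.seed_len:gstart] = True
            elif u < config.p_gene + config.p_te:
                t0 = s + 1000
                h[t0:t0 + config.te_len] = True
        het[chrom] = h
    return het, features, seeded, body_cg


def _place_cytosines(config: SimulationConfig, rng: np.random.Generator):
    sites: dict[str, dict[str, np.ndarray]] = {}
    for chrom, size in config.chrom_sizes.items():
        pos_all, strand_all = [], []
        for strand_code in (0, 1):  # + / -
            n_guess = int(size / config.cytosine_spacing * 1.3) + 10
            gaps = rng.geometric(1.0 / config.cytosine_spacing, size=n_guess)
            pos = np.cumsum(gaps) - 1
            pos = pos[pos < size]
            pos_all.append(pos)
            strand_all.append(np.full(len(pos), strand_code, dtype=np.int8))
        pos = np.concatenate(pos_all)
        strand = np.concatenate(strand_all)
        order = np.argsort(pos, kind="stable")
        pos, strand = pos[order], strand[order]
        ctx = rng.choice(3, size=len(pos), p=list(config.context_probs)).astype(np.int8)
        sites[chrom] = {"pos": pos, "strand": strand, "context": ctx}
    return sites


def _gene_index(
    features: list[FeatureAnnotation], chrom: str, pos: np.ndarray
) -> tuple[np.ndarray, list[FeatureAnnotation]]:
    """Per-site index into the chromosome's gene list (-1 = intergenic)."""
    genes = sorted(
        (f for f in features if f.chrom == chrom and f.kind == "gene"),
        key=lambda f: f.start,
    )
    if not genes:
        return np.full(len(pos), -1, dtype=np.int64), genes
    starts = np.array([g.start for g in genes])
    ends = np.array([g.end for g in genes])
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
    return np.where(ok, idx, -1), genes


def _true_levels_for_sample(
    config: SimulationConfig,
    sample_id: str,
    generation: int,
    het: dict[str, np.ndarray],
    sites: dict[str, dict[str, np.ndarray]],
    gene_idx: dict[str, tuple[np.ndarray, list[FeatureAnnotation]]],
    body_cg: dict[str, float],
    seeded: set[str],
    jitter_rng: np.random.Generator,
    spread_d: dict[tuple[str, str], float],
) -> dict[str, np.ndarray]:
    levels: dict[str, np.ndarray] = {}
    for chrom in config.chrom_sizes:
        s = sites[chrom]
        pos, ctx = s["pos"], s["context"]
        in_het = het[chrom][pos]
        idx, genes = gene_idx[chrom]
        lvl = np.empty(len(pos), dtype=float)
        if generation == 0:
            per_ctx_het = (config.het_cg, config.het_chg, config.het_chh)
            cg_factor = 1.0
        else:
            per_ctx_het = (
                config.ddm1_het_cg, config.ddm1_het_chg, config.ddm1_het_chh
            )
            cg_factor = (1.0 - config.cg_loss_rate) ** generation
        gene_body = np.array(
            [body_cg[g.feature_id] for g in genes] or [0.0], dtype=float
        )
        for c in range(3):
            m = ctx == c
            if c == 0:  # CG
                eu = np.where(
                    idx >= 0, gene_body[np.clip(idx, 0, None)], config.eu_cg
                ) * cg_factor
            else:
                eu = np.full(len(pos), config.eu_noncg)
            lvl[m] = np.where(in_het[m], per_ctx_het[c], eu[m])
        # non-CG spreading from the 3' seed into seeded genes
        if generation >= 1:
            d_nominal = config.spread_distance(generation)
            for g in genes:
                if g.feature_id not in seeded:
                    continue
                key = (sample_id, g.feature_id)
                if config.spread_mode == "spreading":
                    d = d_nominal * jitter_rng.lognormal(0.0, config.spread_jitter_sd)
                    d = min(d, g.length)
                    spread_d[key] = d
                    if g.strand == "+":
                        zlo, zhi = int(g.end - d), g.end
                    else:
                        zlo, zhi = g.start, int(g.start + d)
                    plateau_chg = config.spread_plateau_chg
                    plateau_chh = config.spread_plateau_chh
                else:  # uniform gain over the gene, same growth schedule
                    scale = d_nominal / config.spread_distance(9)
                    jit = jitter_rng.lognormal(0.0, config.uniform_jitter_sd)
                    spread_d[key] = scale * jit * g.length
                    zlo, zhi = g.start, g.end
                    plateau_chg = config.spread_plateau_chg * scale * jit
                    plateau_chh = config.spread_plateau_chh * scale * jit
                a, b = np.searchsorted(pos, [zlo, zhi])
                if a == b:
                    continue
                seg_ctx = ctx[a:b]
                seg = lvl[a:b]
                seg[seg_ctx == 1] = np.maximum(seg[seg_ctx == 1], plateau_chg)
                seg[seg_ctx == 2] = np.maximum(seg[seg_ctx == 2], plateau_chh)
        levels[chrom] = np.clip(lvl, 0.0, 1.0)
    return levels


def _sample_counts(
    config: SimulationConfig,
    sample_id: str,
    genotype: str,
    generation_label: str,
    sites: dict[str, dict[str, np.ndarray]],
    levels: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> MethylomeSample:
    frames = []
    for chrom in config.chrom_sizes:
        s = sites[chrom]
        n = rng.poisson(config.coverage, size=len(s["pos"]))
        meth = rng.binomial(n, levels[chrom])
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": s["pos"],
                    "strand": np.where(s["strand"] == 0, "+", "-"),
                    "context": np.array(CONTEXTS)[s["context"]],
                    "meth": meth,
                    "total": n,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    return MethylomeSample(
        df, sample_id=sample_id, genotype=genotype, generation=generation_label
    )


def simulate_generations(
    config: Optional[SimulationConfig] = None, seed: int = 0
) -> tuple[dict[str, MethylomeSample], SyntheticTruth]:
    """Simulate a multi-generation cohort with planted truth.

    Returns (samples, truth) where samples maps sample ids ("WT",
    "1G-1", ..., "9G-4") to :class:`MethylomeSample`.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    het, features, seeded, body_cg = _build_layout(config, rng)
    sites = _place_cytosines(config, rng)
    gene_idx = {
        chrom: _gene_index(features, chrom, sites[chrom]["pos"])
        for chrom in config.chrom_sizes
    }
    # planted CG hypo-DMR windows = every window fully inside heterochromatin
    planted: set[tuple[str, int]] = set()
    for chrom, h in het.items():
        full = h.reshape(-1, _GRID).all(axis=1)
        for w in np.flatnonzero(full):
            planted.add((chrom, int(w) * _GRID))
    seeded_set = set(seeded)
    spread_d: dict[tuple[str, str], float] = {}
    true_levels: dict[str, dict[str, np.ndarray]] = {}
    samples: dict[str, MethylomeSample] = {}

    plan: list[tuple[str, str, str, int]] = []
    for i in range(config.n_wt):
        sid = "WT" if config.n_wt == 1 else f"WT-{i + 1}"
        plan.append((sid, "WT", "WT", 0))
    for gen_label, n in config.generations.items():
        g = _generation_number(gen_label)
        for i in range(n):
            plan.append((f"{gen_label}-{i + 1}", "ddm1", gen_label, g))

    for sid, genotype, gen_label, g in plan:
        lv = _true_levels_for_sample(
            config, sid, g, het, sites, gene_idx, body_cg, seeded_set, rng, spread_d
        )
        true_levels[sid] = lv
        samples[sid] = _sample_counts(config, sid, genotype, gen_label, sites, lv, rng)

    truth = SyntheticTruth(
        config=config, seed=seed, chrom_sizes=dict(config.chrom_sizes),
        het=het, features=features, seeded_genes=seeded, body_cg=body_cg,
        sites=sites, planted_cg_hypo_windows=planted, spread_d=spread_d,
        true_levels=true_levels,
    )
    return samples, truth


def simulate_reads(
    truth: SyntheticTruth,
    sample_id: str,
    seed: int = 0,
    region: Optional[tuple[str, int, int]] = None,
) -> tuple[ReadSet, dict[str, set[str]]]:
    """Simulate aligned reads for one sample, with planted artifacts.

    Artifacts: with ``duplicate_rate`` a read receives a clonal duplicate
    (same start/strand/calls, fresh quality); with ``failure_rate`` a read
    is a bisulfite-conversion failure, all its calls methylated. Returns
    (readset, labels) with labels["failed"] and labels["clonal_duplicate"]
    holding the planted read ids.
    """
    config = truth.config
    rng = np.random.default_rng(seed)
    if region is None:
        regions = [(c, 0, s) for c, s in truth.chrom_sizes.items()]
    else:
        regions = [region]
    reads: list[ReadRecord] = []
    failed: set[str] = set()
    dup_of: set[str] = set()
    rid = 0
    for chrom, lo, hi in regions:
        s = truth.sites[chrom]
        lv = truth.true_levels[sample_id][chrom]
        pos_by_strand = {}
        for sc in (0, 1):
            m = s["strand"] == sc
            pos_by_strand[sc] = (np.flatnonzero(m), s["pos"][m])
        n_reads = int(round((hi - lo) * config.coverage / config.read_len))
        starts = rng.integers(lo, max(hi - config.read_len, lo + 1), size=n_reads)
        strands = rng.integers(0, 2, size=n_reads)
        quals = rng.integers(10, 41, size=n_reads)
        is_fail = rng.random(n_reads) < config.failure_rate
        has_dup = rng.random(n_reads) < config.duplicate_rate
        for k in range(n_reads):
            start = int(starts[k])
            sc = int(strands[k])
            site_idx, site_pos = pos_by_strand[sc]
            a, b = np.searchsorted(site_pos, [start, start + config.read_len])
            covered = site_idx[a:b]
            offsets = site_pos[a:b] - start
            if is_fail[k]:
                states = np.ones(len(covered), dtype=bool)
            else:
                states = rng.random(len(covered)) < lv[covered]
            calls = [
                (int(o), CONTEXTS[s["context"][i]], bool(st))
                for o, i, st in zip(offsets, covered, states)
            ]
            name = f"r{rid}"
            rid += 1
            read = ReadRecord(
                name, chrom, start, "+" if sc == 0 else "-", float(quals[k]), calls
            )
            reads.append(read)
            if is_fail[k]:
                failed.add(name)
            if has_dup[k]:
                dname = f"r{rid}"
                rid += 1
                dq = float(rng.integers(10, 41))
                reads.append(
                    ReadRecord(dname, chrom, start, read.strand, dq, list(calls))
                )
                dup_of.add(dname)
                if is_fail[k]:
                    failed.add(dname)
    labels = {"failed": failed, "clonal_duplicate": dup_of}
    return ReadSet(reads, provenance=sample_id), labels


@dataclass
class EpirilSim:
    probe_table: ProbeStatusTable
    markers: MarkerTable
    lines: list[str]
    true_fraction: pd.Series  # planted ddm1-derived fraction over target probes
    haplotype_truth: dict[str, dict[str, list[tuple[int, int, str]]]]
    local_change: pd.DataFrame  # trans genes x lines, continuous
    gains: pd.DataFrame  # trans genes x lines, boolean
    trans_genes: list[str]


def simulate_epirils(
    truth: SyntheticTruth,
    n_lines: Optional[int] = None,
    seed: int = 0,
    status_noise: Optional[float] = None,
) -> EpirilSim:
    """Simulate epiRIL probe-status and marker tables with mosaic
    haplotypes and planted trans-effect genes.

    Haplotypes follow a Markov switching process along the marker grid;
    probes in heterochromatin are M in the WT parent, U in the ddm1 parent,
    and in a line take the status of the haplotype they sit on (with a
    small ``status_noise`` chance of I). Trans-effect loci get a local
    methylation change proportional to the line's true ddm1 fraction,
    independent of the local haplotype.
    """
    config = truth.config
    if status_noise is not None:
        config = replace(config, status_noise=status_noise)
    n_lines = n_lines if n_lines is not None else config.n_epirils
    rng = np.random.default_rng(seed)
    lines = [f"epiRIL{i + 1}" for i in range(n_lines)]
    # marker grid and probe positions
    marker_pos = {
        c: np.arange(config.marker_spacing, s, config.marker_spacing)
        for c, s in truth.chrom_sizes.items()
    }
    probe_rows = []
    for chrom, h in truth.het.items():
        for p in range(0, truth.chrom_sizes[chrom], config.probe_spacing):
            if h[p:p + _GRID].all():
                probe_rows.append((chrom, p, p + _GRID, True))
            elif p % (4 * config.probe_spacing) == 0:
                probe_rows.append((chrom, p, p + _GRID, False))  # non-target probe
    probes = pd.DataFrame(probe_rows, columns=["chrom", "start", "end", "is_het"])
    is_het = probes.pop("is_het").to_numpy()

    status: dict[str, np.ndarray] = {}
    status["WT"] = np.where(is_het, "M", "M")
    status["ddm1"] = np.where(is_het, "U", "M")

    hap_truth: dict[str, dict[str, list[tuple[int, int, str]]]] = {}
    marker_records = []
    frac = {}
    for line in lines:
        segs_all: dict[str, list[tuple[int, int, str]]] = {}
        probe_state = np.empty(len(probes), dtype=object)
        for chrom, size in truth.chrom_sizes.items():
            mp = marker_pos[chrom]
            state = int(rng.random() < 0.5)  # 0 = WT, 1 = ddm1
            # crossovers between markers; true breakpoint uniform in the gap
            segs = []
            seg_start = 0
            states = [state]  # state at mp[0]
            for i in range(1, len(mp)):
                if rng.random() < config.crossover_prob:
                    bp = int(rng.integers(mp[i - 1], mp[i]))
                    segs.append((seg_start, bp, "ddm1" if state else "WT"))
                    seg_start = bp
                    state = 1 - state
                states.append(state)
            if rng.random() < config.crossover_prob:  # after the last marker
                bp = int(rng.integers(mp[-1], size))
                segs.append((seg_start, bp, "ddm1" if state else "WT"))
                seg_start = bp
                state = 1 - state
            segs.append((seg_start, size, "ddm1" if state else "WT"))
            segs_all[chrom] = segs
            for pos, st in zip(mp, states):
                marker_records.append((line, chrom, int(pos), "ddm1" if st else "WT"))
            # probe statuses from the true segments
            pm = probes["chrom"] == chrom
            ppos = probes.loc[pm, "start"].to_numpy()
            lab = np.empty(len(ppos), dtype=object)
            for s0, s1, sl in segs:
                sel = (ppos >= s0) & (ppos < s1)
                lab[sel] = sl
            probe_state[pm.to_numpy()] = lab
        on_ddm1 = (probe_state == "ddm1") & is_het
        st = np.where(is_het, np.where(on_ddm1, "U", "M"), "M")
        noise = rng.random(len(st)) < config.status_noise
        st = np.where(noise & is_het, "I", st)
        status[line] = st
        hap_truth[line] = segs_all
        frac[line] = float(on_ddm1.sum() / is_het.sum())

    markers = MarkerTable(
        pd.DataFrame(marker_records, columns=["line", "chrom", "pos", "state"])
    )
    table = ProbeStatusTable(
        probes=probes, status=pd.DataFrame(status)
    )
    true_fraction = pd.Series(frac, name="ddm1_fraction")

    # planted trans effects at a random subset of arm genes
    genes = truth.genes()
    n_trans = min(config.n_trans_genes, len(genes))
    pick = rng.choice(len(genes), size=n_trans, replace=False)
    trans = [genes[i].feature_id for i in pick]
    f = true_fraction.loc[lines].to_numpy()
    local = {}
    gains = {}
    for line, fl in zip(lines, f):
        local[line] = config.trans_slope * fl + rng.normal(
            0.0, config.trans_noise_sd, size=n_trans
        )
        p_gain = 1.0 / (1.0 + np.exp(-config.trans_logistic_k * (fl - 0.5)))
        gains[line] = rng.random(n_trans) < p_gain
    local_df = pd.DataFrame(local, index=trans)
    gains_df = pd.DataFrame(gains, index=trans)
    return EpirilSim(
        probe_table=table, markers=markers, lines=lines,
        true_fraction=true_fraction, haplotype_truth=hap_truth,
        local_change=local_df, gains=gains_df, trans_genes=trans,
    )


def simulate_chip(
    truth: SyntheticTruth, seed: int = 0, fold: Optional[float] = None
) -> ChipTrack:
    """Poisson ChIP read track with intensity proportional to
    heterochromatin: start rate base * (1 + fold * h(x)).

    ``fold=0`` produces a homogeneous track regardless of layout.
    """
    config = truth.config
    fold = config.chip_fold if fold is None else fold
    rng = np.random.default_rng(seed)
    intervals = {}
    for chrom, h in truth.het.items():
        rate = config.chip_base_rate * (1.0 + fold * h.astype(float))
        counts = rng.poisson(rate)
        starts = np.repeat(np.arange(len(rate)), counts)
        intervals[chrom] = np.column_stack(
            [starts, starts + config.chip_read_len]
        )
    return ChipTrack(intervals)
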