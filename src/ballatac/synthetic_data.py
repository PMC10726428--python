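"""Synthetic cohorts with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes —
negative-binomial region counts with per-sample size factors and
per-region dispersion, subtype-enriched effect blocks with one
deliberately correlated subtype pair (mimicking the recurrent confusion
between the two Philadelphia-positive-like subtypes), a progenitor
staircase over fixed-width windows, Tn5 insertion profiles with core
depletion at bound motifs, Hardy-Weinberg genotypes with total and allelic
accessibility effects, and a toy annotated genome with histone marks,
loops and gene models. Everything is driven by an integer seed through
independent `numpy.random.default_rng` streams, so outputs are bit-stable
across runs.

The defaults are the desk-scale study conditions used by the acceptance
checks: 10 subtypes x 8 samples, 20,000 regions, 1% enriched regions per
subtype at log2 effect 2, dispersion ~ LogNormal(log 0.2, 0.5), depth
giving mean count 50, and a correlated pair sharing 60% of its enriched
block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ConfigError, CountMatrix, GeneModelRecord, LoopRecord, PeakRecord, VariantRecord, region_id
from .regions import GenomicInterval, RegionSet

__all__ = [
    "CohortTruth",
    "FootprintTruth",
    "QtlTruth",
    "AnnotationBundle",
    "simulate_cohort",
    "simulate_validation",
    "simulate_peaks",
    "simulate_progenitors",
    "simulate_insertions",
    "simulate_genotypes_allelic",
    "simulate_annotations",
]


# ---------------------------------------------------------------------------
# truth records
# ---------------------------------------------------------------------------

@dataclass
class CohortTruth:
    """Generating parameters of a simulated subtype cohort."""

    regions: RegionSet
    enriched: dict[str, list[str]]          # subtype -> planted region ids
    shared_block: list[str]                 # enriched in both correlated subtypes
    correlated_pair: tuple[str, str]
    mu: pd.Series                           # per-region NB mean
    alpha: pd.Series                        # per-region NB dispersion
    size_factors: pd.Series
    delta: float

    def exclusive_enriched(self) -> dict[str, list[str]]:
        """Planted regions enriched in exactly one subtype (recoverable truth)."""
        shared = set(self.shared_block)
        return {st: [r for r in ids if r not in shared] for st, ids in self.enriched.items()}


@dataclass
class FootprintTruth:
    bound: dict[tuple[str, str], set[str]]      # (motif, group) -> bound occurrence ids
    depth: dict[tuple[str, str], float]         # (motif, group) -> core depletion in [0, 1]
    flank_rate: float = 5.0


@dataclass
class QtlTruth:
    causal: list[str]
    beta: float
    pi: float
    variant_region: dict[str, str] = field(default_factory=dict)


@dataclass
class AnnotationBundle:
    regions: RegionSet
    genes: list[GeneModelRecord]
    k27ac: RegionSet
    k4me1: RegionSet
    k27me3: RegionSet
    loops: list[LoopRecord]
    blacklist: RegionSet
    gene_sets: dict[str, set[str]]
    planted_states: dict[str, str]
    planted_loops: dict[str, str]           # region id -> looped gene id


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _region_catalog(n_regions: int, width: int = 400, spacing: int = 5000,
                    per_chrom: int = 2000, prefix: str = "chr") -> RegionSet:
    """Evenly spaced fixed-width regions over as many chromosomes as needed."""
    ivs = []
    for i in range(n_regions):
        chrom = f"{prefix}{i // per_chrom + 1}"
        start = 10_000 + (i % per_chrom) * spacing
        ivs.append(GenomicInterval(chrom, start, start + width))
    return RegionSet(ivs, provenance="roi")


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean, dispersion alpha) with variance mean + alpha * mean^2."""
    r = 1.0 / np.maximum(alpha, 1e-12)
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


# ---------------------------------------------------------------------------
# subtype cohort
# ---------------------------------------------------------------------------

def simulate_cohort(
    n_subtypes: int = 10,
    n_per_subtype: int = 8,
    n_regions: int = 20_000,
    enriched_fraction: float = 0.01,
    delta: float = 2.0,
    alpha_log_mean: float = float(np.log(0.2)),
    alpha_log_sd: float = 0.5,
    mean_count: float = 50.0,
    mu_log_sd: float = 0.8,
    size_factor_log_sd: float = 0.2,
    correlated_share: float = 0.6,
    seed: int = 0,
) -> tuple[CountMatrix, CohortTruth]:
    """Multi-subtype cohort with planted subtype-enriched regions.

    Counts follow count_ij ~ NB(s_j * mu_i * 2^{delta * 1[i enriched for
    subtype(j)]}, alpha_i) with log-normal mu, alpha and size factors. The
    first two subtypes form the correlated pair: ``correlated_share`` of
    their enriched block is common to both, the remainder private, so
    their samples confuse classifiers the way biologically adjacent
    subtypes do. The sample sheet carries inert covariates
    (tss_enrichment, site, run) for exercising covariate-adjusted designs.
    """
    n_enriched = int(round(enriched_fraction * n_regions))
    if n_enriched < 1:
        raise ConfigError("enriched_fraction * n_regions must be >= 1 per subtype")
    rng = np.random.default_rng(seed)
    regions = _region_catalog(n_regions)
    rids = np.array(regions.ids)

    subtypes = [f"S{i + 1:02d}" for i in range(n_subtypes)]
    pair = (subtypes[0], subtypes[1])
    n_shared = int(round(correlated_share * n_enriched))
    n_private = n_enriched - n_shared
    # one disjoint pool: shared block + 2 private blocks + blocks for the others
    need = n_shared + 2 * n_private + (n_subtypes - 2) * n_enriched
    if need > n_regions:
        raise ConfigError("not enough regions for the requested enrichment layout")
    pool = rng.choice(n_regions, size=need, replace=False)
    cursor = 0
    shared = pool[cursor: cursor + n_shared]; cursor += n_shared
    enriched: dict[str, list[str]] = {}
    for st in subtypes:
        if st in pair:
            block = pool[cursor: cursor + n_private]; cursor += n_private
            enriched[st] = sorted(rids[np.concatenate([shared, block])])
        else:
            block = pool[cursor: cursor + n_enriched]; cursor += n_enriched
            enriched[st] = sorted(rids[block])

    mu = np.exp(rng.normal(np.log(mean_count), mu_log_sd, size=n_regions))
    alpha = np.exp(rng.normal(alpha_log_mean, alpha_log_sd, size=n_regions))

    sample_ids = [f"{st}_r{j + 1}" for st in subtypes for j in range(n_per_subtype)]
    labels = [st for st in subtypes for _ in range(n_per_subtype)]
    s = np.exp(rng.normal(0.0, size_factor_log_sd, size=len(sample_ids)))
    s /= np.exp(np.log(s).mean())  # geometric mean 1

    rid_pos = {r: i for i, r in enumerate(rids)}
    effect = np.zeros((n_regions, len(sample_ids)))
    for j, st in enumerate(labels):
        idx = [rid_pos[r] for r in enriched[st]]
        effect[idx, j] = delta
    mean = s[None, :] * mu[:, None] * np.exp2(effect)
    counts = _nb_draws(rng, mean, alpha[:, None])

    samples = pd.DataFrame(
        {
            "subtype": labels,
            "tss_enrichment": rng.normal(8.0, 1.0, size=len(sample_ids)),
            "site": rng.choice(["siteA", "siteB"], size=len(sample_ids)),
            "run": rng.choice(["run1", "run2"], size=len(sample_ids)),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    cm = CountMatrix(pd.DataFrame(counts, index=rids, columns=sample_ids), samples)
    truth = CohortTruth(
        regions=regions,
        enriched=enriched,
        shared_block=sorted(rids[shared]),
        correlated_pair=pair,
        mu=pd.Series(mu, index=rids),
        alpha=pd.Series(alpha, index=rids),
        size_factors=pd.Series(s, index=sample_ids),
        delta=delta,
    )
    return cm, truth


def simulate_validation(
    truth: CohortTruth,
    subtypes: Sequence[str],
    n_per_subtype: int = 8,
    size_factor_log_sd: float = 0.2,
    seed: int = 101,
) -> CountMatrix:
    """Held-out samples from existing subtypes under the same truth.

    Uses the training cohort's mu, alpha, delta and enriched blocks but
    fresh samples with independent size factors, emulating an externally
    processed validation cohort.
    """
    rng = np.random.default_rng(seed)
    rids = np.array(truth.regions.ids)
    rid_pos = {r: i for i, r in enumerate(rids)}
    sample_ids = [f"V_{st}_r{j + 1}" for st in subtypes for j in range(n_per_subtype)]
    labels = [st for st in subtypes for _ in range(n_per_subtype)]
    s = np.exp(rng.normal(0.0, size_factor_log_sd, size=len(sample_ids)))
    s /= np.exp(np.log(s).mean())
    effect = np.zeros((len(rids), len(sample_ids)))
    for j, st in enumerate(labels):
        idx = [rid_pos[r] for r in truth.enriched[st]]
        effect[idx, j] = truth.delta
    mean = s[None, :] * truth.mu.to_numpy()[:, None] * np.exp2(effect)
    counts = _nb_draws(rng, mean, truth.alpha.to_numpy()[:, None])
    samples = pd.DataFrame({"subtype": labels}, index=pd.Index(sample_ids, name="sample_id"))
    return CountMatrix(pd.DataFrame(counts, index=rids, columns=sample_ids), samples)


# ---------------------------------------------------------------------------
# peaks and summits
# ---------------------------------------------------------------------------

def simulate_peaks(
    regions: RegionSet,
    sample_subtypes: Mapping[str, str],
    dropout_prob: float = 0.0,
    jitter_sd: float = 10.0,
    peak_pad: int = 50,
    seed: int = 0,
) -> tuple[dict[str, list[PeakRecord]], dict[str, list[tuple[str, int]]]]:
    """Per-sample peaks and per-subtype summits over a true region set.

    Every true region emits one subtype-level summit at its midpoint plus
    Gaussian jitter (clipped inside the region) and, per sample, a peak
    covering the region extended by ``peak_pad`` bp with independent
    dropout. Recovery through the region-of-interest selection is then
    measurable against the input regions.
    """
    rng = np.random.default_rng(seed)
    subtypes = sorted(set(sample_subtypes.values()))
    summits: dict[str, list[tuple[str, int]]] = {st: [] for st in subtypes}
    for iv in regions:
        for st in subtypes:
            j = int(round(rng.normal(0.0, jitter_sd)))
            pos = int(np.clip(iv.midpoint + j, iv.start, iv.end - 1))
            summits[st].append((iv.chrom, pos))
    peaks: dict[str, list[PeakRecord]] = {sid: [] for sid in sample_subtypes}
    for sid in sorted(sample_subtypes):
        for iv in regions:
            if rng.random() < dropout_prob:
                continue
            peaks[sid].append(
                PeakRecord(
                    chrom=iv.chrom,
                    start=max(iv.start - peak_pad, 0),
                    end=iv.end + peak_pad,
                    name=f"{sid}_{region_id(iv.chrom, iv.start, iv.end)}",
                    qvalue_neglog10=2.0,
                    summit_offset=(iv.midpoint - max(iv.start - peak_pad, 0)),
                )
            )
    return peaks, summits


# ---------------------------------------------------------------------------
# progenitor staircase
# ---------------------------------------------------------------------------

def simulate_progenitors(
    stages: Sequence[str] = ("HSC", "MPP", "CLP", "PreProB", "ProB"),
    n_regions: int = 2000,
    loci_fraction: float = 0.02,
    delta: float = 2.0,
    n_per_stage: int = 6,
    n_ball: int = 8,
    window_width: int = 250,
    mean_count: float = 50.0,
    alpha_log_mean: float = float(np.log(0.2)),
    alpha_log_sd: float = 0.5,
    seed: int = 0,
) -> tuple[CountMatrix, dict[str, list[str]]]:
    """Staircase design over fixed-width windows plus a leukemia-like group.

    Each stage's identity loci (``loci_fraction`` of windows) are elevated
    by ``delta`` log2 units in that stage only. Samples labeled ``B-ALL``
    share the terminal stage's profile (the Pro-B-like cell of origin), so
    a k-NN trained on the progenitors should assign them to that stage.
    Returns the windowed count matrix and the stage -> loci truth map
    (key ``B-ALL`` aliases the terminal stage's loci).
    """
    rng = np.random.default_rng(seed)
    n_loci = max(int(round(loci_fraction * n_regions)), 1)
    regions = _region_catalog(n_regions, width=window_width, spacing=1000)
    rids = np.array(regions.ids)
    pool = rng.choice(n_regions, size=n_loci * len(stages), replace=False)
    loci = {st: sorted(rids[pool[i * n_loci: (i + 1) * n_loci]]) for i, st in enumerate(stages)}

    mu = np.exp(rng.normal(np.log(mean_count), 0.8, size=n_regions))
    alpha = np.exp(rng.normal(alpha_log_mean, alpha_log_sd, size=n_regions))
    labels = [st for st in stages for _ in range(n_per_stage)] + ["B-ALL"] * n_ball
    sample_ids = [f"{st}_r{j + 1}" for st in stages for j in range(n_per_stage)] + [
        f"BALL_r{j + 1}" for j in range(n_ball)
    ]
    s = np.exp(rng.normal(0.0, 0.2, size=len(sample_ids)))
    s /= np.exp(np.log(s).mean())

    rid_pos = {r: i for i, r in enumerate(rids)}
    terminal = stages[-1]
    effect = np.zeros((n_regions, len(sample_ids)))
    for j, lab in enumerate(labels):
        profile = terminal if lab == "B-ALL" else lab
        effect[[rid_pos[r] for r in loci[profile]], j] = delta
    mean = s[None, :] * mu[:, None] * np.exp2(effect)
    counts = _nb_draws(rng, mean, alpha[:, None])
    samples = pd.DataFrame({"stage": labels}, index=pd.Index(sample_ids, name="sample_id"))
    truth = dict(loci)
    truth["B-ALL"] = loci[terminal]
    return CountMatrix(pd.DataFrame(counts, index=rids, columns=sample_ids), samples), truth


# ---------------------------------------------------------------------------
# insertion profiles
# ---------------------------------------------------------------------------

def simulate_insertions(
    motif_depths: Mapping[str, Mapping[str, float]],
    n_occurrences: int = 500,
    frac_bound: float = 0.5,
    motif_length: int = 10,
    w_out: int = 50,
    flank_rate: float = 5.0,
    seed: int = 0,
):
    """Poisson insertion profiles with core depletion at bound occurrences.

    ``motif_depths[motif][group]`` is the depletion depth d in [0, 1].
    Per motif, the same ``frac_bound`` share of occurrences is bound in
    every group (so group contrasts isolate the depth difference); bound
    cores draw Poisson(rate * (1 - d)) per base, everything else
    Poisson(rate). Returns (profiles[group][motif] -> list of profiles,
    FootprintTruth).
    """
    from .footprints import InsertionProfile

    rng = np.random.default_rng(seed)
    window = motif_length + 2 * w_out
    groups = sorted({g for depths in motif_depths.values() for g in depths})
    profiles: dict[str, dict[str, list]] = {g: {} for g in groups}
    bound_map: dict[tuple[str, str], set[str]] = {}
    depth_map: dict[tuple[str, str], float] = {}
    for motif in sorted(motif_depths):
        occ_ids = [f"{motif}:occ{i:04d}" for i in range(n_occurrences)]
        n_bound = int(round(frac_bound * n_occurrences))
        bound_idx = set(rng.choice(n_occurrences, size=n_bound, replace=False).tolist())
        for g in groups:
            d = float(motif_depths[motif].get(g, 0.0))
            plist = []
            for i, oid in enumerate(occ_ids):
                rate = np.full(window, flank_rate)
                if i in bound_idx:
                    rate[w_out: w_out + motif_length] *= 1.0 - d
                plist.append(InsertionProfile(oid, g, rng.poisson(rate), w_out))
            profiles[g][motif] = plist
            bound_map[(motif, g)] = {occ_ids[i] for i in bound_idx}
            depth_map[(motif, g)] = d
    return profiles, FootprintTruth(bound=bound_map, depth=depth_map, flank_rate=flank_rate)


# ---------------------------------------------------------------------------
# genotypes and allelic counts
# ---------------------------------------------------------------------------

def simulate_genotypes_allelic(
    n_samples: int = 60,
    n_regions: int = 1000,
    frac_with_variant: float = 0.3,
    frac_causal: float = 0.2,
    beta: float = 0.5,
    pi: float = 0.7,
    maf_range: tuple[float, float] = (0.10, 0.45),
    mean_count: float = 50.0,
    alpha_log_mean: float = float(np.log(0.2)),
    alpha_log_sd: float = 0.5,
    read_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[list[VariantRecord], pd.DataFrame, CountMatrix, RegionSet, QtlTruth]:
    """Cohort with genotype-linked total and allelic accessibility effects.

    One variant is placed inside ``frac_with_variant`` of the regions;
    dosages follow Hardy-Weinberg at a uniform MAF. A ``frac_causal``
    share of QC-passing variants (imputation R^2 >= 0.8, realized sample
    MAF >= 0.05 — a causal variant removed by QC would measure QC, not the
    test) scales its region's NB mean by 2^{beta * dosage / 2} and skews
    het allele reads to ``pi``. Reads overlapping the variant are a
    binomial ``read_fraction`` thinning of the region count; null hets
    draw alt reads at 0.5. Imputation R^2 is None (directly genotyped)
    for half the variants and Uniform(0.5, 1) otherwise.
    """
    rng = np.random.default_rng(seed)
    regions = _region_catalog(n_regions, width=500, spacing=5000)
    rids = np.array(regions.ids)
    n_var = int(round(frac_with_variant * n_regions))
    var_regions = np.sort(rng.choice(n_regions, size=n_var, replace=False))

    mu = np.exp(rng.normal(np.log(mean_count), 0.8, size=n_regions))
    alpha = np.exp(rng.normal(alpha_log_mean, alpha_log_sd, size=n_regions))
    s = np.exp(rng.normal(0.0, 0.2, size=n_samples))
    s /= np.exp(np.log(s).mean())
    sample_ids = [f"P{j + 1:03d}" for j in range(n_samples)]

    variants: list[VariantRecord] = []
    var_region_id: dict[str, str] = {}
    for k, ri in enumerate(var_regions):
        iv = regions[int(ri)]
        pos = iv.start + (iv.end - iv.start) // 2
        maf = rng.uniform(*maf_range)
        dos = rng.binomial(2, maf, size=n_samples).astype(float)
        r2 = None if rng.random() < 0.5 else float(rng.uniform(0.5, 1.0))
        vid = f"rs{k + 1:05d}"
        variants.append(
            VariantRecord(id=vid, chrom=iv.chrom, pos=pos, ref="A", alt="G", dosages=dos, imputation_r2=r2)
        )
        var_region_id[vid] = regions.ids[int(ri)]

    passing = [v for v in variants if v.r2 >= 0.8 and v.maf() >= 0.05]
    n_causal = int(round(frac_causal * len(passing)))
    causal_ids = sorted(v.id for v in rng.choice(np.array(passing, dtype=object), size=n_causal, replace=False))
    causal = set(causal_ids)

    rid_pos = {r: i for i, r in enumerate(rids)}
    log2_effect = np.zeros((n_regions, n_samples))
    for v in variants:
        if v.id in causal:
            log2_effect[rid_pos[var_region_id[v.id]], :] = beta * v.dosages / 2.0
    mean = s[None, :] * mu[:, None] * np.exp2(log2_effect)
    counts = _nb_draws(rng, mean, alpha[:, None])
    samples = pd.DataFrame({"group": ["cohort"] * n_samples}, index=pd.Index(sample_ids, name="sample_id"))
    cm = CountMatrix(pd.DataFrame(counts, index=rids, columns=sample_ids), samples)

    ac_rows = []
    for v in variants:
        ri = rid_pos[var_region_id[v.id]]
        p_alt = pi if v.id in causal else 0.5
        for j in range(n_samples):
            if v.dosages[j] != 1:
                continue
            n_reads = rng.binomial(int(counts[ri, j]), read_fraction)
            alt = rng.binomial(n_reads, p_alt)
            ac_rows.append(
                {"variant_id": v.id, "sample_id": sample_ids[j], "ref_reads": n_reads - alt, "alt_reads": alt}
            )
    allele_counts = pd.DataFrame(ac_rows, columns=["variant_id", "sample_id", "ref_reads", "alt_reads"])
    truth = QtlTruth(causal=causal_ids, beta=beta, pi=pi, variant_region=var_region_id)
    return variants, allele_counts, cm, regions, truth


# ---------------------------------------------------------------------------
# annotations: genes, marks, loops, blacklist
# ---------------------------------------------------------------------------

def simulate_annotations(
    seed: int = 0,
    n_genes: int = 30,
    n_regions: int = 40,
    loop_fraction: float = 0.5,
    cancer_fraction: float = 0.3,
) -> AnnotationBundle:
    """Toy annotated genome for the region and network stages.

    Genes sit every 100 kb on one chromosome (alternating strand, three
    exons, a CDS spanning the middle exon); candidate regions fall in the
    intergenic space between consecutive genes. Each region is planted one
    chromatin state (round-robin over active / bivalent_poised / repressed
    / unmarked) realized as covering histone-mark intervals, and
    ``loop_fraction`` of regions loop to the promoter of the nearest
    downstream gene. A blacklist interval is placed clear of all regions.
    """
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    genes: list[GeneModelRecord] = []
    for i in range(n_genes):
        gstart = 50_000 + i * 100_000
        strand = "+" if i % 2 == 0 else "-"
        exons = [(gstart, gstart + 2_000), (gstart + 10_000, gstart + 12_000), (gstart + 20_000, gstart + 22_000)]
        tss = gstart if strand == "+" else exons[-1][1] - 1
        genes.append(
            GeneModelRecord(
                gene_id=f"G{i + 1:03d}",
                gene_name=f"GENE{i + 1}",
                chrom=chrom,
                strand=strand,
                tss=tss,
                exons=exons,
                cds_start=exons[1][0],
                cds_end=exons[1][1],
                expression=float(rng.lognormal(2.0, 1.0)),
            )
        )
    # regions midway between consecutive genes
    ivs = []
    for i in range(n_regions):
        g = genes[i % n_genes]
        base = g.exons[-1][1] + 30_000 + (i // n_genes) * 3_000
        ivs.append(GenomicInterval(chrom, base, base + 500))
    regs = RegionSet(ivs, provenance="custom")

    states = ["active", "bivalent_poised", "repressed", "unmarked"]
    planted: dict[str, str] = {}
    k27ac_iv, k4me1_iv, k27me3_iv = [], [], []
    for i, (iv, rid) in enumerate(zip(regs, regs.ids)):
        st = states[i % 4]
        planted[rid] = st
        cover = GenomicInterval(iv.chrom, iv.start - 100, iv.end + 100)
        if st == "active":
            (k27ac_iv if i % 8 < 4 else k4me1_iv).append(cover)
        elif st == "bivalent_poised":
            k27me3_iv.append(cover)
            k4me1_iv.append(cover)
        elif st == "repressed":
            k27me3_iv.append(cover)
    loops: list[LoopRecord] = []
    planted_loops: dict[str, str] = {}
    gene_by_id = {g.gene_id: g for g in genes}
    for i, (iv, rid) in enumerate(zip(regs, regs.ids)):
        if rng.random() >= loop_fraction:
            continue
        g = genes[(i + 1) % n_genes]
        loops.append(
            LoopRecord(chrom, iv.start - 50, iv.end + 50, chrom, g.tss - 500, g.tss + 500,
                       score=float(rng.uniform(2, 20)), sample_id="synthetic").canonical()
        )
        planted_loops[rid] = g.gene_id
    del gene_by_id
    blacklist = RegionSet([GenomicInterval(chrom, 1_000, 2_000)])
    cancer = {g.gene_id for g in rng.choice(np.array(genes, dtype=object),
                                            size=int(cancer_fraction * n_genes), replace=False)}
    return AnnotationBundle(
        regions=regs,
        genes=genes,
        k27ac=RegionSet(k27ac_iv) if k27ac_iv else RegionSet([]),
        k4me1=RegionSet(k4me1_iv) if k4me1_iv else RegionSet([]),
        k27me3=RegionSet(k27me3_iv) if k27me3_iv else RegionSet([]),
        loops=loops,
        blacklist=blacklist,
        gene_sets={"cancer": cancer},
        planted_states=planted,
        planted_loops=planted_loops,
    )
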