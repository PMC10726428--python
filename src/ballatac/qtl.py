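"""Chromatin-accessibility QTL scan combining total and allelic evidence.

Candidate variants are biallelic SNVs inside open-chromatin regions that
pass imputation-quality (R^2 >= 0.80) and minor-allele-frequency gates.
Two orthogonal signals are tested per (variant, region) pair: a
total-count association (ordinary least squares of stabilized
accessibility on alt-allele dose, optional covariates) and allelic
imbalance (exact binomial test of the pooled alt fraction pi against 0.5
across heterozygous carriers, optional beta-binomial overdispersion).
The two p-values are merged by Fisher's method and a genome-wide
Benjamini-Hochberg FDR is applied; significance is called at q < 0.10.

beta is the log2 accessibility difference between homozygous alternative
and homozygous reference carriers (the regression is on dosage / 2).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import VariantRecord
from .regions import RegionSet

logger = logging.getLogger("ballatac")

__all__ = [
    "filter_variants",
    "total_assoc",
    "allelic_test",
    "combine_and_fdr",
    "qtl_scan",
    "qtl_footprint_overlap",
    "eqtl_concordance",
]


def filter_variants(
    variants: Sequence[VariantRecord],
    roi: RegionSet,
    min_r2: float = 0.80,
    min_maf: float = 0.05,
) -> list[tuple[VariantRecord, str]]:
    """Candidate (variant, containing region id) pairs after QC gates.

    Keeps biallelic SNVs located inside a region of interest whose
    imputation R^2 (1.0 when directly genotyped) is at least ``min_r2``
    and whose sample minor-allele frequency is at least ``min_maf``. A
    variant inside several (non-merged) regions pairs with each.
    """
    pairs: list[tuple[VariantRecord, str]] = []
    for v in variants:
        if v.r2 < min_r2 or v.maf() < min_maf:
            continue
        for idx in roi.overlapping_indices(v.chrom, v.pos, v.pos + 1):
            pairs.append((v, roi.ids[idx]))
    return pairs


def total_assoc(
    signal: np.ndarray,
    dosages: np.ndarray,
    covariates: np.ndarray | None = None,
) -> dict | None:
    """OLS of stabilized region signal on alt-allele dose.

    The regressor is dosage / 2, so beta estimates the log2 signal
    difference between the two homozygous genotype classes. Samples with
    missing dosage are dropped. Returns None (pair skipped) when the
    dosage is constant among retained samples.
    """
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(signal, dtype=float)
    keep = ~np.isnan(d)
    d, y = d[keep], y[keep]
    if np.unique(d).size < 2:
        return None
    g = d / 2.0
    X = g[:, None] if covariates is None else np.column_stack([g, np.asarray(covariates)[keep]])
    X = sm.add_constant(X, prepend=False)
    fit = sm.OLS(y, X).fit()
    return {
        "beta": float(fit.params[0]),
        "se_beta": float(fit.bse[0]),
        "p_total": float(fit.pvalues[0]),
        "n": int(keep.sum()),
    }


def allelic_test(
    ref_reads: Sequence[int],
    alt_reads: Sequence[int],
    min_het: int = 2,
    min_reads: int = 10,
    beta_binomial: bool = False,
) -> dict | None:
    """Allelic-imbalance test over heterozygous carriers of one variant.

    Reads are pooled across hets; pi = alt / (alt + ref) and the two-sided
    exact binomial test of pi = 0.5 gives p_allelic. Returns None when
    fewer than ``min_het`` informative hets or ``min_reads`` pooled reads
    are available. With ``beta_binomial`` and >= 5 hets, per-sample
    overdispersion is moment-estimated and a beta-binomial tail replaces
    the binomial one.
    """
    ref = np.asarray(ref_reads, dtype=int)
    alt = np.asarray(alt_reads, dtype=int)
    tot = ref + alt
    informative = tot > 0
    if informative.sum() < min_het or tot.sum() < min_reads:
        return None
    ref, alt, tot = ref[informative], alt[informative], tot[informative]
    n = int(tot.sum())
    a = int(alt.sum())
    pi = a / n
    if beta_binomial and len(tot) >= 5:
        # moment estimate of the intraclass correlation rho from per-het fractions
        fr = alt / tot
        vr = fr.var(ddof=1)
        mean_inv = (1.0 / tot).mean()
        p0 = fr.mean()
        denom = p0 * (1 - p0)
        rho = 0.0 if denom == 0 else max((vr - denom * mean_inv) / (denom * (1 - mean_inv)), 0.0)
        rho = min(rho, 0.99)
        if rho > 0:
            ab = (1.0 / rho - 1.0) / 2.0  # symmetric null: alpha = beta
            lo = stats.betabinom.cdf(a, n, ab, ab)
            hi = stats.betabinom.sf(a - 1, n, ab, ab)
            p = min(1.0, 2.0 * min(lo, hi))
            return {"pi": pi, "p_allelic": float(p), "n_het": len(tot), "n_reads": n}
    p = stats.binomtest(a, n, 0.5, alternative="two-sided").pvalue
    return {"pi": pi, "p_allelic": float(p), "n_het": len(tot), "n_reads": n}


def fisher_combine(p1: float | None, p2: float | None) -> float:
    """Fisher's method for two p-values; passes through a single one."""
    ps = [p for p in (p1, p2) if p is not None and np.isfinite(p)]
    if not ps:
        return float("nan")
    if len(ps) == 1:
        return float(ps[0])
    stat = -2.0 * np.sum(np.log(np.clip(ps, 1e-300, 1.0)))
    return float(stats.chi2.sf(stat, df=2 * len(ps)))


def combine_and_fdr(
    results: pd.DataFrame,
    fdr_level: float = 0.10,
) -> pd.DataFrame:
    """Fisher-combined p-values with genome-wide Benjamini-Hochberg FDR.

    ``results`` needs columns variant_id, region_id, pos, p_total and
    p_allelic (NaN where unavailable). Adds p_combined, qvalue, a
    ``significant`` flag at q < ``fdr_level`` and a ``lead`` flag marking,
    per region, the variant with the smallest combined p (position breaks
    ties).
    """
    df = results.copy()
    df["p_combined"] = [
        fisher_combine(
            pt if pd.notna(pt) else None,
            pa if pd.notna(pa) else None,
        )
        for pt, pa in zip(df["p_total"], df["p_allelic"])
    ]
    ok = df["p_combined"].notna()
    df["qvalue"] = np.nan
    if ok.any():
        df.loc[ok, "qvalue"] = multipletests(df.loc[ok, "p_combined"], method="fdr_bh")[1]
    df["significant"] = (df["qvalue"] < fdr_level).fillna(False)
    df["lead"] = False
    for _, grp in df[ok].groupby("region_id"):
        lead_idx = grp.sort_values(["p_combined", "pos"], kind="stable").index[0]
        df.at[lead_idx, "lead"] = True
    return df


def qtl_scan(
    stabilized: pd.DataFrame,
    variants: Sequence[VariantRecord],
    allele_counts: pd.DataFrame,
    roi: RegionSet,
    covariates: np.ndarray | None = None,
    min_r2: float = 0.80,
    min_maf: float = 0.05,
    min_het: int = 2,
    min_reads: int = 10,
    fdr_level: float = 0.10,
    beta_binomial: bool = False,
) -> pd.DataFrame:
    """End-to-end scan: filter, test, combine, FDR.

    ``stabilized`` is the variance-stabilized region x sample matrix;
    ``allele_counts`` has columns variant_id, sample_id, ref_reads,
    alt_reads recorded for heterozygous samples. Pairs whose total test is
    skipped (constant dosage) and whose allelic test is unavailable are
    dropped; a missing allelic test otherwise degrades the combined
    p-value to the total-association p alone.
    """
    samples = list(stabilized.columns)
    ac = allele_counts.set_index(["variant_id", "sample_id"]) if len(allele_counts) else None
    rows = []
    for v, rid in filter_variants(variants, roi, min_r2=min_r2, min_maf=min_maf):
        if rid not in stabilized.index:
            continue
        tot = total_assoc(stabilized.loc[rid].to_numpy(), v.dosages, covariates)
        allelic = None
        if ac is not None and v.id in ac.index.get_level_values(0):
            sub = ac.loc[v.id]
            het_samples = [s for s in sub.index if s in samples]
            if het_samples:
                allelic = allelic_test(
                    sub.loc[het_samples, "ref_reads"].to_numpy(),
                    sub.loc[het_samples, "alt_reads"].to_numpy(),
                    min_het=min_het,
                    min_reads=min_reads,
                    beta_binomial=beta_binomial,
                )
        if tot is None and allelic is None:
            continue
        rows.append(
            {
                "variant_id": v.id,
                "region_id": rid,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "beta": tot["beta"] if tot else np.nan,
                "se_beta": tot["se_beta"] if tot else np.nan,
                "p_total": tot["p_total"] if tot else np.nan,
                "pi": allelic["pi"] if allelic else np.nan,
                "p_allelic": allelic["p_allelic"] if allelic else np.nan,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["variant_id", "region_id", "chrom", "pos", "ref", "alt", "beta",
                     "se_beta", "p_total", "pi", "p_allelic", "p_combined", "qvalue",
                     "significant", "lead"]
        )
    return combine_and_fdr(pd.DataFrame(rows), fdr_level=fdr_level)


def qtl_footprint_overlap(
    qtls: pd.DataFrame,
    occurrences: pd.DataFrame,
) -> dict:
    """Fraction of QTLs falling inside a bound motif occurrence.

    ``occurrences`` needs columns motif_id, chrom, start, end, bound. Only
    bound occurrences count. Returns the overlap fraction and a per-motif
    abundance table sorted by descending QTL count.
    """
    bound = occurrences[occurrences["bound"]]
    per_motif: dict[str, int] = {}
    n_hit = 0
    for _, q in qtls.iterrows():
        hits = bound[
            (bound["chrom"] == q["chrom"]) & (bound["start"] <= q["pos"]) & (q["pos"] < bound["end"])
        ]
        if len(hits):
            n_hit += 1
            for m in hits["motif_id"].unique():
                per_motif[m] = per_motif.get(m, 0) + 1
    table = pd.Series(per_motif, dtype=int).sort_values(ascending=False)
    frac = n_hit / len(qtls) if len(qtls) else float("nan")
    return {"fraction": frac, "n_overlapping": n_hit, "per_motif": table}


def eqtl_concordance(
    qtls: pd.DataFrame,
    external: pd.DataFrame,
) -> dict:
    """Effect-direction concordance with an external eQTL table.

    Joined on variant_id; alleles are harmonized before comparing signs
    (an external record whose ref/alt are swapped relative to ours has its
    effect sign flipped; allele mismatches are excluded and counted).
    Concordant means sign(beta) equals the harmonized external sign.
    """
    ext = external.set_index("variant_id")
    n_shared = 0
    n_concordant = 0
    n_unorientable = 0
    for _, q in qtls.iterrows():
        if q["variant_id"] not in ext.index:
            continue
        e = ext.loc[q["variant_id"]]
        if e["ref"] == q["ref"] and e["alt"] == q["alt"]:
            sign_ext = np.sign(e["effect_sign"])
        elif e["ref"] == q["alt"] and e["alt"] == q["ref"]:
            sign_ext = -np.sign(e["effect_sign"])
        else:
            n_unorientable += 1
            continue
        n_shared += 1
        if np.sign(q["beta"]) == sign_ext:
            n_concordant += 1
    if n_unorientable:
        logger.info("eqtl_concordance: %d unorientable records excluded", n_unorientable)
    return {
        "n_shared": n_shared,
        "concordant_fraction": n_concordant / n_shared if n_shared else float("nan"),
        "n_unorientable": n_unorientable,
    }
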