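"""Count normalization and negative-binomial differential accessibility.

The engine is a per-region negative-binomial log-link GLM with a fixed
(moment-estimated, trend-shrunk) dispersion, fit by iteratively reweighted
least squares vectorized across all regions at once, with a
normal-approximation Wald test on the contrast coefficient and
Benjamini-Hochberg adjustment within each contrast. On top of it sit the
cohort-level selection rules: one-vs-rest subtype contrasts with an
exclusivity filter (a subtype-enriched site must be significant in exactly
one subtype), the union-style progenitor identity loci at a stricter
adjusted-p gate, the leukemia-vs-Pro-B contrast, and a Kolmogorov-Smirnov
test of differential-site proximity to differentially expressed genes.

No fold-change shrinkage, independent filtering, or outlier handling is
applied; those deltas versus reference count-model tools are deliberate
and documented in the methods note.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix, NormalizationError, ValidationError, parse_region_id
from .regions import RegionSet

logger = logging.getLogger("ballatac")

__all__ = [
    "size_factors",
    "stabilize",
    "estimate_dispersion",
    "nb_wald",
    "one_vs_rest",
    "exclusivity_filter",
    "progenitor_identity_loci",
    "ball_vs_prob",
    "deg_proximity_ks",
]

LN2 = np.log(2.0)
ALPHA_MIN = 1e-8


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def size_factors(counts: CountMatrix | pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j, s_j is the median over reference rows of
    count_ij / geomean_i, where reference rows have all-positive counts.
    With ``pseudo_reference`` the geometric mean is taken over positive
    entries only (rows with any positive count qualify), for sparse
    matrices without an all-positive row.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    k = df.to_numpy(dtype=float)
    if pseudo_reference:
        with np.errstate(divide="ignore"):
            logk = np.where(k > 0, np.log(k), np.nan)
        ref = np.exp(np.nanmean(logk, axis=1))
        rows = ~np.isnan(ref) & (ref > 0)
    else:
        rows = (k > 0).all(axis=1)
        if not rows.any():
            raise NormalizationError(
                "no all-positive reference row; consider pseudo_reference=True"
            )
        ref = np.exp(np.log(k[rows]).mean(axis=1))
        ratios = k[rows] / ref[:, None]
        return pd.Series(np.median(ratios, axis=0), index=df.columns, name="size_factor")
    if not rows.any():
        raise NormalizationError("no usable reference row")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = k[rows] / ref[rows][:, None]
    ratios = np.where(k[rows] > 0, ratios, np.nan)
    s = np.nanmedian(ratios, axis=0)
    if np.isnan(s).any() or (s <= 0).any():
        raise NormalizationError("degenerate size factor for some sample")
    return pd.Series(s, index=df.columns, name="size_factor")


def stabilize(
    counts: CountMatrix | pd.DataFrame,
    sf: pd.Series | np.ndarray,
    zscore: bool = False,
) -> pd.DataFrame:
    """Variance-stabilized signal v_ij = log2(count_ij / s_j + 1).

    ``zscore=True`` additionally standardizes each region row to mean 0 and
    unit standard deviation (rows with zero spread stay at 0), the form
    used for heatmaps and classifier feature matrices.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    s = np.asarray(sf, dtype=float)
    v = np.log2(df.to_numpy(dtype=float) / s[None, :] + 1.0)
    if zscore:
        mu = v.mean(axis=1, keepdims=True)
        sd = v.std(axis=1, ddof=0, keepdims=True)
        v = np.where(sd > 0, (v - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(v, index=df.index, columns=df.columns)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def estimate_dispersion(
    counts: CountMatrix | pd.DataFrame,
    sf: pd.Series | np.ndarray,
    groups: Sequence | None = None,
) -> pd.Series:
    """Per-region NB dispersion: moment estimate shrunk to a mean trend.

    The raw estimate on normalized counts is alpha_i = max((v_i - m_i) /
    m_i^2, 1e-8) with m and v the mean and unbiased variance. When
    ``groups`` is given, m and v pool within-group moments (group-wise
    means, pooled residual variance), so real group effects do not inflate
    the dispersion; with a single group this reduces to the marginal
    formula. A robust linear trend of log alpha on log mean is then fit;
    below-trend estimates are shrunk halfway toward it in log space while
    above-trend estimates are kept as-is (downward shrinkage would
    understate the test SE exactly where multiple testing selects for it).
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    s = np.asarray(sf, dtype=float)
    q = df.to_numpy(dtype=float) / s[None, :]
    n = q.shape[1]
    if n < 3:
        raise ValidationError("dispersion estimation needs >= 3 samples")
    if groups is None:
        m = q.mean(axis=1)
        v = q.var(axis=1, ddof=1)
    else:
        groups = np.asarray(groups)
        m = q.mean(axis=1)
        ss = np.zeros(q.shape[0])
        dof = 0
        for g in np.unique(groups):
            cols = groups == g
            ng = int(cols.sum())
            if ng < 2:
                continue
            sub = q[:, cols]
            ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            dof += ng - 1
        if dof < 1:
            raise ValidationError("no group with >= 2 samples for dispersion")
        v = ss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (v - m) / np.where(m > 0, m**2, np.nan)
    raw = np.where(np.isfinite(raw), raw, ALPHA_MIN)
    raw = np.maximum(raw, ALPHA_MIN)

    # robust trend in log-log space over informative rows
    ok = (m > 0) & (raw > ALPHA_MIN * 10)
    if ok.sum() >= 10:
        x = np.log(m[ok])
        y = np.log(raw[ok])
        slope, intercept = _robust_line(x, y)
        with np.errstate(divide="ignore"):
            trend = np.where(m > 0, np.exp(intercept + slope * np.log(np.maximum(m, 1e-12))), np.nan)
        trend = np.where(np.isfinite(trend), trend, np.exp(np.median(y)))
    else:
        trend = np.full_like(raw, max(np.median(raw), ALPHA_MIN))
    trend = np.maximum(trend, ALPHA_MIN)
    # shrink toward the trend from below only: multiple testing selects
    # regions whose dispersion came out low by chance, and pulling
    # above-trend estimates further down understates the Wald SE and
    # manufactures discoveries (conservative sharing, in the spirit of the
    # max-of-fit-and-estimate mode of early count-model tools)
    alpha = np.maximum(np.exp(0.5 * (np.log(raw) + np.log(trend))), raw)
    alpha = np.maximum(alpha, ALPHA_MIN)
    return pd.Series(alpha, index=df.index, name="dispersion")


def _robust_line(x: np.ndarray, y: np.ndarray, n_iter: int = 5) -> tuple[float, float]:
    """Tukey-bisquare reweighted least-squares line; returns (slope, intercept)."""
    w = np.ones_like(x)
    slope = intercept = 0.0
    for _ in range(n_iter):
        W = w.sum()
        xb = (w * x).sum() / W
        yb = (w * y).sum() / W
        sxx = (w * (x - xb) ** 2).sum()
        slope = (w * (x - xb) * (y - yb)).sum() / sxx if sxx > 0 else 0.0
        intercept = yb - slope * xb
        r = y - (intercept + slope * x)
        s = np.median(np.abs(r)) / 0.6745 or 1.0
        u = np.clip(r / (4.685 * s), -1, 1)
        w = (1 - u**2) ** 2
    return slope, intercept


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def build_design(
    samples: pd.DataFrame,
    group_indicator: np.ndarray,
    covariates: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Intercept + one-hot covariates (first level reference) + group column.

    The group indicator is the final column, named ``group``; its
    coefficient is the tested contrast (log fold change of indicator 1 over
    indicator 0).
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(samples))}
    for cov in covariates or ():
        col = samples[cov]
        if pd.api.types.is_numeric_dtype(col):
            x = col.to_numpy(dtype=float)
            cols[cov] = x - x.mean()
        else:
            levels = sorted(col.astype(str).unique())
            for lv in levels[1:]:
                cols[f"{cov}[{lv}]"] = (col.astype(str) == lv).to_numpy(dtype=float)
    cols["group"] = np.asarray(group_indicator, dtype=float)
    X = pd.DataFrame(cols, index=samples.index)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValidationError("design matrix is rank deficient")
    return X


# ---------------------------------------------------------------------------
# NB Wald GLM (vectorized IRLS)
# ---------------------------------------------------------------------------

def nb_wald(
    counts: CountMatrix | pd.DataFrame,
    sf: pd.Series | np.ndarray,
    dispersions: pd.Series | np.ndarray,
    design: pd.DataFrame,
    coef: str = "group",
    max_iter: int = 50,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Negative-binomial Wald test for one coefficient, all regions at once.

    Fits, per region i, counts ~ NB(mu, alpha_i) with log mu = log s_j +
    x_j' beta_i by IRLS with the dispersion held fixed, then reports
    log2FC = beta_coef / ln 2, its standard error from the observed Fisher
    information, the Wald statistic and a two-sided p-value from a t
    reference with n - p degrees of freedom, plus a
    Benjamini-Hochberg adjusted p across converged regions. Regions whose
    IRLS does not converge within ``max_iter`` get missing p-values and are
    excluded from the adjustment (count logged).
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    Y = df.to_numpy(dtype=float)
    s = np.asarray(sf, dtype=float)
    alpha = np.asarray(dispersions, dtype=float)[:, None]
    X = design.to_numpy(dtype=float)
    ci = list(design.columns).index(coef)
    R, n = Y.shape
    p = X.shape[1]
    offset = np.log(s)[None, :]

    # init from a log-linear least-squares fit
    eta0 = np.log(Y / s[None, :] + 0.5)
    pinv = np.linalg.pinv(X)
    B = eta0 @ pinv.T  # (R, p)

    converged = np.zeros(R, dtype=bool)
    XtWX = np.empty((R, p, p))
    for _ in range(max_iter):
        eta = np.clip(B @ X.T + offset, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (Y - mu) / mu
        XtWX = np.einsum("ni,rn,nj->rij", X, W, X, optimize=True)
        XtWz = np.einsum("ni,rn,rn->ri", X, W, z, optimize=True)
        XtWX_reg = XtWX + 1e-10 * np.eye(p)[None]
        B_new = np.linalg.solve(XtWX_reg, XtWz[..., None])[..., 0]
        delta = np.abs(B_new - B).max(axis=1)
        newly = (delta < tol) & ~converged
        converged |= newly
        B = B_new
        if converged.all():
            break
    n_fail = int((~converged).sum())
    if n_fail:
        logger.info("nb_wald: %d/%d regions failed to converge", n_fail, R)

    cov = np.linalg.inv(XtWX + 1e-10 * np.eye(p)[None])
    se = np.sqrt(np.maximum(cov[:, ci, ci], 0.0))
    beta = B[:, ci]
    log2fc = beta / LN2
    lfc_se = se / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, beta / se, 0.0)
    # t reference with residual df: the dispersion is plugged in, and the
    # normal tail is visibly too light for cohort-scale sample sizes
    pval = 2.0 * stats.t.sf(np.abs(wald), df=max(n - p, 1))
    pval = np.where(converged & (se > 0), pval, np.nan)

    padj = np.full(R, np.nan)
    ok = ~np.isnan(pval)
    if ok.any():
        padj[ok] = multipletests(pval[ok], method="fdr_bh")[1]

    base_mean = (Y / s[None, :]).mean(axis=1)
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "lfcSE": lfc_se,
            "wald_stat": wald,
            "pvalue": pval,
            "padj": padj,
            "converged": converged,
        },
        index=df.index,
    )


# ---------------------------------------------------------------------------
# cohort-level selection rules
# ---------------------------------------------------------------------------

def one_vs_rest(
    counts: CountMatrix,
    group_col: str = "subtype",
    covariates: Sequence[str] | None = None,
    padj_max: float = 0.05,
    min_abs_lfc: float = 1.0,
    rest_exclude: Sequence[str] = (),
    dispersions: pd.Series | None = None,
    sf: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """One-vs-rest contrasts: each subtype against all other samples pooled.

    Subtypes with fewer than two samples are skipped (logged). Labels in
    ``rest_exclude`` (e.g. a catch-all group) never form their own contrast
    and are dropped from every rest pool. Each returned frame carries a
    ``significant`` flag: padj < ``padj_max`` and |log2FC| >= ``min_abs_lfc``.
    Size factors and dispersions are computed once on the full matrix
    (dispersion pooled within subtype) unless supplied.
    """
    labels = counts.samples[group_col].astype(str)
    if sf is None:
        sf = size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersion(counts, sf, groups=labels.to_numpy())
    usable = labels[~labels.isin(rest_exclude)]
    results: dict[str, pd.DataFrame] = {}
    for subtype in sorted(usable.unique()):
        n_sub = int((usable == subtype).sum())
        if n_sub < 2:
            logger.info("one_vs_rest: skipping singleton subtype %r", subtype)
            continue
        keep = ~labels.isin([x for x in rest_exclude if x != subtype])
        sub_counts = counts.counts.loc[:, keep.to_numpy()]
        sub_samples = counts.samples.loc[keep.to_numpy()]
        indicator = (labels[keep] == subtype).to_numpy(dtype=float)
        design = build_design(sub_samples, indicator, covariates)
        res = nb_wald(sub_counts, sf[keep.to_numpy()], dispersions, design)
        res["significant"] = (
            (res["padj"] < padj_max) & (res["log2FC"].abs() >= min_abs_lfc)
        ).fillna(False)
        results[subtype] = res
    return results


def exclusivity_filter(per_subtype: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Subtype-enriched catalog: regions significant in exactly one subtype.

    Regions differential in two or more one-vs-rest contrasts are excluded
    outright. Direction is enriched when log2FC > 0 in the single
    significant contrast, depleted otherwise. Returns a frame indexed by
    region id with columns subtype, direction, log2FC, padj.
    """
    sig_sets = {st: res.index[res["significant"]].to_numpy() for st, res in per_subtype.items()}
    counts_per_region: dict[str, int] = {}
    for ids in sig_sets.values():
        for rid in ids:
            counts_per_region[rid] = counts_per_region.get(rid, 0) + 1
    rows = []
    for st, res in per_subtype.items():
        for rid in sig_sets[st]:
            if counts_per_region[rid] != 1:
                continue
            lfc = res.at[rid, "log2FC"]
            rows.append(
                {
                    "region_id": rid,
                    "subtype": st,
                    "direction": "enriched" if lfc > 0 else "depleted",
                    "log2FC": lfc,
                    "padj": res.at[rid, "padj"],
                }
            )
    catalog = pd.DataFrame(rows, columns=["region_id", "subtype", "direction", "log2FC", "padj"])
    return catalog.set_index("region_id").sort_index()


def progenitor_identity_loci(
    windowed_counts: CountMatrix,
    stage_col: str = "stage",
    padj_max: float = 0.005,
    min_abs_lfc: float = 1.0,
    covariates: Sequence[str] | None = None,
    windows: RegionSet | None = None,
) -> RegionSet:
    """Developmental-stage identity loci over fixed-width windows.

    Union over one-vs-rest stage contrasts of significant windows at the
    stricter padj < 0.005 gate; unlike the subtype catalog, exclusivity is
    NOT required, so a window differential for several stages is kept once.

    When the matrix rows are windowed ids with parent suffixes rather than
    ``chrom:start-end``, pass the windowed RegionSet so ids map back to
    coordinates.
    """
    per_stage = one_vs_rest(
        windowed_counts,
        group_col=stage_col,
        covariates=covariates,
        padj_max=padj_max,
        min_abs_lfc=min_abs_lfc,
    )
    ids: set[str] = set()
    for res in per_stage.values():
        ids.update(res.index[res["significant"]])
    kept = sorted(ids)
    if windows is not None:
        lookup = {rid: iv for rid, iv in zip(windows.ids, windows)}
        intervals = [lookup[rid] for rid in kept]
    else:
        intervals = [parse_region_id(rid) for rid in kept]
    return RegionSet(intervals, ids=kept, provenance="das")


def ball_vs_prob(
    counts: CountMatrix,
    group_col: str = "group",
    case_label: str = "B-ALL",
    control_label: str = "Pro-B",
    padj_max: float = 0.05,
    min_abs_lfc: float = 1.0,
    covariates: Sequence[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Single leukemia-vs-progenitor contrast, split by direction.

    Returns {'all', 'case_enriched', 'control_enriched'}; enrichment is the
    sign of log2FC (case over control) among significant regions. Run
    without covariates by default.
    """
    labels = counts.samples[group_col].astype(str)
    keep = labels.isin([case_label, control_label]).to_numpy()
    sub = counts.subset_samples(list(counts.samples.index[keep]))
    lab = sub.samples[group_col].astype(str)
    if (lab == case_label).sum() < 2 or (lab == control_label).sum() < 2:
        raise ValidationError("both contrast groups need >= 2 samples")
    sf = size_factors(sub)
    disp = estimate_dispersion(sub, sf, groups=lab.to_numpy())
    design = build_design(sub.samples, (lab == case_label).to_numpy(dtype=float), covariates)
    res = nb_wald(sub, sf, disp, design)
    res["significant"] = ((res["padj"] < padj_max) & (res["log2FC"].abs() >= min_abs_lfc)).fillna(False)
    sig = res[res["significant"]]
    return {
        "all": res,
        "case_enriched": sig[sig["log2FC"] > 0],
        "control_enriched": sig[sig["log2FC"] < 0],
    }


def deg_proximity_ks(
    das: RegionSet,
    deg_tss: Sequence[tuple[str, int]],
    background_tss: Sequence[tuple[str, int]],
    alternative: str = "two-sided",
) -> dict[str, float]:
    """KS test of DAS proximity for DEG versus background TSSs.

    For each TSS the distance to the nearest DAS midpoint (same chromosome)
    is computed; the two distance samples are compared with a two-sample
    Kolmogorov-Smirnov test. ``alternative='less'`` tests the one-sided
    hypothesis that DEG TSSs are nearer.
    """
    if len(das) == 0:
        raise ValueError("empty DAS set")
    if not len(deg_tss) or not len(background_tss):
        raise ValueError("TSS lists must be non-empty")
    mids: dict[str, np.ndarray] = {}
    for iv in das:
        mids.setdefault(iv.chrom, []).append(iv.midpoint)  # type: ignore[arg-type]
    mids = {c: np.sort(np.asarray(v)) for c, v in mids.items()}

    def nearest(tss_list: Sequence[tuple[str, int]]) -> np.ndarray:
        out = np.empty(len(tss_list))
        for i, (chrom, pos) in enumerate(tss_list):
            arr = mids.get(chrom)
            if arr is None:
                out[i] = np.inf
                continue
            j = np.searchsorted(arr, pos)
            cands = arr[max(j - 1, 0): j + 1]
            out[i] = np.abs(cands - pos).min()
        return out

    d_deg = nearest(deg_tss)
    d_bg = nearest(background_tss)
    ks = stats.ks_2samp(d_deg, d_bg, alternative=alternative, method="auto")
    return {"D": float(ks.statistic), "pvalue": float(ks.pvalue)}
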