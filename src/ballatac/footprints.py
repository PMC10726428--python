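"""Tn5-insertion footprint scoring and differential TF binding.

A transcription factor bound at its motif blocks Tn5 transposition, so an
occupied occurrence shows a local dip in per-base insertion counts inside
the motif core relative to the immediate flanks. The footprint score (FPS)
quantifies this as flank-minus-core mean on a profile normalized to unit
mean, so it is invariant to sequencing depth. Bound/unbound calls come
from a two-component Gaussian mixture over occurrence scores. Group
differences (ΔFPS) are averaged over occurrences scored in both groups,
with a sign-flip permutation p-value; subtype-enriched factors are chosen
by taking, per motif and subtype, the median ΔFPS against every other
subtype and ranking ("top median" selection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ConfigError
from .regions import RegionSet

logger = logging.getLogger("ballatac")

__all__ = [
    "MotifOccurrence",
    "InsertionProfile",
    "footprint_score",
    "bound_call",
    "differential_footprint",
    "pairwise_subtype_matrix",
    "top_median_selection",
    "footprints_at_regions",
]


@dataclass(frozen=True)
class MotifOccurrence:
    motif_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    roi_id: str | None = None

    @property
    def occurrence_id(self) -> str:
        return f"{self.motif_id}@{self.chrom}:{self.start}-{self.end}"


@dataclass
class InsertionProfile:
    """Per-base Tn5 insertion counts over [-w_out, motif, +w_out].

    ``counts`` has length motif_length + 2 * w_out; ``w_out`` locates the
    motif core inside the window.
    """

    occurrence_id: str
    group_id: str
    counts: np.ndarray
    w_out: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if (self.counts < 0).any():
            raise ValueError("negative insertion counts")
        if self.counts.size <= 2 * self.w_out:
            raise ValueError("window shorter than its flanks")

    @property
    def motif_length(self) -> int:
        return self.counts.size - 2 * self.w_out

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def footprint_score(
    profile: InsertionProfile,
    flank_width: int = 30,
    min_cov: int = 20,
) -> float:
    """Flank-minus-core depletion score; NaN when coverage is too low.

    The profile is normalized to mean 1 over the whole window; FPS is the
    mean over the two ``flank_width``-bp flanks adjacent to the motif core
    minus the mean over the core. Deeper core depletion gives a larger
    score; a uniform profile scores 0, and the score is invariant to
    scaling the profile by any positive constant.
    """
    if flank_width < 1 or flank_width > profile.w_out:
        raise ConfigError(f"flank_width {flank_width} outside [1, w_out={profile.w_out}]")
    total = profile.total
    if total < min_cov:
        return float("nan")
    norm = profile.counts / profile.counts.mean()
    w = profile.w_out
    m = profile.motif_length
    core = norm[w: w + m]
    flank = np.concatenate([norm[w - flank_width: w], norm[w + m: w + m + flank_width]])
    return float(flank.mean() - core.mean())


def bound_call(
    scores: Mapping[str, float] | pd.Series,
    seed: int = 0,
    min_occurrences: int = 20,
    separation_sd: float = 0.1,
) -> tuple[pd.Series, float]:
    """Bound/unbound split of footprint scores for one motif and group.

    Fits a 2-component Gaussian mixture (k-means initialized, fixed seed)
    to the finite scores; occurrences with posterior > 0.5 for the
    upper-mean component are called bound. When the fitted component means
    sit within ``separation_sd`` pooled standard deviations of each other
    the fit is degenerate and a mean + 1 sd threshold is used instead.
    Fewer than ``min_occurrences`` scored occurrences yields all-unbound.
    Returns (bound flags indexed by occurrence, threshold used; the
    threshold is NaN on the mixture path).
    """
    s = pd.Series(scores, dtype=float)
    finite = s[np.isfinite(s)]
    flags = pd.Series(False, index=s.index)
    if len(finite) < min_occurrences:
        logger.warning("bound_call: only %d scored occurrences; all unbound", len(finite))
        return flags, float("nan")
    x = finite.to_numpy()[:, None]
    pooled_sd = float(finite.std(ddof=0))
    if pooled_sd <= 1e-12 * max(1.0, abs(float(finite.mean()))):
        # effectively identical scores: no separation, nothing is bound
        return flags, float(finite.mean())
    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(n_components=2, init_params="kmeans", random_state=seed, n_init=1)
    gm.fit(x)
    mu = gm.means_.ravel()
    if abs(mu[0] - mu[1]) < separation_sd * pooled_sd:
        thr = float(finite.mean() + finite.std(ddof=0))
        flags.loc[finite.index] = finite > thr
        return flags, thr
    upper = int(np.argmax(mu))
    post = gm.predict_proba(x)[:, upper]
    flags.loc[finite.index] = post > 0.5
    return flags, float("nan")


def _paired_scores(
    profiles_a: Sequence[InsertionProfile],
    profiles_b: Sequence[InsertionProfile],
    flank_width: int,
    min_cov: int,
) -> np.ndarray:
    """Per-occurrence FPS differences (A - B) over jointly scored occurrences."""
    fa = {p.occurrence_id: footprint_score(p, flank_width, min_cov) for p in profiles_a}
    fb = {p.occurrence_id: footprint_score(p, flank_width, min_cov) for p in profiles_b}
    shared = sorted(set(fa) & set(fb))
    d = np.array([fa[o] - fb[o] for o in shared])
    return d[np.isfinite(d)]


def differential_footprint(
    profiles_a: Sequence[InsertionProfile],
    profiles_b: Sequence[InsertionProfile],
    motif_id: str = ".",
    group_a: str = "A",
    group_b: str = "B",
    n_perm: int = 1000,
    seed: int = 0,
    flank_width: int = 30,
    min_cov: int = 20,
    min_occurrences: int = 10,
) -> dict:
    """Group ΔFPS for one motif with a sign-flip permutation p-value.

    ΔFPS is the mean over occurrences scored in both groups of
    FPS_A - FPS_B; z standardizes it by the empirical standard error.
    Swapping group labels within an occurrence flips the sign of its
    difference, so the permutation null flips signs independently
    (seeded); the two-sided p uses the add-one rule. Results with fewer
    than ``min_occurrences`` joint occurrences are flagged unreliable.
    """
    d = _paired_scores(profiles_a, profiles_b, flank_width, min_cov)
    n = d.size
    reliable = n >= min_occurrences
    if n == 0:
        return {
            "motif_id": motif_id, "group_a": group_a, "group_b": group_b,
            "delta_fps": float("nan"), "z": float("nan"), "pvalue": float("nan"),
            "n_occurrences": 0, "reliable": False,
        }
    delta = float(d.mean())
    sd = float(d.std(ddof=1)) if n > 1 else 0.0
    z = delta / (sd / np.sqrt(n)) if sd > 0 else (0.0 if delta == 0 else np.inf * np.sign(delta))
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    perm = (signs * d[None, :]).mean(axis=1)
    pval = (np.sum(np.abs(perm) >= abs(delta)) + 1.0) / (n_perm + 1.0)
    return {
        "motif_id": motif_id, "group_a": group_a, "group_b": group_b,
        "delta_fps": delta, "z": float(z), "pvalue": float(pval),
        "n_occurrences": int(n), "reliable": bool(reliable),
    }


def pairwise_subtype_matrix(
    profiles: Mapping[str, Mapping[str, Sequence[InsertionProfile]]],
    motifs: Sequence[str] | None = None,
    flank_width: int = 30,
    min_cov: int = 20,
) -> pd.DataFrame:
    """Per-subtype median pairwise ΔFPS for every motif.

    ``profiles[group][motif]`` holds the group-pooled insertion profiles.
    Entry (motif, s) is the median over all other subtypes t of
    ΔFPS(s, t) = mean per-occurrence FPS_s - FPS_t, emphasizing factors
    consistently more protected in s than in each other subtype. Signed
    scores are used (enrichment-seeking).
    """
    groups = sorted(profiles)
    if len(groups) < 2:
        raise ConfigError("need at least 2 subtypes")
    if motifs is None:
        motifs = sorted({m for g in groups for m in profiles[g]})
    mat = pd.DataFrame(index=list(motifs), columns=groups, dtype=float)
    for motif in motifs:
        # score each group's occurrences once
        per_group = {
            g: {p.occurrence_id: footprint_score(p, flank_width, min_cov)
                for p in profiles[g].get(motif, ())}
            for g in groups
        }
        for s in groups:
            deltas = []
            for t in groups:
                if t == s:
                    continue
                shared = set(per_group[s]) & set(per_group[t])
                d = np.array([per_group[s][o] - per_group[t][o] for o in sorted(shared)])
                d = d[np.isfinite(d)]
                if d.size:
                    deltas.append(d.mean())
            mat.at[motif, s] = float(np.median(deltas)) if deltas else np.nan
    mat.index.name = "motif_id"
    return mat


def top_median_selection(matrix: pd.DataFrame, top_n: int = 10) -> dict[str, list[str]]:
    """Top motifs per subtype by descending median pairwise ΔFPS.

    Ties at the cut resolve to lexicographically first motif id; NaN rows
    never rank.
    """
    if top_n < 1:
        raise ConfigError("top_n must be >= 1")
    out: dict[str, list[str]] = {}
    for subtype in matrix.columns:
        col = matrix[subtype].dropna()
        ranked = col.sort_index().sort_values(ascending=False, kind="stable")
        out[subtype] = list(ranked.index[:top_n])
    return out


def footprints_at_regions(
    profiles_a: Sequence[InsertionProfile],
    profiles_b: Sequence[InsertionProfile],
    occurrences: Mapping[str, MotifOccurrence],
    das: RegionSet,
    **kwargs,
) -> dict:
    """differential_footprint restricted to occurrences inside a region set.

    ``occurrences`` maps occurrence_id to its genomic location; profiles
    whose occurrence does not intersect ``das`` are dropped before testing.
    """
    def inside(p: InsertionProfile) -> bool:
        occ = occurrences.get(p.occurrence_id)
        return occ is not None and das.overlaps_any(occ.chrom, occ.start, occ.end)

    return differential_footprint(
        [p for p in profiles_a if inside(p)],
        [p for p in profiles_b if inside(p)],
        **kwargs,
    )
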