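"""Genomic interval algebra and region-of-interest procedures.

Implements the open-chromatin catalog construction used throughout the
pipeline: reproducibility-filtered summit extension into 301-bp intervals,
overlap merging and blacklist removal; fixed-width windowing; midpoint
annotation against a gene model; histone-mark chromatin-state calls; and
loop-anchor overlap reports. All coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ConfigError,
    GeneModelRecord,
    LoopRecord,
    PeakRecord,
    region_id,
)

logger = logging.getLogger("ballatac")

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "merge_intervals",
    "select_roi",
    "window_regions",
    "annotate_regions",
    "classify_chromatin_state",
    "overlap_loops",
    "overlap_fraction",
]

ANNOTATION_PRECEDENCE = ("promoter", "5'UTR", "3'UTR", "exon", "intron", "distal_intergenic")
CHROMATIN_STATES = ("active", "bivalent_poised", "repressed", "unmarked")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class RegionSet:
    """An ordered set of genomic intervals with stable string ids.

    Intervals are kept in genomic sort order (chromosome lexicographic,
    then start). Merge-producing operations guarantee pairwise
    non-overlapping output; the constructor itself does not merge.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval | tuple],
        ids: Sequence[str] | None = None,
        provenance: str = "custom",
    ) -> None:
        ivs = [
            iv if isinstance(iv, GenomicInterval) else GenomicInterval(iv[0], int(iv[1]), int(iv[2]))
            for iv in intervals
        ]
        if ids is None:
            ids = [region_id(iv.chrom, iv.start, iv.end) for iv in ivs]
        else:
            ids = list(ids)
            if len(ids) != len(ivs):
                raise ValueError("ids length does not match intervals")
        order = sorted(range(len(ivs)), key=lambda i: (ivs[i].chrom, ivs[i].start, ivs[i].end))
        self._intervals = [ivs[i] for i in order]
        self._ids = [ids[i] for i in order]
        self.provenance = provenance
        # per-chromosome numpy views for fast overlap queries
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[int]] = {}
        for i, iv in enumerate(self._intervals):
            by_chrom.setdefault(iv.chrom, []).append(i)
        for chrom, idx in by_chrom.items():
            starts = np.array([self._intervals[i].start for i in idx])
            ends = np.array([self._intervals[i].end for i in idx])
            self._index[chrom] = (starts, ends, np.array(idx))

    # -- container protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._intervals[i]

    @property
    def ids(self) -> list[str]:
        return list(self._ids)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self._intervals],
                "start": [iv.start for iv in self._intervals],
                "end": [iv.end for iv in self._intervals],
                "region_id": self._ids,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "custom") -> "RegionSet":
        ids = df["region_id"].tolist() if "region_id" in df.columns else None
        return cls(
            (GenomicInterval(c, int(s), int(e)) for c, s, e in zip(df["chrom"], df["start"], df["end"])),
            ids=ids,
            provenance=provenance,
        )

    # -- queries -----------------------------------------------------------
    def overlaps_any(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) on chrom intersects any interval by >=1 bp."""
        hit = self._index.get(chrom)
        if hit is None:
            return False
        starts, ends, _ = hit
        lo = np.searchsorted(starts, end, side="left")
        return bool((ends[:lo] > start).any())

    def overlapping_indices(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices (into this set) of intervals intersecting [start, end)."""
        hit = self._index.get(chrom)
        if hit is None:
            return np.array([], dtype=int)
        starts, ends, idx = hit
        lo = np.searchsorted(starts, end, side="left")
        mask = ends[:lo] > start
        return idx[:lo][mask]

    def overlap_flags(self, other: "RegionSet") -> np.ndarray:
        """Boolean per interval of self: intersects other by >=1 bp."""
        return np.array(
            [other.overlaps_any(iv.chrom, iv.start, iv.end) for iv in self._intervals]
        )


def merge_intervals(
    intervals: Iterable[GenomicInterval | tuple], provenance: str = "custom"
) -> RegionSet:
    """Merge overlapping intervals into a sorted, non-overlapping set.

    Book-ended intervals ([a,b) and [b,c)) are kept separate: merging
    requires >=1 bp of genuine overlap, so the union of covered bases is
    preserved exactly.
    """
    ivs = sorted(
        (
            iv if isinstance(iv, GenomicInterval) else GenomicInterval(iv[0], int(iv[1]), int(iv[2]))
            for iv in intervals
        ),
        key=lambda iv: (iv.chrom, iv.start, iv.end),
    )
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            merged.append(iv)
    return RegionSet(merged, provenance=provenance)


# ---------------------------------------------------------------------------
# region-of-interest selection
# ---------------------------------------------------------------------------

def select_roi(
    subtype_summits: Mapping[str, Sequence[tuple[str, int]]],
    per_sample_peaks: Mapping[str, Sequence[PeakRecord]],
    sample_subtypes: Mapping[str, str],
    blacklist: RegionSet | None = None,
    min_support: int = 2,
    half_width: int = 150,
    support_mode: str = "summit",
) -> RegionSet:
    """Build the open-chromatin region-of-interest catalog.

    Pipeline: (1) keep each subtype-level summit supported by peaks of at
    least ``min_support`` distinct samples of that subtype; (2) extend each
    surviving summit s symmetrically to [s-half_width, s+half_width+1), a
    301-bp interval at the default; (3) merge overlapping intervals; (4)
    discard any merged interval intersecting the blacklist by >=1 bp.

    ``support_mode`` controls the reproducibility check: "summit" counts a
    sample when one of its peaks contains the summit position, "interval"
    when one of its peaks overlaps the extended interval.

    Parameters
    ----------
    subtype_summits
        Map subtype -> list of (chrom, summit position).
    per_sample_peaks
        Map sample_id -> its narrowPeak records (already q-filtered).
    sample_subtypes
        Map sample_id -> subtype label.
    """
    if min_support < 1:
        raise ConfigError("min_support must be >= 1")
    if support_mode not in ("summit", "interval"):
        raise ConfigError(f"unknown support_mode {support_mode!r}")

    # per-sample merged peak index for fast containment tests
    sample_index: dict[str, RegionSet] = {
        sid: merge_intervals((p.chrom, p.start, p.end) for p in peaks) if peaks else RegionSet([])
        for sid, peaks in per_sample_peaks.items()
    }
    samples_by_subtype: dict[str, list[str]] = {}
    for sid in per_sample_peaks:
        st = sample_subtypes.get(sid)
        if st is None:
            raise ConfigError(f"sample {sid!r} has no subtype assignment")
        samples_by_subtype.setdefault(st, []).append(sid)

    known_chroms = {iv.chrom for rs in sample_index.values() for iv in rs}
    extended: list[GenomicInterval] = []
    for subtype, summits in subtype_summits.items():
        sids = samples_by_subtype.get(subtype, [])
        for chrom, pos in summits:
            if chrom not in known_chroms:
                logger.warning("summit %s:%d on chromosome absent from all peaks", chrom, pos)
            lo = max(pos - half_width, 0)
            hi = pos + half_width + 1
            if support_mode == "summit":
                support = sum(
                    sample_index[sid].overlaps_any(chrom, pos, pos + 1) for sid in sids
                )
            else:
                support = sum(sample_index[sid].overlaps_any(chrom, lo, hi) for sid in sids)
            if support >= min_support:
                extended.append(GenomicInterval(chrom, lo, hi))

    merged = merge_intervals(extended, provenance="roi")
    if blacklist is not None and len(blacklist):
        keep = [iv for iv in merged if not blacklist.overlaps_any(iv.chrom, iv.start, iv.end)]
        merged = RegionSet(keep, provenance="roi")
    return merged


def window_regions(regions: RegionSet, width: int = 250) -> RegionSet:
    """Tile each region into consecutive fixed-width windows.

    Windows run left to right; a final partial window shorter than half the
    width is absorbed into the previous window (or kept alone when the
    region itself is shorter than the width). Covered bases are conserved
    exactly. Window ids carry the parent id with a ``_w<k>`` suffix.
    """
    if width < 1:
        raise ConfigError("window width must be >= 1")
    out_iv: list[GenomicInterval] = []
    out_ids: list[str] = []
    for iv, pid in zip(regions, regions.ids):
        edges = list(range(iv.start, iv.end, width)) + [iv.end]
        if len(edges) > 2 and (edges[-1] - edges[-2]) * 2 < width:
            del edges[-2]  # absorb short remainder into the previous window
        for k in range(len(edges) - 1):
            out_iv.append(GenomicInterval(iv.chrom, edges[k], edges[k + 1]))
            out_ids.append(f"{pid}_w{k}")
    return RegionSet(out_iv, ids=out_ids, provenance="windowed")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _annotate_midpoint(
    chrom: str,
    m: int,
    genes: Sequence[GeneModelRecord],
    promoter_window: tuple[int, int],
) -> tuple[str, str | None, int | None]:
    """Classify one midpoint; returns (category, gene_id, signed TSS distance)."""
    up, down = promoter_window
    best_cat = "distal_intergenic"
    best_rank = len(ANNOTATION_PRECEDENCE) - 1
    nearest_gene: str | None = None
    nearest_dist: int | None = None
    for g in genes:
        if g.chrom != chrom:
            continue
        # signed distance: positive downstream of the TSS in gene orientation
        dist = (m - g.tss) if g.strand == "+" else (g.tss - m)
        if nearest_dist is None or abs(dist) < abs(nearest_dist):
            nearest_dist, nearest_gene = dist, g.gene_id
        cat = None
        if -up <= dist <= down:
            cat = "promoter"
        elif g.start <= m < g.end:
            in_exon = any(s <= m < e for s, e in g.exons)
            if in_exon:
                cat = "exon"
                if g.cds_start is not None:
                    five_side = m < g.cds_start if g.strand == "+" else m >= g.cds_end
                    three_side = m >= g.cds_end if g.strand == "+" else m < g.cds_start
                    if five_side:
                        cat = "5'UTR"
                    elif three_side:
                        cat = "3'UTR"
            else:
                cat = "intron"
        if cat is not None:
            rank = ANNOTATION_PRECEDENCE.index(cat)
            if rank < best_rank:
                best_rank, best_cat = rank, cat
    return best_cat, nearest_gene, nearest_dist


def annotate_regions(
    regions: RegionSet,
    genes: Sequence[GeneModelRecord],
    promoter_window: tuple[int, int] = (2000, 500),
) -> pd.DataFrame:
    """Assign each region one genomic category by its midpoint.

    Precedence is promoter > 5'UTR > 3'UTR > exon > intron >
    distal_intergenic, with the promoter window spanning
    ``promoter_window[0]`` bp upstream to ``promoter_window[1]`` bp
    downstream of the TSS in gene orientation. Distances to the nearest TSS
    are signed (positive downstream). Regions on chromosomes absent from
    the gene model become distal_intergenic with missing gene.
    """
    if not genes:
        raise ValueError("gene model is empty")
    rows = []
    for iv, rid in zip(regions, regions.ids):
        cat, gene, dist = _annotate_midpoint(iv.chrom, iv.midpoint, genes, promoter_window)
        rows.append({"region_id": rid, "category": cat, "nearest_gene": gene, "tss_distance": dist})
    return pd.DataFrame(rows).set_index("region_id")


def classify_chromatin_state(
    regions: RegionSet,
    k27ac: RegionSet,
    k4me1: RegionSet,
    k27me3: RegionSet,
) -> pd.DataFrame:
    """Histone-mark chromatin state per region.

    active: (H3K27ac or H3K4me1) without H3K27me3; bivalent_poised:
    H3K27me3 together with an active mark; repressed: H3K27me3 alone;
    unmarked otherwise. "Has mark" means >=1 bp overlap. The four states
    partition the region set.
    """
    ac = regions.overlap_flags(k27ac)
    me1 = regions.overlap_flags(k4me1)
    me3 = regions.overlap_flags(k27me3)
    act = ac | me1
    state = np.where(
        act & ~me3, "active", np.where(act & me3, "bivalent_poised", np.where(me3, "repressed", "unmarked"))
    )
    return pd.DataFrame({"region_id": regions.ids, "state": state}).set_index("region_id")


def overlap_loops(
    regions: RegionSet,
    loops: Sequence[LoopRecord],
    genes: Sequence[GeneModelRecord],
    gene_set: set[str] | None = None,
    promoter_window: tuple[int, int] = (2000, 500),
) -> pd.DataFrame:
    """Per-region loop participation and looped-gene report.

    A region is in a loop when it overlaps either anchor; its looped genes
    are those whose promoter window overlaps the opposite anchor.
    ``in_gene_set`` flags regions looped to a member of ``gene_set``.
    """
    up, down = promoter_window
    prom_iv, prom_ids = [], []
    for g in genes:
        if g.strand == "+":
            lo, hi = g.tss - up, g.tss + down + 1
        else:
            lo, hi = g.tss - down, g.tss + up + 1
        prom_iv.append(GenomicInterval(g.chrom, max(lo, 0), hi))
        prom_ids.append(g.gene_id)
    promoters = RegionSet(prom_iv, ids=prom_ids)

    rows = []
    for iv, rid in zip(regions, regions.ids):
        looped: set[str] = set()
        in_loop = False
        for lp in loops:
            hit1 = iv.chrom == lp.chrom1 and iv.start < lp.end1 and lp.start1 < iv.end
            hit2 = iv.chrom == lp.chrom2 and iv.start < lp.end2 and lp.start2 < iv.end
            if not (hit1 or hit2):
                continue
            in_loop = True
            for other in ([(lp.chrom2, lp.start2, lp.end2)] if hit1 else []) + (
                [(lp.chrom1, lp.start1, lp.end1)] if hit2 else []
            ):
                for gi in promoters.overlapping_indices(*other):
                    looped.add(promoters.ids[gi])
        rows.append(
            {
                "region_id": rid,
                "in_loop": in_loop,
                "looped_genes": sorted(looped),
                "in_gene_set": bool(gene_set and looped & gene_set),
            }
        )
    return pd.DataFrame(rows).set_index("region_id")


def overlap_fraction(a: RegionSet, b: RegionSet) -> float:
    """Fraction of a's regions intersecting b by >=1 bp."""
    if len(a) == 0:
        raise ValueError("overlap fraction undefined for an empty region set")
    return float(a.overlap_flags(b).mean())
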