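"""Activity-by-contact element-to-gene scoring and TF-target networks.

An element's effect on a gene is modeled as its regulatory activity A (the
geometric mean of ATAC and H3K27ac signal) weighted by its contact C with
the gene promoter (promoter capture Hi-C loop score; 0 without a loop),
normalized over the gene's candidate elements:

    ABC(e, g) = A_e * C_{e,g} / sum_{e'} A_{e'} * C_{e',g}

Predictions at ABC >= 0.04 feed the network stage, which joins
subtype-enriched differential sites, bound motif occurrences and retained
element-gene links into TF -> target-gene edges ranked by differential
footprint signal (TFs) and expression (genes).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModelRecord, LoopRecord
from .regions import GenomicInterval, RegionSet

logger = logging.getLogger("ballatac")

__all__ = [
    "region_activity",
    "candidate_elements",
    "abc_scores",
    "build_tf_target_network",
]

ABC_THRESHOLD = 0.04


def region_activity(
    atac: pd.Series | np.ndarray,
    k27ac: pd.Series | np.ndarray,
    pseudocount: float = 0.0,
) -> pd.Series | np.ndarray:
    """Element activity A = sqrt((atac + pc) * (k27ac + pc)).

    Symmetric in its two inputs; equals the common value when they agree
    and the pseudocount is 0.
    """
    a = np.asarray(atac, dtype=float)
    k = np.asarray(k27ac, dtype=float)
    if (a < 0).any() or (k < 0).any():
        raise ValueError("activity inputs must be non-negative")
    out = np.sqrt((a + pseudocount) * (k + pseudocount))
    if isinstance(atac, pd.Series):
        return pd.Series(out, index=atac.index, name="activity")
    return out


def candidate_elements(
    elements: RegionSet,
    genes: Sequence[GeneModelRecord],
    loops: Sequence[LoopRecord],
    max_dist: int = 2_000_000,
    promoter_window: tuple[int, int] = (2000, 500),
) -> pd.DataFrame:
    """Candidate (element, gene) pairs within ``max_dist`` with contact C.

    An element is a candidate for every gene whose TSS lies within
    ``max_dist`` of its midpoint on the same chromosome. Contact is the
    summed score of loops joining the element (either anchor) to the gene
    promoter window (opposite anchor); elements without such a loop get
    C = 0.
    """
    up, down = promoter_window
    rows = []
    for iv, rid in zip(elements, elements.ids):
        mid = iv.midpoint
        for g in genes:
            if g.chrom != iv.chrom or abs(g.tss - mid) > max_dist:
                continue
            if g.strand == "+":
                p_lo, p_hi = g.tss - up, g.tss + down + 1
            else:
                p_lo, p_hi = g.tss - down, g.tss + up + 1
            contact = 0.0
            for lp in loops:
                a1 = iv.chrom == lp.chrom1 and iv.start < lp.end1 and lp.start1 < iv.end
                a2 = iv.chrom == lp.chrom2 and iv.start < lp.end2 and lp.start2 < iv.end
                p1 = g.chrom == lp.chrom1 and p_lo < lp.end1 and lp.start1 < p_hi
                p2 = g.chrom == lp.chrom2 and p_lo < lp.end2 and lp.start2 < p_hi
                if (a1 and p2) or (a2 and p1):
                    contact += lp.score
            rows.append({"region_id": rid, "gene_id": g.gene_id, "contact": contact})
    return pd.DataFrame(rows, columns=["region_id", "gene_id", "contact"])


def abc_scores(
    candidates: pd.DataFrame,
    activity: Mapping[str, float] | pd.Series,
    include_promoter: bool = True,
    promoter_activity: Mapping[str, float] | None = None,
    threshold: float = ABC_THRESHOLD,
) -> pd.DataFrame:
    """Normalized activity-by-contact scores per candidate element.

    ``candidates`` holds (region_id, gene_id, contact) rows; ``activity``
    maps region ids to A. With ``include_promoter`` each gene additionally
    receives its own promoter as a candidate (region id
    ``<gene>:promoter``) whose contact is the maximum contact observed for
    that gene and whose activity comes from ``promoter_activity``. Scores
    for each gene sum to 1 over its candidates; rows with
    ``abc_score >= threshold`` are flagged ``retained``. Genes whose total
    A*C is zero yield no predictions (logged).
    """
    act = dict(activity.items() if hasattr(activity, "items") else activity)
    frames = []
    dropped = 0
    for gene, grp in candidates.groupby("gene_id", sort=True):
        rows = grp[["region_id", "contact"]].copy()
        rows["activity"] = rows["region_id"].map(act)
        if rows["activity"].isna().any():
            missing = rows.loc[rows["activity"].isna(), "region_id"].tolist()
            raise KeyError(f"no activity for elements {missing[:3]}")
        if include_promoter and promoter_activity and gene in promoter_activity:
            rows = pd.concat(
                [
                    rows,
                    pd.DataFrame(
                        {
                            "region_id": [f"{gene}:promoter"],
                            "contact": [rows["contact"].max() if len(rows) else 0.0],
                            "activity": [promoter_activity[gene]],
                        }
                    ),
                ],
                ignore_index=True,
            )
        rows["gene_id"] = gene
        ac = rows["activity"] * rows["contact"]
        total = ac.sum()
        if total <= 0:
            dropped += 1
            continue
        rows["abc_score"] = ac / total
        frames.append(rows)
    if dropped:
        logger.info("abc_scores: %d genes with zero total activity*contact", dropped)
    if not frames:
        return pd.DataFrame(columns=["region_id", "gene_id", "contact", "activity", "abc_score", "retained"])
    out = pd.concat(frames, ignore_index=True)
    out["retained"] = out["abc_score"] >= threshold
    return out[["region_id", "gene_id", "contact", "activity", "abc_score", "retained"]]


def build_tf_target_network(
    das_catalog: pd.DataFrame,
    bound_occurrences: pd.DataFrame,
    abc: pd.DataFrame,
    gene_set: set[str],
    tf_scores: Mapping[str, float],
    gene_expression: Mapping[str, float],
    das_regions: RegionSet | None = None,
    top_tf_n: int = 10,
    top_gene_n: int = 20,
) -> pd.DataFrame:
    """TF -> target-gene edges through enriched differential sites.

    An edge (motif, gene) exists when a bound occurrence of the motif lies
    inside an enriched catalog region that carries a retained ABC link to
    a gene in ``gene_set``. TFs are ranked by mean differential footprint
    signal over their edges' motifs (``tf_scores``), genes by expression;
    the network is truncated to the top ``top_tf_n`` TFs and
    ``top_gene_n`` genes. ``bound_occurrences`` needs columns motif_id,
    chrom, start, end, bound; occurrence-to-region assignment uses
    ``das_regions`` (defaults to intervals parsed from catalog region
    ids).
    """
    from .io_formats import parse_region_id

    enriched = das_catalog[das_catalog["direction"] == "enriched"]
    if das_regions is None:
        das_regions = RegionSet(
            [GenomicInterval(*parse_region_id(rid)) for rid in enriched.index],
            ids=list(enriched.index),
        )
    retained = abc[abc["retained"] & abc["gene_id"].isin(gene_set)]
    links = retained.groupby("region_id")["gene_id"].apply(set).to_dict()

    edge_map: dict[tuple[str, str], set[str]] = {}
    bound = bound_occurrences[bound_occurrences["bound"]]
    for _, occ in bound.iterrows():
        for idx in das_regions.overlapping_indices(occ["chrom"], int(occ["start"]), int(occ["end"])):
            rid = das_regions.ids[idx]
            if rid not in enriched.index or rid not in links:
                continue
            for gene in links[rid]:
                edge_map.setdefault((occ["motif_id"], gene), set()).add(rid)
    if not edge_map:
        logger.info("build_tf_target_network: empty motif/region/gene intersection")
        return pd.DataFrame(
            columns=["motif_id", "gene_id", "supporting_regions", "tf_rank_score", "gene_rank_score"]
        )

    rows = [
        {
            "motif_id": m,
            "gene_id": g,
            "supporting_regions": sorted(rids),
            "tf_rank_score": float(tf_scores.get(m, np.nan)),
            "gene_rank_score": float(gene_expression.get(g, np.nan)),
        }
        for (m, g), rids in sorted(edge_map.items())
    ]
    edges = pd.DataFrame(rows)
    top_tfs = (
        edges.drop_duplicates("motif_id")
        .sort_values(["tf_rank_score", "motif_id"], ascending=[False, True], kind="stable")["motif_id"]
        .head(top_tf_n)
    )
    top_genes = (
        edges.drop_duplicates("gene_id")
        .sort_values(["gene_rank_score", "gene_id"], ascending=[False, True], kind="stable")["gene_id"]
        .head(top_gene_n)
    )
    out = edges[edges["motif_id"].isin(top_tfs) & edges["gene_id"].isin(top_genes)]
    return out.reset_index(drop=True)
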