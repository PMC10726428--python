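"""Readers and writers for the standard files the pipeline touches.

Every coordinate held in memory is 0-based half-open (BED convention);
1-based formats (VCF) are converted at the boundary on read and converted
back on write. Readers never reorder samples relative to the sample sheet.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ballatac")

__all__ = [
    "ParseError",
    "FormatError",
    "ValidationError",
    "ConfigError",
    "NormalizationError",
    "PeakRecord",
    "LoopRecord",
    "VariantRecord",
    "GeneModelRecord",
    "CountMatrix",
    "read_narrowpeak",
    "read_bedpe_loops",
    "read_vcf_minimal",
    "read_counts",
    "write_counts",
    "read_bed",
    "write_bed",
    "read_gene_model",
    "read_sample_sheet",
    "parse_region_id",
    "region_id",
]


class ParseError(ValueError):
    """A line of a text format could not be parsed."""


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Parsed content violates an invariant (negative count, duplicate id...)."""


class ConfigError(ValueError):
    """An operation was configured with an invalid parameter."""


class NormalizationError(ValueError):
    """Size-factor computation failed (e.g. no all-positive reference row)."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakRecord:
    """One ENCODE narrowPeak entry.

    ``summit_offset`` is the offset of the summit from ``start``; -1 means
    absent, in which case consumers fall back to the interval midpoint.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: int = 0
    strand: str = "."
    signal: float = 0.0
    pvalue_neglog10: float = -1.0
    qvalue_neglog10: float = -1.0
    summit_offset: int = -1

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid peak interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.summit_offset != -1 and not 0 <= self.summit_offset < self.end - self.start:
            raise ValidationError(
                f"summit offset {self.summit_offset} outside peak of width "
                f"{self.end - self.start}"
            )

    @property
    def summit(self) -> int:
        """Absolute summit position (midpoint when the offset is absent)."""
        if self.summit_offset == -1:
            return self.start + (self.end - self.start) // 2
        return self.start + self.summit_offset


@dataclass(frozen=True)
class LoopRecord:
    """A chromatin loop between two anchors, canonically ordered."""

    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    score: float = 0.0
    sample_id: str = "."

    @property
    def span(self) -> int:
        """Anchor-midpoint separation; only meaningful intrachromosomally."""
        m1 = (self.start1 + self.end1) // 2
        m2 = (self.start2 + self.end2) // 2
        return abs(m2 - m1)

    @property
    def intrachromosomal(self) -> bool:
        return self.chrom1 == self.chrom2

    def canonical(self) -> "LoopRecord":
        """Anchor1 first by (chrom, start)."""
        if (self.chrom2, self.start2) < (self.chrom1, self.start1):
            return LoopRecord(self.chrom2, self.start2, self.end2,
                              self.chrom1, self.start1, self.end1,
                              self.score, self.sample_id)
        return self


@dataclass
class VariantRecord:
    """A biallelic SNV with per-sample alt-allele dosages.

    ``pos`` is 0-based (converted from the 1-based VCF POS on read).
    ``imputation_r2`` of None means directly genotyped and is treated as 1.0
    by downstream filters. Dosages are floats in {0, 1, 2} with NaN for
    missing genotypes.
    """

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    dosages: np.ndarray
    imputation_r2: float | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt for variant {self.id}")
        self.dosages = np.asarray(self.dosages, dtype=float)

    @property
    def r2(self) -> float:
        return 1.0 if self.imputation_r2 is None else self.imputation_r2

    def maf(self) -> float:
        d = self.dosages[~np.isnan(self.dosages)]
        if d.size == 0:
            return 0.0
        f = float(d.mean()) / 2.0
        return min(f, 1.0 - f)


@dataclass
class GeneModelRecord:
    """A gene model with TSS, exon blocks and optional CDS bounds.

    ``tss`` is the block start on + strand and block end - 1 ... the last
    covered base ... on - strand (0-based). ``cds_start/cds_end`` come from
    the BED12 thick interval and enable UTR annotation; None when the thick
    interval is empty.
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    tss: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_start: int | None = None
    cds_end: int | None = None
    expression: float | None = None

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class CountMatrix:
    """Region x sample integer counts, aligned with a sample sheet.

    ``counts`` is a regions-by-samples integer DataFrame whose index holds
    region ids of the form ``chrom:start-end``; ``samples`` is indexed by
    sample_id in the same order as the columns and carries the group label
    and covariates.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValidationError("count columns do not match sample sheet order")
        if self.counts.isna().any().any():
            raise ValidationError("count matrix contains missing cells")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValidationError("negative counts")

    @property
    def region_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_regions(self, ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(ids)], self.samples)

    def subset_samples(self, ids: Sequence[str]) -> "CountMatrix":
        ids = list(ids)
        return CountMatrix(self.counts[ids], self.samples.loc[ids])


# ---------------------------------------------------------------------------
# region-id helpers
# ---------------------------------------------------------------------------

_REGION_ID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def region_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


def parse_region_id(rid: str) -> tuple[str, int, int]:
    m = _REGION_ID_RE.match(rid)
    if m is None:
        raise ParseError(f"malformed region id {rid!r}; expected chrom:start-end")
    return m.group("chrom"), int(m.group("start")), int(m.group("end"))


# ---------------------------------------------------------------------------
# narrowPeak
# ---------------------------------------------------------------------------

#: -log10 of the q < 0.05 gate applied to MACS2 narrowPeak calls on read.
DEFAULT_MIN_QVALUE_NEGLOG10 = -math.log10(0.05)


def read_narrowpeak(
    path: str | Path,
    min_qvalue_neglog10: float | None = DEFAULT_MIN_QVALUE_NEGLOG10,
) -> list[PeakRecord]:
    """Read a 10-column ENCODE narrowPeak file.

    Records with ``qvalue_neglog10 <= min_qvalue_neglog10`` are dropped;
    the default gate keeps peaks with q < 0.05. Pass None to disable the
    filter.
    """
    peaks: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise ParseError(
                    f"{path}:{lineno}: expected 10 narrowPeak columns, got {len(fields)}"
                )
            try:
                rec = PeakRecord(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    name=fields[3],
                    score=int(float(fields[4])),
                    strand=fields[5],
                    signal=float(fields[6]),
                    pvalue_neglog10=float(fields[7]),
                    qvalue_neglog10=float(fields[8]),
                    summit_offset=int(fields[9]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if min_qvalue_neglog10 is not None and not (
                rec.qvalue_neglog10 > min_qvalue_neglog10
            ):
                continue
            peaks.append(rec)
    return peaks


# ---------------------------------------------------------------------------
# BEDPE loops
# ---------------------------------------------------------------------------

def read_bedpe_loops(
    path: str | Path,
    max_span: int | None = 2_000_000,
    same_chrom_only: bool = True,
) -> list[LoopRecord]:
    """Read BEDPE loop calls; drop interchromosomal and long-span records.

    The defaults implement the significant-intrachromosomal-under-2-Mb rule
    used for promoter capture Hi-C loop libraries. Anchors are canonically
    ordered so anchor1 precedes anchor2 genomically.
    """
    loops: list[LoopRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}:{lineno}: expected >=6 BEDPE columns, got {len(fields)}"
                )
            try:
                c1, s1, e1 = fields[0], int(fields[1]), int(fields[2])
                c2, s2, e2 = fields[3], int(fields[4]), int(fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if min(s1, e1, s2, e2) < 0:
                raise ParseError(f"{path}:{lineno}: negative coordinate")
            name = fields[6] if len(fields) > 6 else "."
            score = float(fields[7]) if len(fields) > 7 and fields[7] != "." else 0.0
            rec = LoopRecord(c1, s1, e1, c2, s2, e2, score=score, sample_id=name).canonical()
            if same_chrom_only and not rec.intrachromosomal:
                continue
            if max_span is not None and rec.intrachromosomal and rec.span >= max_span:
                continue
            loops.append(rec)
    return loops


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_minimal(path: str | Path) -> list[VariantRecord]:
    """Read biallelic SNVs from a VCF 4.x file via cyvcf2.

    Multiallelic records and indels are skipped (count logged). Genotypes,
    phased or unphased, are collapsed to alt-allele dosage; missing
    genotypes become NaN. The INFO R2 field, when present, is carried as
    ``imputation_r2``. Positions are converted to 0-based.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exceptions for bad headers
        raise FormatError(f"{path}: not a readable VCF ({exc})") from exc

    records: list[VariantRecord] = []
    n_skipped = 0
    for rec in vcf:
        alts = rec.ALT
        if len(alts) != 1 or len(rec.REF) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        gts = rec.genotypes  # [[a, b, phased], ...]
        dosages = np.full(len(vcf.samples), np.nan)
        for j, gt in enumerate(gts):
            alleles = [a for a in gt[:-1] if a is not None and a >= 0]
            if alleles:
                dosages[j] = float(sum(alleles))
        r2 = rec.INFO.get("R2")
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alts[0]}"
        records.append(
            VariantRecord(
                id=vid,
                chrom=rec.CHROM,
                pos=rec.POS - 1,
                ref=rec.REF,
                alt=alts[0],
                dosages=dosages,
                imputation_r2=float(r2) if r2 is not None else None,
            )
        )
    if n_skipped:
        logger.info("read_vcf_minimal: skipped %d non-SNV/multiallelic records", n_skipped)
    return records


# ---------------------------------------------------------------------------
# count matrix / sample sheet
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, sample_sheet: pd.DataFrame | None = None) -> CountMatrix:
    """Read a region x sample TSV count matrix.

    First column is the region id ``chrom:start-end``; remaining columns are
    samples holding non-negative integers. When a sample sheet is supplied,
    columns are validated (not reordered) against it; otherwise a minimal
    sheet is fabricated from the column names.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate region ids: {dups[:5]}")
    for rid in df.index:
        parse_region_id(rid)
    vals = df.to_numpy()
    if np.isnan(vals.astype(float)).any():
        raise ValidationError("missing cells in count matrix")
    if (vals < 0).any():
        raise ValidationError("negative count in matrix")
    if not np.allclose(vals, np.round(vals.astype(float))):
        raise ValidationError("non-integer count in matrix")
    df = df.astype(np.int64)
    if sample_sheet is None:
        sample_sheet = pd.DataFrame(index=pd.Index(df.columns, name="sample_id"))
    else:
        if set(df.columns) != set(sample_sheet.index):
            raise ValidationError("count columns do not match sample sheet")
        sample_sheet = sample_sheet.loc[list(df.columns)]
    return CountMatrix(df, sample_sheet)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.rename_axis("region_id").to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path, group_col: str = "subtype") -> pd.DataFrame:
    """Read a TSV sample sheet indexed by unique sample_id.

    The group column (subtype or progenitor stage) must be present; all
    other columns are carried as covariates. B-other-style catch-all labels
    are preserved verbatim so downstream stages can include or exclude them.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError("sample sheet lacks a sample_id column")
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample ids in sample sheet")
    if group_col not in df.columns:
        raise FormatError(f"sample sheet lacks the group column {group_col!r}")
    return df.set_index("sample_id")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED3/BED6 as (chrom, start, end, name) tuples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            name = fields[3] if len(fields) > 3 else region_id(fields[0], start, end)
            out.append((fields[0], start, end, name))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_gene_model(path: str | Path, expression: dict[str, float] | None = None) -> list[GeneModelRecord]:
    """Read gene models from BED12.

    blockStarts/blockSizes become exon blocks; the thick interval becomes
    the CDS (None when degenerate); the TSS is taken from the strand. The
    BED name field is used as both gene_id and gene_name unless it contains
    ``id|name``.
    """
    genes: list[GeneModelRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{lineno}: expected 12 BED12 columns, got {len(f)}")
            try:
                start, end = int(f[1]), int(f[2])
                thick_start, thick_end = int(f[6]), int(f[7])
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError(f"{path}:{lineno}: blockCount does not match block lists")
            strand = f[5]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            name = f[3]
            gene_id, _, gene_name = name.partition("|")
            gene_name = gene_name or gene_id
            tss = start if strand == "+" else end - 1
            cds = (thick_start, thick_end) if thick_end > thick_start else (None, None)
            genes.append(
                GeneModelRecord(
                    gene_id=gene_id,
                    gene_name=gene_name,
                    chrom=f[0],
                    strand=strand,
                    tss=tss,
                    exons=exons,
                    cds_start=cds[0],
                    cds_end=cds[1],
                    expression=(expression or {}).get(gene_id),
                )
            )
    return genes
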