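"""Gene models and annotation I/O.

A gene model carries the coordinates both halves of the pipeline key on: the
strand-aware transcription start site (for ChIP tag-density windows) and the
exonic length (for FPKM).  Coordinates are 0-based half-open throughout (BED
convention); the TSS of a plus-strand gene is its ``start``, of a minus-strand
gene its ``end`` coordinate.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["GeneModel", "GenomeAnnotation", "read_bed12", "write_bed12"]


def _merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted list of disjoint intervals."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass(frozen=True)
class GeneModel:
    """One gene: id, location, strand and exon structure.

    ``exons`` are half-open ``(start, end)`` intervals in chromosome
    coordinates; they may be supplied unsorted or overlapping, the exonic
    length is the length of their union.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        for s, e in self.exons:
            if not self.start <= s < e <= self.end:
                raise ValueError(f"gene {self.gene_id}: exon ({s}, {e}) outside gene span")

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site (5' end of the gene)."""
        return self.start if self.strand == "+" else self.end

    @property
    def exonic_length(self) -> int:
        """Length in bp of the union of exon intervals (gene span if exonless)."""
        if not self.exons:
            return self.end - self.start
        return sum(e - s for s, e in _merge_intervals(self.exons))


class GenomeAnnotation:
    """An ordered collection of gene models with fast per-field access."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: list[GeneModel] = list(genes)
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicated gene ids: {dupes}")
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def exonic_lengths(self) -> pd.Series:
        return pd.Series(
            [g.exonic_length for g in self.genes], index=self.gene_ids, name="exonic_length"
        )

    def tss_table(self) -> pd.DataFrame:
        """Per-gene chrom, strand and TSS, indexed by gene id."""
        return pd.DataFrame(
            {
                "chrom": [g.chrom for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "tss": [g.tss for g in self.genes],
            },
            index=pd.Index(self.gene_ids, name="gene_id"),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "chrom": g.chrom,
                    "start": g.start,
                    "end": g.end,
                    "strand": g.strand,
                    "tss": g.tss,
                    "exonic_length": g.exonic_length,
                    "n_exons": len(g.exons),
                }
            )
        return pd.DataFrame(rows).set_index("gene_id")


def _opener(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_bed12(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write gene models as BED12 (one line per gene, exons as blocks)."""
    with _opener(path, "w") as fh:
        for g in annotation:
            exons = _merge_intervals(g.exons) if g.exons else [(g.start, g.end)]
            sizes = ",".join(str(e - s) for s, e in exons)
            starts = ",".join(str(s - g.start) for s, _ in exons)
            fields = [
                g.chrom,
                str(g.start),
                str(g.end),
                g.gene_id,
                "0",
                g.strand,
                str(g.start),
                str(g.end),
                "0",
                str(len(exons)),
                sizes,
                starts,
            ]
            fh.write("\t".join(fields) + "\n")


def read_bed12(path: str | Path) -> GenomeAnnotation:
    """Read gene models from a BED12 file (gzip tolerated)."""
    names = [
        "chrom", "start", "end", "name", "score", "strand",
        "thick_start", "thick_end", "rgb", "block_count", "block_sizes", "block_starts",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=names, comment="#", dtype=str)
    genes = []
    for row in df.itertuples(index=False):
        start = int(row.start)
        sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
        offsets = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
        exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
        genes.append(
            GeneModel(
                gene_id=row.name,
                chrom=row.chrom,
                start=start,
                end=int(row.end),
                strand=row.strand,
                exons=exons,
            )
        )
    return GenomeAnnotation(genes)
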