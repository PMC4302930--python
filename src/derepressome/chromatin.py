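"""H3K27me3 TSS tag-density scoring and high/low mark classification.

The chromatin half of the pipeline reduces a ChIP-seq tag library to one
number per gene: the count of tags within 2 kb of the transcription start
site.  Counts are log-normalized onto a bounded 0-10 scale anchored so that
10 is the smallest count capturing 95% of genes, and genes scoring at most
2/10 are classified as carrying low H3K27me3 signal, above 2/10 as high.

Tag strand is ignored (a histone mark has no strand); the TSS window is
strand-aware only through the TSS position itself.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .annotation import GenomeAnnotation

__all__ = [
    "TagSet",
    "ChromatinParams",
    "read_bed_tags",
    "count_tss_tags",
    "TssSignalScaler",
    "scale_to_ten",
    "classify_mark",
    "score_tss_density",
]

logger = logging.getLogger(__name__)


class TagSet:
    """ChIP-seq tag positions, held per chromosome in sorted order.

    Each tag is a single 0-based genomic position with a strand; only the
    position enters the density computation.
    """

    def __init__(self, tags: pd.DataFrame | None = None):
        if tags is None:
            tags = pd.DataFrame({"chrom": [], "pos": [], "strand": []})
        required = {"chrom", "pos", "strand"}
        if not required.issubset(tags.columns):
            raise ValueError(f"tag frame needs columns {sorted(required)}")
        if len(tags) and (tags["pos"] < 0).any():
            raise ValueError("tag positions must be >= 0")
        self.tags = tags.reset_index(drop=True)
        self._sorted: dict[str, np.ndarray] = {
            chrom: np.sort(sub["pos"].to_numpy(dtype=np.int64))
            for chrom, sub in self.tags.groupby("chrom", sort=True)
        }

    def __len__(self) -> int:
        return len(self.tags)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._sorted)

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of tags with start <= pos < end on one chromosome."""
        positions = self._sorted.get(chrom)
        if positions is None:
            return 0
        return int(np.searchsorted(positions, end) - np.searchsorted(positions, start))

    def to_bed(self, path: str | Path) -> None:
        """Write tags as BED6 (1-bp intervals)."""
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            for i, row in enumerate(self.tags.itertuples(index=False)):
                pos = int(row.pos)
                fh.write(f"{row.chrom}\t{pos}\t{pos + 1}\ttag_{i}\t0\t{row.strand}\n")


def read_bed_tags(path: str | Path) -> TagSet:
    """Read tags from BED (>=3 columns; strand taken from column 6 if present)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError("tag BED needs at least chrom, start, end columns")
    out = pd.DataFrame(
        {
            "chrom": df[0],
            "pos": df[1].astype(np.int64),
            "strand": df[5] if df.shape[1] >= 6 else ".",
        }
    )
    return TagSet(out)


@dataclass(frozen=True)
class ChromatinParams:
    """Knobs of the TSS density score.

    window_bp: half-width of the TSS window (tags in [TSS-w, TSS+w) count).
    capture_quantile: the scaled value 10 is anchored at the smallest raw
        count capturing this fraction of genes.
    threshold: scaled values <= threshold are 'low', above it 'high'.
    """

    window_bp: int = 2000
    capture_quantile: float = 0.95
    scale_max: float = 10.0
    threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")
        if not 0 < self.capture_quantile < 1:
            raise ValueError("capture_quantile must be in (0, 1)")
        if not 0 < self.threshold < self.scale_max:
            raise ValueError("need 0 < threshold < scale_max")


def count_tss_tags(
    tags: TagSet,
    annotation: GenomeAnnotation,
    params: ChromatinParams = ChromatinParams(),
) -> pd.Series:
    """Raw tag count within ``window_bp`` of each gene's TSS.

    The window is [TSS - w, TSS + w), half-open on the right, clipped at 0.
    Genes on chromosomes absent from the tag set count 0 (a warning is
    logged once per chromosome).
    """
    warned: set[str] = set()
    counts = np.empty(len(annotation), dtype=np.int64)
    for i, gene in enumerate(annotation):
        if gene.chrom not in tags._sorted and gene.chrom not in warned and len(tags):
            logger.warning("chromosome %s has no tags; its genes count 0", gene.chrom)
            warned.add(gene.chrom)
        lo = max(0, gene.tss - params.window_bp)
        counts[i] = tags.count_in(gene.chrom, lo, gene.tss + params.window_bp)
    return pd.Series(counts, index=pd.Index(annotation.gene_ids, name="gene_id"), name="raw_count")


class TssSignalScaler(TransformerMixin, BaseEstimator):
    """Log-normalize raw TSS tag counts onto a bounded 0-10 scale.

    ``fit`` learns the anchor count: the smallest raw count that captures
    ``capture_quantile`` of the genes (the empirical quantile taken as an
    element of the data).  ``transform`` maps a count ``r`` to

        min(scale_max, scale_max * log2(r + 1) / log2(anchor + 1)),

    so a gene at exactly the anchor scores exactly ``scale_max`` and counts
    above it are clipped.  An all-zero anchor maps everything to 0.

    Attributes
    ----------
    anchor_ : float
        The capture-quantile raw count learned by ``fit``.
    n_features_in_ : int
        Always 1 (a single count per gene).
    """

    def __init__(self, capture_quantile: float = 0.95, scale_max: float = 10.0):
        self.capture_quantile = capture_quantile
        self.scale_max = scale_max

    def _validate(self, X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 2 and arr.shape[1] == 1:
            arr = arr[:, 0]
        if arr.ndim != 1:
            raise ValueError("expected one raw count per gene (1-d array or single column)")
        if arr.size == 0:
            raise ValueError("need at least one gene")
        if (arr < 0).any() or not np.isfinite(arr).all():
            raise ValueError("raw counts must be finite and >= 0")
        return arr

    def fit(self, X, y=None) -> "TssSignalScaler":
        if not 0 < self.capture_quantile < 1:
            raise ValueError("capture_quantile must be in (0, 1)")
        arr = self._validate(X)
        # smallest data value whose ECDF reaches the capture quantile
        self.anchor_ = float(np.quantile(arr, self.capture_quantile, method="inverted_cdf"))
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "anchor_")
        arr = self._validate(X)
        if self.anchor_ <= 0:
            return np.zeros_like(arr)
        scaled = self.scale_max * np.log2(arr + 1.0) / np.log2(self.anchor_ + 1.0)
        return np.minimum(scaled, self.scale_max)


def scale_to_ten(raw_counts: pd.Series, params: ChromatinParams = ChromatinParams()) -> pd.Series:
    """Functional wrapper over :class:`TssSignalScaler` (fit and transform in one)."""
    scaler = TssSignalScaler(
        capture_quantile=params.capture_quantile, scale_max=params.scale_max
    )
    values = scaler.fit_transform(np.asarray(raw_counts, dtype=float))
    return pd.Series(values, index=raw_counts.index, name="scaled")


def classify_mark(scaled: pd.Series, params: ChromatinParams = ChromatinParams()) -> pd.Series:
    """'low' if scaled <= threshold (2/10 by default), else 'high'."""
    values = np.asarray(scaled, dtype=float)
    if (values < 0).any() or (values > params.scale_max).any():
        bad = np.flatnonzero((values < 0) | (values > params.scale_max))
        raise ValueError(f"scaled values outside [0, {params.scale_max}] at rows {bad[:5]}")
    classes = np.where(values <= params.threshold, "low", "high")
    return pd.Series(classes, index=scaled.index, name="mark_class")


def score_tss_density(
    tags: TagSet,
    annotation: GenomeAnnotation,
    params: ChromatinParams = ChromatinParams(),
) -> pd.DataFrame:
    """Full chromatin table: raw window count, 0-10 scaled value, mark class."""
    raw = count_tss_tags(tags, annotation, params)
    scaled = scale_to_ten(raw, params)
    mark = classify_mark(scaled, params)
    return pd.DataFrame({"raw_count": raw, "scaled": scaled, "mark_class": mark})
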