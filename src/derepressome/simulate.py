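"""Synthetic study generator: annotation, RNA-seq counts, ChIP tags, truth.

Emulates the measurement structure of a sorted-endothelium knockout study:
two genotypes (control vs methyltransferase-null), one RNA-seq library per
embryo replicate, and one H3K27me3 ChIP tag library from control cells.
About 18% of genes carry the repressive mark; a small marked subset is
truly derepressed (upregulated) in the mutant, a smaller marked subset
downregulated, and an unmarked set is differentially expressed for reasons
unrelated to the mark.  Marked genes sit at a 4-fold lower expression
baseline, as repressed chromatin dictates.

Counts are simulated at gene level (the analysis consumes per-gene
quantities; no reads, no aligner): negative-binomial RNA fragments with a
common dispersion, Poisson ChIP tags with uniform background plus TSS-window
enrichment at marked genes.  Coordinates are 0-based half-open.

Everything is driven by one seed; the same config is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import GeneModel, GenomeAnnotation, read_bed12, write_bed12
from .chromatin import TagSet, read_bed_tags
from .expression import CountMatrix, read_design

__all__ = [
    "SimulationConfig",
    "generate_annotation",
    "make_truth",
    "simulate_rnaseq_counts",
    "simulate_chip_tags",
    "simulate_study",
    "write_fixture",
    "read_fixture",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic fixture.

    Scale parameters (gene number, marked fraction, target counts) echo the
    proportions of a mouse endothelium study at desk scale; sequencing depth
    is kept realistic so that count noise, not depth, limits detection.
    """

    n_genes: int = 2000
    fraction_marked: float = 0.18
    n_targets_up: int = 50
    n_targets_down: int = 6
    n_unmarked_de: int = 80
    replicates_per_condition: int = 3
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 1.0
    marked_baseline_factor: float = 0.25
    min_target_baseline: float = 1.0
    nb_dispersion: float = 0.05
    target_log2fc_mean: float = 2.0
    target_log2fc_sd: float = 0.25
    chip_background_rate: float = 5e-5
    chip_enrichment_factor: float = 200.0
    chip_window_bp: int = 2000
    library_size: int = 30_000_000
    n_chromosomes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("n_genes", self.n_genes >= 1),
            ("fraction_marked", 0.0 <= self.fraction_marked <= 1.0),
            ("n_targets_up", self.n_targets_up >= 0),
            ("n_targets_down", self.n_targets_down >= 0),
            ("n_unmarked_de", self.n_unmarked_de >= 0),
            ("replicates_per_condition", self.replicates_per_condition >= 2),
            ("baseline_log_sd", self.baseline_log_sd > 0),
            ("marked_baseline_factor", self.marked_baseline_factor > 0),
            ("min_target_baseline", self.min_target_baseline >= 0),
            ("nb_dispersion", self.nb_dispersion >= 0),
            ("target_log2fc_sd", self.target_log2fc_sd >= 0),
            ("chip_background_rate", self.chip_background_rate > 0),
            ("chip_enrichment_factor", self.chip_enrichment_factor >= 1),
            ("chip_window_bp", self.chip_window_bp > 0),
            ("library_size", self.library_size > 0),
            ("n_chromosomes", self.n_chromosomes >= 1),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"invalid configuration field: {name}={getattr(self, name)!r}")
        n_marked = round(self.fraction_marked * self.n_genes)
        if self.n_targets_up + self.n_targets_down > n_marked:
            raise ValueError(
                "invalid configuration field: n_targets_up + n_targets_down "
                f"({self.n_targets_up + self.n_targets_down}) exceeds the marked gene "
                f"count ({n_marked})"
            )
        n_unmarked = self.n_genes - n_marked
        if self.n_unmarked_de > n_unmarked:
            raise ValueError(
                f"invalid configuration field: n_unmarked_de={self.n_unmarked_de} exceeds "
                f"the unmarked gene count ({n_unmarked})"
            )

    @property
    def n_marked(self) -> int:
        return round(self.fraction_marked * self.n_genes)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent deterministic stream per generator stage
    return np.random.default_rng([config.seed, stream])


def generate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Gene models on synthetic chromosomes with realistic spacing.

    Exonic lengths are log-normal around 1.5 kb (floor 200 bp); genes carry
    1-8 exons separated by short introns; strands are random.  Neighbouring
    TSS windows may occasionally overlap, which downstream code tolerates.
    """
    rng = _rng(config, 0)
    genes: list[GeneModel] = []
    width = len(str(config.n_genes))
    cursors = {f"chr{c + 1}": 10_000 for c in range(config.n_chromosomes)}
    chrom_names = sorted(cursors)
    for i in range(config.n_genes):
        chrom = chrom_names[i % config.n_chromosomes]
        start = cursors[chrom] + int(rng.integers(5_000, 25_000))
        exonic = int(np.clip(rng.lognormal(np.log(1500.0), 0.6), 200, 20_000))
        n_exons = int(min(8, 1 + rng.poisson(2)))
        cuts = np.sort(rng.choice(np.arange(1, exonic), size=n_exons - 1, replace=False)) \
            if n_exons > 1 and exonic > n_exons else np.array([], dtype=int)
        sizes = np.diff(np.concatenate([[0], cuts, [exonic]])).astype(int)
        sizes = sizes[sizes > 0]
        introns = rng.integers(200, 3_000, size=len(sizes) - 1) if len(sizes) > 1 else []
        exons = []
        pos = start
        for j, size in enumerate(sizes):
            exons.append((pos, pos + int(size)))
            pos += int(size)
            if j < len(sizes) - 1:
                pos += int(introns[j])
        end = exons[-1][1]
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"gene_{i:0{width}d}",
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                exons=tuple(exons),
            )
        )
        cursors[chrom] = end
    return GenomeAnnotation(genes)


def make_truth(annotation: GenomeAnnotation, config: SimulationConfig) -> pd.DataFrame:
    """Ground truth per gene: mark status, target class, effect, baseline.

    Exactly ``round(fraction_marked * n_genes)`` genes are marked; direct
    targets (up or down in the mutant) are drawn from the marked set, the
    unmarked differentially expressed set from the rest.  Marked genes get a
    ``marked_baseline_factor``-fold depressed baseline; direct targets are
    redrawn until their silenced baseline is detectably expressed
    (``min_target_baseline`` FPKM) — a derepression phenotype presupposes a
    measurable transcript.
    """
    rng = _rng(config, 1)
    ids = annotation.gene_ids
    n = len(ids)
    marked = np.zeros(n, dtype=bool)
    marked_idx = rng.choice(n, size=config.n_marked, replace=False)
    marked[marked_idx] = True
    up_idx = rng.choice(marked_idx, size=config.n_targets_up, replace=False)
    remaining = np.setdiff1d(marked_idx, up_idx)
    down_idx = rng.choice(remaining, size=config.n_targets_down, replace=False)
    unmarked_idx = np.flatnonzero(~marked)
    ude_idx = rng.choice(unmarked_idx, size=config.n_unmarked_de, replace=False)

    target_class = np.array(["none"] * n, dtype=object)
    target_class[up_idx] = "up"
    target_class[down_idx] = "down"

    lfc = np.zeros(n)
    lfc[up_idx] = rng.normal(config.target_log2fc_mean, config.target_log2fc_sd, len(up_idx))
    lfc[down_idx] = -rng.normal(config.target_log2fc_mean, config.target_log2fc_sd, len(down_idx))
    signs = rng.choice([-1.0, 1.0], size=len(ude_idx))
    lfc[ude_idx] = signs * rng.normal(
        config.target_log2fc_mean, config.target_log2fc_sd, len(ude_idx)
    )

    baseline = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, n))
    baseline[marked] *= config.marked_baseline_factor
    for g in np.concatenate([up_idx, down_idx]):
        while baseline[g] < config.min_target_baseline:
            baseline[g] = config.marked_baseline_factor * np.exp(
                rng.normal(config.baseline_log_mean, config.baseline_log_sd)
            )

    unmarked_de = np.zeros(n, dtype=bool)
    unmarked_de[ude_idx] = True
    return pd.DataFrame(
        {
            "is_marked": marked,
            "target_class": target_class,
            "unmarked_de": unmarked_de,
            "true_log2fc": lfc,
            "baseline_mean_expression": baseline,
        },
        index=pd.Index(ids, name="gene_id"),
    )


def simulate_rnaseq_counts(
    annotation: GenomeAnnotation, truth: pd.DataFrame, config: SimulationConfig
) -> tuple[CountMatrix, pd.Series]:
    """Negative-binomial fragment counts per gene and replicate library.

    The expected control count follows the gene's baseline FPKM, exonic
    length and library size; the mutant mean is the control mean times
    ``2 ** true_log2fc``.  Dispersion is shared across genes; dispersion 0
    degenerates to Poisson.
    """
    if config.replicates_per_condition < 2:
        raise ValueError(
            "replicates_per_condition must be >= 2: the permutation test downstream "
            "needs exchangeable replicates"
        )
    missing = [g for g in annotation.gene_ids if g not in truth.index]
    if missing:
        raise ValueError(f"truth table does not cover genes {missing[:5]}")
    rng = _rng(config, 2)
    truth = truth.loc[annotation.gene_ids]
    lengths = annotation.exonic_lengths().to_numpy(dtype=float)
    depth = (lengths / 1e3) * (config.library_size / 1e6)
    mu_ctrl = truth["baseline_mean_expression"].to_numpy() * depth
    mu_mut = mu_ctrl * 2.0 ** truth["true_log2fc"].to_numpy()

    reps = config.replicates_per_condition
    samples = [f"control_{i + 1}" for i in range(reps)] + [f"mutant_{i + 1}" for i in range(reps)]

    def draw(mu: np.ndarray) -> np.ndarray:
        mu_col = np.maximum(mu, 1e-12)[:, None]
        if config.nb_dispersion == 0:
            return rng.poisson(np.broadcast_to(mu_col, (len(mu), reps)))
        r = 1.0 / config.nb_dispersion
        return rng.negative_binomial(r, r / (r + mu_col), size=(len(mu), reps))

    counts = np.hstack([draw(mu_ctrl), draw(mu_mut)])
    frame = pd.DataFrame(counts, index=truth.index, columns=samples)
    library = pd.Series(float(config.library_size), index=samples, name="library_size")
    design = pd.Series(
        ["control"] * reps + ["mutant"] * reps, index=pd.Index(samples, name="sample"),
        name="condition",
    )
    return CountMatrix(frame, library), design


def simulate_chip_tags(
    annotation: GenomeAnnotation, truth: pd.DataFrame, config: SimulationConfig
) -> TagSet:
    """Poisson background tags genome-wide plus TSS-window enrichment at
    marked genes (enrichment factor relative to background rate)."""
    rng = _rng(config, 3)
    if len(annotation) == 0:
        return TagSet()
    chrom_len = {}
    for gene in annotation:
        chrom_len[gene.chrom] = max(chrom_len.get(gene.chrom, 0), gene.end + 10_000)
    chroms, positions, strands = [], [], []
    for chrom in sorted(chrom_len):
        n_bg = rng.poisson(config.chip_background_rate * chrom_len[chrom])
        pos = np.sort(rng.integers(0, chrom_len[chrom], size=n_bg))
        chroms.extend([chrom] * n_bg)
        positions.extend(pos.tolist())
        strands.extend(rng.choice(["+", "-"], size=n_bg).tolist())
    marked_ids = set(truth.index[truth["is_marked"]])
    w = config.chip_window_bp
    extra_rate = config.chip_background_rate * (config.chip_enrichment_factor - 1.0)
    for gene in annotation:
        if gene.gene_id not in marked_ids:
            continue
        lo, hi = max(0, gene.tss - w), gene.tss + w
        n_extra = rng.poisson(extra_rate * (hi - lo))
        pos = np.sort(rng.integers(lo, hi, size=n_extra))
        chroms.extend([gene.chrom] * n_extra)
        positions.extend(pos.tolist())
        strands.extend(rng.choice(["+", "-"], size=n_extra).tolist())
    tags = pd.DataFrame({"chrom": chroms, "pos": positions, "strand": strands})
    tags = tags.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return TagSet(tags)


def simulate_study(config: SimulationConfig):
    """Generate the full fixture: (annotation, truth, counts, design, tags)."""
    annotation = generate_annotation(config)
    truth = make_truth(annotation, config)
    counts, design = simulate_rnaseq_counts(annotation, truth, config)
    tags = simulate_chip_tags(annotation, truth, config)
    return annotation, truth, counts, design, tags


_FILES = {
    "annotation": "annotation.bed12",
    "counts": "counts.tsv",
    "design": "design.tsv",
    "tags": "tags.bed",
    "truth": "truth.tsv",
    "config": "config.yaml",
}


def write_fixture(outdir: str | Path, config: SimulationConfig | None = None, components=None):
    """Write a complete fixture to ``outdir`` and return the manifest.

    ``components`` may supply a pre-generated ``simulate_study`` tuple;
    otherwise the study is generated from ``config``.  The manifest lists
    every file with its SHA-256 and the generating seed.
    """
    if components is None:
        if config is None:
            raise ValueError("need a config or pre-generated components")
        components = simulate_study(config)
    annotation, truth, counts, design, tags = components
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    write_bed12(annotation, outdir / _FILES["annotation"])
    counts.to_tsv(outdir / _FILES["counts"])
    design.rename("condition").rename_axis("sample").reset_index().to_csv(
        outdir / _FILES["design"], sep="\t", index=False
    )
    tags.to_bed(outdir / _FILES["tags"])
    truth.to_csv(outdir / _FILES["truth"], sep="\t")
    if config is not None:
        with open(outdir / _FILES["config"], "w") as fh:
            yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)

    manifest = {
        "seed": None if config is None else config.seed,
        "files": {},
    }
    for key, name in _FILES.items():
        path = outdir / name
        if not path.exists():
            continue
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest["files"][key] = {"path": name, "sha256": digest}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_fixture(outdir: str | Path):
    """Read a fixture back: (annotation, truth, counts, design, tags, config)."""
    outdir = Path(outdir)
    annotation = read_bed12(outdir / _FILES["annotation"])
    truth = pd.read_csv(outdir / _FILES["truth"], sep="\t", index_col=0)
    design = read_design(outdir / _FILES["design"])
    config = None
    if (outdir / _FILES["config"]).exists():
        with open(outdir / _FILES["config"]) as fh:
            config = SimulationConfig(**yaml.safe_load(fh))
    library = None
    if config is not None:
        library = pd.Series(float(config.library_size), index=design.index)
    counts = CountMatrix.from_tsv(outdir / _FILES["counts"], library_size=library)
    tags = read_bed_tags(outdir / _FILES["tags"])
    return annotation, truth, counts, design, tags, config
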