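"""Cross-referencing of differential expression and TSS mark classes.

Each gene falls into one of six categories, the product of its DE status
(up/down/ns in the mutant) and its H3K27me3 TSS class (high/low).  Genes
both marked and significantly upregulated on methyltransferase loss are the
derepressed direct-target candidates.  Two association analyses accompany
the partition: marked genes' expression level versus unmarked (rank-sum per
condition) and mark-versus-DE independence (Fisher's exact test).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .genetics import FisherResult, fisher_exact_2x2

__all__ = [
    "cross_reference",
    "category_counts",
    "extract_direct_targets",
    "mark_vs_expression_test",
    "mark_vs_de_association",
]

CATEGORIES = [
    "marked_up", "marked_down", "marked_ns",
    "unmarked_up", "unmarked_down", "unmarked_ns",
]


def cross_reference(de: pd.DataFrame, marks: pd.DataFrame) -> pd.DataFrame:
    """Join DE status with mark class into the six-way category partition.

    Both tables must cover exactly the same gene universe; a mismatch is an
    error listing the symmetric difference.
    """
    if de.index.has_duplicates or marks.index.has_duplicates:
        raise ValueError("duplicated gene ids in input tables")
    if set(de.index) != set(marks.index):
        diff = sorted(set(de.index) ^ set(marks.index))
        raise ValueError(f"gene universes differ; symmetric difference: {diff[:10]}"
                         + ("..." if len(diff) > 10 else ""))
    status = de["status"]
    mark = marks.loc[de.index, "mark_class"]
    prefix = np.where(mark == "high", "marked", "unmarked")
    category = pd.Series(
        [f"{p}_{s}" for p, s in zip(prefix, status)], index=de.index, name="category"
    )
    return pd.DataFrame({"status": status, "mark_class": mark, "category": category})


def category_counts(integrated: pd.DataFrame) -> pd.Series:
    """Counts per category over the full six-way partition (zeros included)."""
    counts = integrated["category"].value_counts()
    return counts.reindex(CATEGORIES, fill_value=0).astype(int)


def extract_direct_targets(integrated: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Derepressed direct-target candidates and their downregulated counterpart.

    Returns (marked_up gene ids, marked_down gene ids), each sorted.
    """
    up = sorted(integrated.index[integrated["category"] == "marked_up"])
    down = sorted(integrated.index[integrated["category"] == "marked_down"])
    return up, down


def mark_vs_expression_test(
    fpkm: pd.DataFrame, marks: pd.DataFrame, design: pd.Series
) -> pd.DataFrame:
    """Do marked genes sit at lower expression?  Rank-sum per condition.

    Compares per-gene mean FPKM between high- and low-marked genes with a
    two-sided Mann-Whitney test, separately within each condition.  Returns
    one row per condition with group medians, the U statistic and p.  An
    empty class yields a flagged row with NaN statistics.
    """
    if set(fpkm.index) != set(marks.index):
        raise ValueError("fpkm and marks must share the same gene universe")
    mark = marks.loc[fpkm.index, "mark_class"]
    rows = []
    for condition in sorted(design.unique()):
        samples = design.index[design == condition]
        mean_expr = fpkm.loc[:, samples].mean(axis=1)
        high = mean_expr[mark == "high"]
        low = mean_expr[mark == "low"]
        if len(high) == 0 or len(low) == 0:
            rows.append(
                {
                    "condition": condition,
                    "median_marked": float(high.median()) if len(high) else np.nan,
                    "median_unmarked": float(low.median()) if len(low) else np.nan,
                    "statistic": np.nan,
                    "p_value": np.nan,
                    "degenerate": True,
                }
            )
            continue
        stat, p = mannwhitneyu(high, low, alternative="two-sided")
        rows.append(
            {
                "condition": condition,
                "median_marked": float(high.median()),
                "median_unmarked": float(low.median()),
                "statistic": float(stat),
                "p_value": float(p),
                "degenerate": False,
            }
        )
    return pd.DataFrame(rows).set_index("condition")


def mark_vs_de_association(integrated: pd.DataFrame) -> FisherResult:
    """Are marked genes predisposed to differential expression?

    Builds the 2x2 table (marked yes/no x DE yes/no, DE meaning status is
    not 'ns') and runs the two-sided Fisher's exact test.
    """
    marked = integrated["mark_class"] == "high"
    de = integrated["status"] != "ns"
    table = [
        [int((marked & de).sum()), int((marked & ~de).sum())],
        [int((~marked & de).sum()), int((~marked & ~de).sum())],
    ]
    return fisher_exact_2x2(table)
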