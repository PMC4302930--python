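"""Expression quantification and diffrat-ranked differential expression.

FPKM (fragments per kilobase of exon per million mapped fragments) is the
per-gene, per-sample expression unit.  Differential expression between the
mutant (methyltransferase-null) and control endothelium is *ranked* by the
diffrat score on condition means ``a`` (mutant) and ``b`` (control),

    diffrat(a, b) = |a - b| * log2((a + 1) / (b + 1)),

an absolute difference times a pseudocounted log ratio: it is zero iff
``a == b``, antisymmetric in its arguments, and positive for genes
upregulated in the mutant.

Significance is assigned by condition-label permutation, with two schemes:

``pooled`` (default)
    The observed statistic is a variance-moderated standardized difference
    of ``log2(FPKM + 1)`` condition means; the per-gene moderation constant
    is the median within-group standard deviation of the gene's expression
    stratum.  The statistic is recomputed for every distinct relabelling of
    the samples (the two relabellings that reproduce the observed grouping
    are excluded) and the null is pooled across genes, so a gene's p-value
    is the expected rank of its observed score in the pooled permutation
    distribution.  Pooling is what gives the test resolution far below the
    per-gene floor of ``1 / #splits`` — with three replicates per condition
    no per-gene exchangeability argument can reach adjusted p <= 0.01, yet
    a 4-fold derepression is plainly visible against the noise of 2000
    genes; borrowing the null across genes is how few-replicate designs
    earn genome-wide significance.  Up- and down-regulation are each
    controlled at the Benjamini-Hochberg level alpha.

``per-gene``
    A two-sided permutation test on |diffrat| itself, per gene: the
    empirical p is the fraction of distinct label assignments whose
    |diffrat| is at least the observed one (exhaustive when the number of
    distinct assignments is within the permutation budget, else uniformly
    sampled with the stated seed), followed by Benjamini-Hochberg
    adjustment.  Exact and oracle-checkable, but its p-values cannot fall
    below 2/C(n, n1); with three replicates per condition the floor is 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control
from sklearn.base import BaseEstimator

from .annotation import GenomeAnnotation

__all__ = [
    "CountMatrix",
    "ExpressionParams",
    "read_design",
    "compute_fpkm",
    "condition_means",
    "diffrat_score",
    "DiffratPermutationTest",
    "permutation_significance",
    "call_differential",
    "differential_expression",
]

CONTROL, MUTANT = "control", "mutant"


@dataclass
class CountMatrix:
    """Gene x sample fragment counts plus per-sample total mapped fragments.

    ``library_size`` may exceed the column sums (the annotated gene set need
    not cover every mapped fragment); it must be supplied explicitly if so.
    """

    counts: pd.DataFrame
    library_size: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("gene ids must be unique")
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be >= 0")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        self.library_size = self.library_size.reindex(self.counts.columns)
        if self.library_size.isna().any():
            missing = list(self.library_size.index[self.library_size.isna()])
            raise ValueError(f"library_size missing for samples {missing}")
        if (self.library_size <= 0).any():
            raise ValueError("library sizes must be > 0")

    @classmethod
    def from_tsv(cls, path: str | Path, library_size: pd.Series | None = None) -> "CountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        counts.index.name = "gene_id"
        if library_size is None:
            library_size = counts.sum(axis=0)
        return cls(counts, library_size)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def read_design(path: str | Path) -> pd.Series:
    """Read a sample -> condition table (TSV with columns sample, condition)."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "condition"}.issubset(df.columns):
        raise ValueError("design TSV needs columns 'sample' and 'condition'")
    design = df.set_index("sample")["condition"]
    _validate_design(design)
    return design


def _validate_design(design: pd.Series) -> None:
    bad = set(design.unique()) - {CONTROL, MUTANT}
    if bad:
        raise ValueError(f"unknown condition labels {sorted(bad)}; use control/mutant")


def compute_fpkm(counts: CountMatrix, annotation: GenomeAnnotation) -> pd.DataFrame:
    """FPKM[g, s] = counts[g, s] / ((exonic_length[g]/1e3) * (library_size[s]/1e6))."""
    missing = [g for g in counts.counts.index if g not in annotation]
    if missing:
        raise KeyError(f"genes missing from annotation: {missing[:10]}"
                       + ("..." if len(missing) > 10 else ""))
    lengths = annotation.exonic_lengths().reindex(counts.counts.index)
    if (lengths <= 0).any():
        raise ValueError("every gene needs exonic_length > 0")
    per_kb = lengths.to_numpy(dtype=float)[:, None] / 1e3
    per_million = counts.library_size.to_numpy(dtype=float)[None, :] / 1e6
    fpkm = counts.counts.to_numpy(dtype=float) / (per_kb * per_million)
    return pd.DataFrame(fpkm, index=counts.counts.index, columns=counts.counts.columns)


def condition_means(fpkm: pd.DataFrame, design: pd.Series) -> pd.DataFrame:
    """Arithmetic mean FPKM per condition: column ``a`` = mutant, ``b`` = control."""
    _validate_design(design)
    uncovered = [s for s in fpkm.columns if s not in design.index]
    if uncovered:
        raise ValueError(f"design does not cover samples {uncovered}")
    a = fpkm.loc[:, design.index[design == MUTANT]].mean(axis=1)
    b = fpkm.loc[:, design.index[design == CONTROL]].mean(axis=1)
    return pd.DataFrame({"a": a, "b": b})


def diffrat_score(a, b):
    """The diffrat ranking score |a - b| * log2((a + 1)/(b + 1)).

    Accepts scalars or arrays of non-negative expression values; the sign
    follows ``a - b`` (positive = higher in mutant).
    """
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    if (a_arr < 0).any() or (b_arr < 0).any():
        raise ValueError("expression values must be >= 0")
    if not (np.isfinite(a_arr).all() and np.isfinite(b_arr).all()):
        raise ValueError("expression values must be finite")
    out = np.abs(a_arr - b_arr) * np.log2((a_arr + 1.0) / (b_arr + 1.0))
    if np.isscalar(a) and np.isscalar(b):
        return float(out)
    return out


@dataclass(frozen=True)
class ExpressionParams:
    """Significance parameters: threshold, permutation budget, scheme, seed."""

    alpha: float = 0.01
    n_permutations: int = 1000
    method: str = "pooled"
    n_strata: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.method not in {"pooled", "per-gene"}:
            raise ValueError("method must be 'pooled' or 'per-gene'")


def _distinct_splits(n: int, k: int) -> list[tuple[int, ...]]:
    return list(combinations(range(n), k))


class DiffratPermutationTest(BaseEstimator):
    """Diffrat-ranked differential expression with permutation significance.

    A scikit-learn style estimator: ``fit(X, y)`` takes a gene x sample FPKM
    frame and a condition label per sample ('control'/'mutant'), computes the
    per-gene diffrat score on condition means and a permutation p-value per
    the chosen scheme (see module docstring), applies Benjamini-Hochberg
    adjustment and calls status up/down/ns at level ``alpha``.

    Parameters mirror :class:`ExpressionParams`.

    Attributes
    ----------
    results_ : pd.DataFrame
        Columns ``a``, ``b``, ``diffrat``, ``p_raw``, ``p_adj``, ``status``.
    n_splits_used_ : int
        Number of label assignments entering the null.
    exhaustive_ : bool
        Whether the null enumerated every usable distinct assignment.
    """

    def __init__(
        self,
        alpha: float = 0.01,
        n_permutations: int = 1000,
        method: str = "pooled",
        n_strata: int = 10,
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.n_permutations = n_permutations
        self.method = method
        self.n_strata = n_strata
        self.random_state = random_state

    # -- null enumeration ---------------------------------------------------

    def _splits(self, n: int, n_mut: int, drop_observed: bool, rng: np.random.Generator):
        """Distinct assignments of samples to the mutant group.

        Returns (list of index tuples, exhaustive flag).  The observed
        assignment is the last ``n_mut`` samples (callers order columns as
        controls then mutants).  When ``drop_observed``, the observed
        assignment and, for balanced designs, its complement are excluded.
        """
        total = comb(n, n_mut)
        observed = tuple(range(n - n_mut, n))
        complement = tuple(range(n - n_mut)) if 2 * n_mut == n else None
        budget = self.n_permutations
        if total <= budget + (2 if drop_observed else 0):
            splits = _distinct_splits(n, n_mut)
            if drop_observed:
                splits = [s for s in splits if s != observed and s != complement]
            return splits, True
        seen = set()
        if drop_observed:
            seen.update({observed, complement} - {None})
        splits = []
        while len(splits) < budget:
            s = tuple(sorted(rng.choice(n, size=n_mut, replace=False)))
            if s in seen:
                continue
            seen.add(s)
            splits.append(s)
        return splits, False

    @staticmethod
    def _group_stats(Y: np.ndarray, masks: np.ndarray):
        """Means and ddof-1 variances of Y (genes x samples) under each mask row."""
        n1 = masks.sum(axis=1, dtype=float)
        n0 = masks.shape[1] - n1
        m1 = Y @ masks.T / n1
        m0 = Y @ (~masks).T / n0
        q1 = (Y**2) @ masks.T / n1
        q0 = (Y**2) @ (~masks).T / n0
        v1 = np.maximum(q1 - m1**2, 0.0) * n1 / np.maximum(n1 - 1, 1)
        v0 = np.maximum(q0 - m0**2, 0.0) * n0 / np.maximum(n0 - 1, 1)
        return m1, m0, v1, v0, n1, n0

    # -- fitting ------------------------------------------------------------

    def fit(self, X: pd.DataFrame, y) -> "DiffratPermutationTest":
        params = ExpressionParams(
            alpha=self.alpha,
            n_permutations=self.n_permutations,
            method=self.method,
            n_strata=self.n_strata,
            seed=self.random_state,
        )
        fpkm = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        design = pd.Series(np.asarray(y, dtype=object), index=fpkm.columns)
        _validate_design(design)
        n_ctrl = int((design == CONTROL).sum())
        n_mut = int((design == MUTANT).sum())
        if min(n_ctrl, n_mut) < 2:
            raise ValueError(
                "permutation significance needs >= 2 replicates per condition "
                f"(got control={n_ctrl}, mutant={n_mut})"
            )
        # order columns controls-first so the observed assignment is canonical
        order = list(design.index[design == CONTROL]) + list(design.index[design == MUTANT])
        F = fpkm.loc[:, order].to_numpy(dtype=float)
        n = n_ctrl + n_mut
        means = condition_means(fpkm, design)
        diffrat = diffrat_score(means["a"].to_numpy(), means["b"].to_numpy())
        rng = np.random.default_rng(self.random_state)

        if params.method == "per-gene":
            p_raw = self._per_gene_p(F, n, n_mut, rng)
            p_adj = false_discovery_control(p_raw, method="bh")
        else:
            p_up, p_dn = self._pooled_p(F, n, n_mut, rng)
            adj_up = false_discovery_control(p_up, method="bh")
            adj_dn = false_discovery_control(p_dn, method="bh")
            p_raw = np.minimum(1.0, 2.0 * np.minimum(p_up, p_dn))
            p_adj = np.minimum(adj_up, adj_dn)

        status = np.where(
            (p_adj <= params.alpha) & (diffrat > 0),
            "up",
            np.where((p_adj <= params.alpha) & (diffrat < 0), "down", "ns"),
        )
        self.results_ = pd.DataFrame(
            {
                "a": means["a"],
                "b": means["b"],
                "diffrat": diffrat,
                "p_raw": p_raw,
                "p_adj": p_adj,
                "status": status,
            },
            index=fpkm.index,
        )
        return self

    def _per_gene_p(self, F: np.ndarray, n: int, n_mut: int, rng) -> np.ndarray:
        """Two-sided per-gene permutation p on |diffrat| (observed split kept in
        the null when exhaustive, add-one smoothed when sampled)."""
        splits, exhaustive = self._splits(n, n_mut, drop_observed=False, rng=rng)
        masks = np.zeros((len(splits), n), dtype=bool)
        for i, s in enumerate(splits):
            masks[i, list(s)] = True
        m1, m0, *_ = self._group_stats(F, masks)
        null_abs = np.abs(np.abs(m1 - m0) * np.log2((m1 + 1.0) / (m0 + 1.0)))
        observed = tuple(range(n - n_mut, n))
        obs_abs = null_abs[:, splits.index(observed)] if exhaustive else None
        if obs_abs is None:
            mask_obs = np.zeros((1, n), dtype=bool)
            mask_obs[0, n - n_mut:] = True
            m1o, m0o, *_ = self._group_stats(F, mask_obs)
            obs_abs = np.abs(np.abs(m1o - m0o) * np.log2((m1o + 1.0) / (m0o + 1.0)))[:, 0]
        # ties count as >= (conservative)
        count = (null_abs >= obs_abs[:, None] - 1e-12).sum(axis=1)
        self.n_splits_used_ = len(splits)
        self.exhaustive_ = exhaustive
        if exhaustive:
            return count / len(splits)
        return (1.0 + count) / (1.0 + len(splits))

    def _pooled_p(self, F: np.ndarray, n: int, n_mut: int, rng):
        """One-sided (up, down) p-values from the pooled moderated-statistic null."""
        Y = np.log2(F + 1.0)
        n_genes = Y.shape[0]
        mask_obs = np.zeros((1, n), dtype=bool)
        mask_obs[0, n - n_mut:] = True

        # stratified moderation constant from the observed grouping
        m1, m0, v1, v0, n1, n0 = self._group_stats(Y, mask_obs)
        sd_obs = np.sqrt(((n1 - 1) * v1 + (n0 - 1) * v0)[:, 0] / max(n - 2, 1))
        order = np.argsort(Y.mean(axis=1), kind="stable")
        s0 = np.empty(n_genes)
        n_strata = max(1, min(self.n_strata, n_genes))
        for stratum in np.array_split(order, n_strata):
            s0[stratum] = np.median(sd_obs[stratum])
        scale = np.sqrt(1.0 / n_mut + 1.0 / (n - n_mut))

        def stat(m_mut, m_ctrl, v_mut, v_ctrl, nm, nc):
            sd = np.sqrt(((nm - 1) * v_mut + (nc - 1) * v_ctrl) / max(n - 2, 1))
            denom = (sd + s0[:, None]) * scale
            out = np.zeros_like(m_mut)
            np.divide(m_mut - m_ctrl, denom, out=out, where=denom > 0)
            return out

        t_obs = stat(m1, m0, v1, v0, n1, n0)[:, 0]
        splits, exhaustive = self._splits(n, n_mut, drop_observed=True, rng=rng)
        masks = np.zeros((len(splits), n), dtype=bool)
        for i, s in enumerate(splits):
            masks[i, list(s)] = True
        m1s, m0s, v1s, v0s, n1s, n0s = self._group_stats(Y, masks)
        pool = np.sort(stat(m1s, m0s, v1s, v0s, n1s, n0s).ravel())
        total = pool.size
        ge = total - np.searchsorted(pool, t_obs - 1e-12, side="left")
        le = np.searchsorted(pool, t_obs + 1e-12, side="right")
        self.n_splits_used_ = len(splits)
        self.exhaustive_ = exhaustive
        return (1.0 + ge) / (1.0 + total), (1.0 + le) / (1.0 + total)


def permutation_significance(
    fpkm: pd.DataFrame, design: pd.Series, params: ExpressionParams = ExpressionParams()
) -> pd.Series:
    """Adjusted permutation p-values per gene (thin wrapper over the estimator)."""
    test = DiffratPermutationTest(
        alpha=params.alpha,
        n_permutations=params.n_permutations,
        method=params.method,
        n_strata=params.n_strata,
        random_state=params.seed,
    ).fit(fpkm, design.reindex(fpkm.columns))
    return test.results_["p_adj"]


def call_differential(
    table: pd.DataFrame, params: ExpressionParams = ExpressionParams()
) -> pd.DataFrame:
    """(Re)assign status from filled p_adj and diffrat at level alpha."""
    if table["p_adj"].isna().any():
        raise ValueError("p_adj must be filled before calling status")
    out = table.copy()
    sig = out["p_adj"] <= params.alpha
    out["status"] = np.where(
        sig & (out["diffrat"] > 0), "up", np.where(sig & (out["diffrat"] < 0), "down", "ns")
    )
    return out


def differential_expression(
    counts: CountMatrix,
    design: pd.Series,
    annotation: GenomeAnnotation,
    params: ExpressionParams = ExpressionParams(),
) -> pd.DataFrame:
    """Counts to DE table in one call: FPKM, diffrat, permutation p, status."""
    fpkm = compute_fpkm(counts, annotation)
    test = DiffratPermutationTest(
        alpha=params.alpha,
        n_permutations=params.n_permutations,
        method=params.method,
        n_strata=params.n_strata,
        random_state=params.seed,
    ).fit(fpkm, design.reindex(fpkm.columns))
    return test.results_
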