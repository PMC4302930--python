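"""Rescue-cross statistics: Mendelian genotype expectations and Fisher's exact test.

The genotype arithmetic assumes independent assortment of loci and uniform
gamete segregation: each parent transmits one of its two allele symbols with
probability 1/2, and loci combine multiplicatively.  A hemizygous transgene
(e.g. an endothelial Cre driver) is modelled as an ordinary locus with a null
allele, ``cre/0`` x ``0/0``, so half the offspring are transgene-positive.

Target genotypes may use ``*`` as an allele wildcard (``cre/*`` = carries at
least one ``cre`` allele) or omit a locus entirely (pooled over that locus).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "CrossSpec",
    "FisherResult",
    "parse_genotype",
    "mendelian_expected_fraction",
    "genotype_distribution",
    "fisher_exact_2x2",
]

WILDCARD = "*"

AllelePair = tuple[str, str]


def parse_genotype(text: str) -> dict[str, AllelePair]:
    """Parse ``"Ezh2=fl/+,Cre=cre/0"`` into ``{"Ezh2": ("fl", "+"), ...}``."""
    genotype: dict[str, AllelePair] = {}
    for chunk in text.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise ValueError(f"bad locus spec {chunk!r}: expected LOCUS=a/b")
        locus, alleles = chunk.split("=", 1)
        parts = alleles.split("/")
        if len(parts) != 2 or not all(parts):
            raise ValueError(f"bad allele pair {alleles!r} at locus {locus!r}")
        genotype[locus.strip()] = (parts[0].strip(), parts[1].strip())
    if not genotype:
        raise ValueError("empty genotype string")
    return genotype


@dataclass(frozen=True)
class CrossSpec:
    """Sire and dam genotypes over a shared set of independently assorting loci."""

    sire: Mapping[str, AllelePair]
    dam: Mapping[str, AllelePair]

    def __post_init__(self) -> None:
        if set(self.sire) != set(self.dam):
            missing = set(self.sire) ^ set(self.dam)
            raise ValueError(f"sire and dam must share loci; mismatch at {sorted(missing)}")
        for parent in (self.sire, self.dam):
            for locus, pair in parent.items():
                if len(pair) != 2 or not all(pair):
                    raise ValueError(f"locus {locus!r}: allele pair must have two symbols")

    @classmethod
    def from_strings(cls, sire: str, dam: str) -> "CrossSpec":
        return cls(parse_genotype(sire), parse_genotype(dam))


def _match(pattern: str, allele: str) -> bool:
    return pattern == WILDCARD or pattern == allele


def _locus_probability(sire: AllelePair, dam: AllelePair, target: AllelePair) -> float:
    """P(offspring genotype at one locus matches the target pattern).

    The offspring genotype is the unordered pair of one sire and one dam
    gamete, each drawn uniformly; the target pattern ``(x, y)`` matches
    the pair ``{s, d}`` if it matches in either orientation.
    """
    x, y = target
    hits = 0
    for s, d in product(sire, dam):
        if (_match(x, s) and _match(y, d)) or (_match(x, d) and _match(y, s)):
            hits += 1
    return hits / 4.0


def mendelian_expected_fraction(cross: CrossSpec, target: Mapping[str, AllelePair]) -> float:
    """Expected fraction of offspring matching a (possibly wildcarded) genotype.

    Loci omitted from ``target`` are pooled over (probability 1).  An allele
    named in the target that neither parent carries gives fraction 0.
    """
    frac = 1.0
    for locus, pair in target.items():
        if locus not in cross.sire:
            raise KeyError(f"target locus {locus!r} not present in the cross")
        frac *= _locus_probability(cross.sire[locus], cross.dam[locus], pair)
    return frac


def genotype_distribution(cross: CrossSpec) -> dict[tuple[tuple[str, AllelePair], ...], float]:
    """Full offspring genotype distribution (unordered allele pairs per locus).

    Probabilities sum to 1; useful as a conservation check on the per-locus
    arithmetic.
    """
    loci = sorted(cross.sire)
    per_locus: list[dict[AllelePair, float]] = []
    for locus in loci:
        dist: dict[AllelePair, float] = {}
        for s, d in product(cross.sire[locus], cross.dam[locus]):
            key = tuple(sorted((s, d)))
            dist[key] = dist.get(key, 0.0) + 0.25
        per_locus.append(dist)
    out: dict[tuple[tuple[str, AllelePair], ...], float] = {}
    for combo in product(*(d.items() for d in per_locus)):
        key = tuple((locus, pair) for locus, (pair, _) in zip(loci, combo))
        prob = float(np.prod([p for (_, p) in combo]))
        out[key] = out.get(key, 0.0) + prob
    return out


@dataclass(frozen=True)
class FisherResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    ``odds_ratio`` is the sample (cross-product) odds ratio ``ad/bc``;
    ``degenerate`` flags tables with a zero margin, for which no test is
    defined (p is NaN there).
    """

    odds_ratio: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
            "odds_ratio_kind": "sample (ad/bc)",
            "degenerate": self.degenerate,
        }


# Relative tolerance when deciding whether a table is "as extreme as" the
# observed one; guards against float noise in the hypergeometric pmf (the
# same guard R's fisher.test uses).
_REL_EPS = 1e-7


def fisher_exact_2x2(table) -> FisherResult:
    """Exact two-sided test of independence for a 2x2 contingency table.

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed table's
    (the standard two-sided rule).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    (a, b), (c, d) = t
    n = int(t.sum())
    row1, col1 = int(a + b), int(a + c)
    if a * d == 0 and b * c == 0:
        odds = float("nan")
    elif b * c == 0:
        odds = float("inf")
    else:
        odds = (a * d) / (b * c)
    if min(row1, n - row1, col1, n - col1) == 0:
        return FisherResult(odds, float("nan"), ((int(a), int(b)), (int(c), int(d))), True)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = hypergeom.pmf(int(a), n, row1, col1)
    p = float(pmf[pmf <= p_obs * (1 + _REL_EPS)].sum())
    return FisherResult(odds, min(1.0, p), ((int(a), int(b)), (int(c), int(d))), False)
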