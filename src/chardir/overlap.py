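"""Consensus gene lists, Venn partitions and Fisher-exact overlap enrichment.

A "consensus" gene is one called differentially expressed in the same
direction by two independent platforms (e.g. the microarray discriminant
analysis and the RNA-seq comparison).  Whether the observed overlap k
between a query set of size n and a set of D annotated genes in a
universe of N is larger or smaller than chance is measured against the
hypergeometric null: expected = n·D/N, fold-enrichment ratio = k/expected,
and a one-sided Fisher exact p-value from the hypergeometric tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import pandas as pd
from scipy.stats import hypergeom

from .expr_io import GeneSet

logger = logging.getLogger("chardir")


@dataclass
class OverlapResult:
    """2×2 overlap contingency summary with fold enrichment and Fisher p."""

    k: int          # observed overlap
    n: int          # query set size
    D: int          # annotated genes in universe
    N: int          # universe size
    expected: float
    ratio: float
    p: float
    test_side: str  # {"greater", "less"}

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def _directions(de) -> dict[str, str]:
    """Accept a DataFrame with gene_id/direction columns or (gene, direction) pairs."""
    if isinstance(de, pd.DataFrame):
        return dict(zip(de["gene_id"], de["direction"]))
    return {g: d for g, d in de}


def consensus_genes(a, b, direction: str) -> GeneSet:
    """Genes called in the requested direction by BOTH input DE results.

    The consensus may legitimately be empty when the two platforms' calls
    are disjoint; this is logged, not an error.
    """
    genes = consensus_gene_ids(a, b, direction)
    if not genes:
        logger.info("consensus_%s is empty: no shared %s-regulated genes", direction, direction)
    return GeneSet(name=f"consensus_{direction}", genes=frozenset(genes),
                   direction_tag=direction)


def consensus_gene_ids(a, b, direction: str) -> frozenset[str]:
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    da, db = _directions(a), _directions(b)
    return frozenset(g for g, d in da.items() if d == direction and db.get(g) == direction)


def overlap_enrichment(k: int, n: int, D: int, N: int, test_side: str = "greater") -> OverlapResult:
    """Hypergeometric overlap test: X ~ Hypergeom(N, D, n), observed X = k.

    p = P[X >= k] for ``test_side="greater"`` (enrichment), P[X <= k] for
    ``"less"`` (depletion / underrepresentation).
    """
    if test_side not in ("greater", "less"):
        raise ValueError("test_side must be 'greater' or 'less'")
    if n <= 0 or D <= 0:
        raise ValueError("n and D must be positive (expected overlap undefined)")
    if N < max(n, D):
        raise ValueError("universe N must be >= max(n, D)")
    if not (max(0, n + D - N) <= k <= min(n, D)):
        raise ValueError(f"k={k} impossible for n={n}, D={D}, N={N}")
    expected = n * D / N
    ratio = k / expected
    if test_side == "greater":
        p = float(hypergeom.sf(k - 1, N, D, n))
    else:
        p = float(hypergeom.cdf(k, N, D, n))
    return OverlapResult(k=k, n=n, D=D, N=N, expected=expected, ratio=ratio,
                         p=min(p, 1.0), test_side=test_side)


def overlap_enrichment_sets(
    query: GeneSet, annotated: GeneSet, universe: Sequence[str], test_side: str = "greater"
) -> OverlapResult:
    """Convenience wrapper computing k, n, D, N from gene sets and a universe."""
    uni = frozenset(universe)
    q = query.genes & uni
    d = annotated.genes & uni
    return overlap_enrichment(len(q & d), len(q), len(d), len(uni), test_side)


@dataclass
class VennPartition:
    """Exact region counts for 2 or 3 gene sets, keyed by membership pattern.

    Keys are frozensets of set names, e.g. {"A"} for genes only in A,
    {"A","B"} for genes in exactly A and B.
    """

    set_names: list[str]
    regions: dict[frozenset, int]

    @property
    def exactly_one(self) -> int:
        return sum(c for k, c in self.regions.items() if len(k) == 1)

    @property
    def two_or_more(self) -> int:
        return sum(c for k, c in self.regions.items() if len(k) >= 2)

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())


def venn_partition(sets: Sequence[GeneSet]) -> VennPartition:
    """Partition the union of 2 or 3 gene sets into exclusive Venn regions."""
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_partition supports exactly 2 or 3 sets")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("gene set names must be distinct")
    regions: dict[frozenset, int] = {}
    for r in range(1, len(sets) + 1):
        for group in combinations(sets, r):
            inside = frozenset.intersection(*(s.genes for s in group))
            outside = frozenset.union(
                *(s.genes for s in sets if s not in group)
            ) if len(group) < len(sets) else frozenset()
            key = frozenset(s.name for s in group)
            regions[key] = len(inside - outside)
    return VennPartition(set_names=names, regions=regions)
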