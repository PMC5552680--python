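"""Transcription-factor activity as regulon-restricted projections.

The projection of sample expression profiles onto the characteristic
direction restricted to a transcription factor's regulon (its set of
putative target genes) is used as a per-sample estimate of that factor's
activity.  Activities of two factors are then compared by correlating
their projections across samples — with the shared target genes excluded
from one of the regulons first, so that a high correlation cannot be a
trivial consequence of overlapping membership.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .direction import CharacteristicDirection, DirectionError, ProjectionScores, project_samples
from .expr_io import ExpressionMatrix, GeneSet


@dataclass
class ActivityTable:
    """Per-sample activity scores for several regulons."""

    scores: pd.DataFrame  # samples × regulon names

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores.to_numpy(float))):
            raise ValueError("activity scores must be finite")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def regulon_names(self) -> list[str]:
        return list(self.scores.columns)

    def series(self, name: str) -> ProjectionScores:
        return ProjectionScores(self.sample_ids, self.scores[name].to_numpy(float), name)


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    method: str
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")
        if self.n < 3:
            raise ValueError("need n >= 3 samples")


def regulon_activity(
    cd: CharacteristicDirection, X: ExpressionMatrix, regulon: GeneSet
) -> ProjectionScores:
    """Estimate a TF's per-sample activity: project onto its regulon genes."""
    try:
        return project_samples(cd, X, subset=regulon)
    except DirectionError as exc:
        raise DirectionError(f"regulon {regulon.name!r}: {exc}") from exc


def activity_table(
    cd: CharacteristicDirection, X: ExpressionMatrix, regulons: list[GeneSet]
) -> ActivityTable:
    cols = {r.name: regulon_activity(cd, X, r).scores for r in regulons}
    return ActivityTable(pd.DataFrame(cols, index=X.sample_ids))


def exclusive_regulon(a: GeneSet, b: GeneSet) -> GeneSet:
    """Members of *a* not in *b* (avoids spurious correlation from shared targets)."""
    diff = a.genes - b.genes
    if not diff:
        raise ValueError(f"{a.name} \\ {b.name} is empty; nothing to project")
    return GeneSet(name=f"{a.name}_not_{b.name}", genes=frozenset(diff),
                   direction_tag=a.direction_tag)


def activity_correlation(
    s1: ProjectionScores, s2: ProjectionScores, method: str = "pearson"
) -> CorrelationResult:
    """Correlate two activity score series across samples.

    Pearson p-values use the exact t transform; Spearman uses the
    t approximation on the rank correlation.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be pearson or spearman, got {method!r}")
    if s1.sample_ids != s2.sample_ids:
        raise ValueError("score series must be over the same samples in the same order")
    n = len(s1.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 samples")
    x, y = s1.scores, s2.scores
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a score vector; correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        r, p = stats.spearmanr(x, y)
    return CorrelationResult(
        pair=(s1.gene_subset or "s1", s2.gene_subset or "s2"),
        method=method, r=float(r), p=float(p), n=n,
    )
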