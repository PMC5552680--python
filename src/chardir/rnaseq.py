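"""RNA-seq differential expression on RPKM matrices.

Cancer cell lines are compared against mesenchymal stem cells gene by gene:
the fold change is the ratio of mean RPKM (case over control, with a
pseudocount stabilizing zeros), the p-value comes from a Welch t-test on
log2(RPKM + pseudocount), and false-discovery control uses
Benjamini–Hochberg step-up.  Also provides per-sample gene-set expression
sums and the transcription-factor correlation screen (Spearman rank
correlation of each TF gene's expression against a target set-sum series).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expr_io import ExpressionMatrix, GeneSet, SampleAnnotation

logger = logging.getLogger("chardir")


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SetSumSeries:
    """Per-sample total RPKM over a gene set ("sum of expression" series)."""

    name: str
    sums: pd.Series  # indexed by sample_id

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.sums.to_numpy(float))):
            raise ValueError("set sums must be finite")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sums.index)


def differential_expression(
    X: ExpressionMatrix,
    ann: SampleAnnotation,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    fc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-gene case-vs-control differential expression on linear RPKM.

    Returns a DataFrame with columns gene_id, mean_case, mean_ctrl,
    fold_change, log2fc, p, q, minus_log10_p, direction.  Genes at zero in
    both groups are dropped before testing (no information, undefined fold
    change); a gene with zero variance in both groups and equal means gets
    p = 1.  direction is "up" when q < alpha and fold_change >=
    fc_threshold, "down" when q < alpha and fold_change <= 1/fc_threshold,
    else "ns".
    """
    if X.scale_tag != "linear":
        raise ValueError("differential_expression expects linear-scale (RPKM) input")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    mask = ann.class_mask(X.sample_ids)
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("need >=2 samples per class")
    V = X.values
    case, ctrl = V[:, mask], V[:, ~mask]

    nonzero = (case.sum(axis=1) + ctrl.sum(axis=1)) > 0
    n_drop = int((~nonzero).sum())
    if n_drop:
        logger.info("dropping %d genes expressed at zero in both groups", n_drop)
    genes = [g for g, keep in zip(X.gene_ids, nonzero) if keep]
    case, ctrl = case[nonzero], ctrl[nonzero]

    mean_case = case.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    fc = (mean_case + pseudocount) / (mean_ctrl + pseudocount)

    lc = np.log2(case + pseudocount)
    lk = np.log2(ctrl + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(lc, lk, axis=1, equal_var=False)
    flat = (lc.var(axis=1) == 0) & (lk.var(axis=1) == 0)
    equal_means = np.isclose(lc.mean(axis=1), lk.mean(axis=1))
    p = np.where(flat & equal_means, 1.0, p)
    p = np.where(flat & ~equal_means, 0.0, p)
    if np.isnan(p).any():
        p = np.nan_to_num(p, nan=1.0)

    q = bh_adjust(p)
    direction = np.where(
        (q < alpha) & (fc >= fc_threshold),
        "up",
        np.where((q < alpha) & (fc <= 1.0 / fc_threshold), "down", "ns"),
    )
    with np.errstate(divide="ignore"):
        minus_log10_p = -np.log10(np.maximum(p, np.finfo(float).tiny))
    return pd.DataFrame(
        {
            "gene_id": genes,
            "mean_case": mean_case,
            "mean_ctrl": mean_ctrl,
            "fold_change": fc,
            "log2fc": np.log2(fc),
            "p": p,
            "q": q,
            "minus_log10_p": minus_log10_p,
            "direction": direction,
        }
    )


def gene_set_sum(X: ExpressionMatrix, s: GeneSet) -> SetSumSeries:
    """Per-sample sum of RPKM over the member genes of *s*.

    Member genes absent from the matrix are ignored with a logged count.
    """
    present = [g for g in X.gene_ids if g in s.genes]
    if not present:
        raise ValueError(f"gene set {s.name!r} shares no genes with the matrix")
    n_missing = len(s.genes) - len(present)
    if n_missing:
        logger.info("gene set %s: %d member genes absent from matrix", s.name, n_missing)
    sums = X.data.loc[present].sum(axis=0)
    return SetSumSeries(name=s.name, sums=sums)


def tf_correlation_screen(
    X: ExpressionMatrix, tf_genes: GeneSet, target: SetSumSeries
) -> pd.DataFrame:
    """Rank transcription factors by Spearman correlation with a target series.

    For each TF gene present in *X*, computes the Spearman rank correlation
    (midranks for ties) between its expression across the shared samples
    and the target set-sum series; returns a DataFrame (tf, r, p) sorted by
    descending r.  TF genes absent from the matrix are skipped with a log
    entry.
    """
    shared = [s for s in X.sample_ids if s in set(target.sample_ids)]
    if len(shared) < 5:
        raise ValueError(f"need >=5 shared samples, got {len(shared)}")
    y = target.sums.reindex(shared).to_numpy(float)
    rows = []
    skipped = []
    for tf in sorted(tf_genes.genes):
        if tf not in X.data.index:
            skipped.append(tf)
            continue
        x = X.data.loc[tf, shared].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.spearmanr(x, y)
        rows.append((tf, r, p))
    if skipped:
        logger.info("tf_correlation_screen: %d TF genes absent from matrix: %s...",
                    len(skipped), skipped[:5])
    out = pd.DataFrame(rows, columns=["tf", "r", "p"])
    return out.sort_values("r", ascending=False, na_position="last").reset_index(drop=True)
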