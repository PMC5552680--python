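"""Characteristic direction: a shrinkage-regularized linear discriminant.

The characteristic direction is the unit vector normal to the hyperplane in
gene-expression space that best separates two classes of samples
(tumorigenic vs healthy dividing).  It is computed as

    b  ∝  ((1 − γ) Σ_pooled + γ I)⁻¹ (μ_case − μ_ctrl),      ‖b‖₂ = 1,

where Σ_pooled is the pooled within-class covariance and γ ∈ [0, 1] mixes
it with the identity (γ = 1 reduces to the raw class-mean difference,
γ = 0 is classical LDA, which is singular when genes outnumber samples).
Per-gene contributions b_i measure how much each gene drives the
separation; their significance is assessed by a class-label permutation
null with Benjamini–Hochberg FDR control.

With p genes ≫ n samples the regularized matrix is never formed: the
pooled covariance has rank ≤ n − 2, so the solve is routed through the
Woodbury identity on an n × n system.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .expr_io import CASE, CONTROL, ExpressionMatrix, GeneSet, SampleAnnotation
from .rnaseq import bh_adjust


class DirectionError(ValueError):
    pass


@dataclass
class CharacteristicDirection:
    """Unit vector of per-gene contributions to the class separation."""

    gene_ids: list[str]
    b: np.ndarray
    gamma: float
    class_order: tuple[str, str] = (CASE, CONTROL)
    p: Optional[np.ndarray] = None
    q: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        if len(self.gene_ids) != self.b.size:
            raise DirectionError("gene_ids and b length mismatch")
        nrm = float(np.linalg.norm(self.b))
        if abs(nrm - 1.0) > 1e-9:
            raise DirectionError(f"direction must be unit length, got ‖b‖ = {nrm}")
        for vec in (self.p, self.q):
            if vec is not None:
                vec = np.asarray(vec, float)
                if vec.shape != self.b.shape or (vec < 0).any() or (vec > 1).any():
                    raise DirectionError("p/q must match b in shape and lie in [0,1]")

    def as_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"gene_id": self.gene_ids, "b": self.b})
        out["p"] = self.p if self.p is not None else np.nan
        out["q"] = self.q if self.q is not None else np.nan
        return out

    def significant_genes(self, alpha: float = 0.05) -> pd.DataFrame:
        """FDR-filtered contributions, split into positive and negative."""
        if self.q is None:
            raise DirectionError("significance not computed; run gene_significance first")
        df = self.as_frame()
        return df[df["q"] < alpha].sort_values("b", ascending=False).reset_index(drop=True)


@dataclass
class ProjectionScores:
    """Per-sample coordinates along a (possibly regulon-restricted) direction."""

    sample_ids: list[str]
    scores: np.ndarray
    gene_subset: Optional[str] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.sample_ids) != self.scores.size:
            raise DirectionError("sample_ids and scores length mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise DirectionError("projection scores must be finite")

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.sample_ids, name=self.gene_subset or "score")


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _class_split(X: ExpressionMatrix, ann: SampleAnnotation) -> tuple[np.ndarray, np.ndarray]:
    mask = ann.class_mask(X.sample_ids)
    n_case, n_ctrl = int(mask.sum()), int((~mask).sum())
    if n_case < 2 or n_ctrl < 2:
        raise DirectionError(
            f"need >=2 samples per class, got {n_case} case / {n_ctrl} control"
        )
    return mask, X.values


def _direction_from_mask(V: np.ndarray, mask: np.ndarray, gamma: float) -> np.ndarray:
    """Solve ((1-γ)Σ_pooled + γI) b = μ_case − μ_ctrl and unit-normalize.

    Uses the Woodbury identity when genes outnumber samples (γ > 0):
    Σ_pooled = U Uᵀ / (n − 2) with U the within-class-centered data, so
    A⁻¹d = (d − U (γ(n−2)/(1−γ) I + UᵀU)⁻¹ Uᵀ d) / γ.
    """
    p, n = V.shape
    mu_case = V[:, mask].mean(axis=1)
    mu_ctrl = V[:, ~mask].mean(axis=1)
    d = mu_case - mu_ctrl
    if gamma == 1.0:
        b = d
    else:
        U = V.copy()
        U[:, mask] -= mu_case[:, None]
        U[:, ~mask] -= mu_ctrl[:, None]
        dof = n - 2
        if gamma == 0.0 and p > dof:
            raise DirectionError(
                "pooled covariance is singular (gamma=0 with more genes than "
                "within-class degrees of freedom); use gamma > 0"
            )
        if gamma > 0.0 and p > n:
            c = (1.0 - gamma) / dof
            G = U.T @ U
            M = (gamma / c) * np.eye(n) + G
            b = (d - U @ np.linalg.solve(M, U.T @ d)) / gamma
        else:
            A = (1.0 - gamma) * (U @ U.T) / dof + gamma * np.eye(p)
            try:
                b = np.linalg.solve(A, d)
            except np.linalg.LinAlgError as exc:
                raise DirectionError(
                    "regularized covariance is singular (gamma=0 with more genes "
                    "than samples); use gamma > 0"
                ) from exc
    nrm = np.linalg.norm(b)
    if nrm == 0:
        # degenerate: identical class means; keep a deterministic unit vector
        b = np.zeros(p)
        b[0] = 1.0
        return b
    b = b / nrm
    if float(b @ d) < 0:
        b = -b
    return b


def characteristic_direction(
    X: ExpressionMatrix, ann: SampleAnnotation, gamma: float = 0.5
) -> CharacteristicDirection:
    """Fit the characteristic direction separating case from control samples.

    Sign convention: the mean projection score of case samples is at least
    that of control samples. Deterministic given inputs.
    """
    if not 0.0 <= gamma <= 1.0:
        raise DirectionError(f"gamma must be in [0,1], got {gamma}")
    mask, V = _class_split(X, ann)
    b = _direction_from_mask(V, mask, gamma)
    return CharacteristicDirection(gene_ids=X.gene_ids, b=b, gamma=gamma)


def gene_significance(
    cd: CharacteristicDirection,
    X: ExpressionMatrix,
    ann: SampleAnnotation,
    n_perm: int = 1000,
    seed: int = 0,
) -> CharacteristicDirection:
    """Per-gene permutation p-values and BH q-values for |b_i|.

    The null redraws the case/control labels uniformly at random (class
    sizes preserved) and refits the direction; the two-sided p-value for
    gene i is the fraction of permutations with |b_perm,i| >= |b_i|
    (inclusive), with a +1 pseudocount in numerator and denominator.
    """
    if n_perm < 100:
        raise DirectionError("n_perm must be >= 100 for a stable permutation tail")
    if cd.gene_ids != X.gene_ids:
        raise DirectionError("cd and X gene spaces differ; align first")
    mask, V = _class_split(X, ann)
    obs = np.abs(cd.b)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(V.shape[0], dtype=np.int64)
    for _ in range(n_perm):
        perm_mask = rng.permutation(mask)
        b_perm = _direction_from_mask(V, perm_mask, cd.gamma)
        exceed += np.abs(b_perm) >= obs
    p = (exceed + 1) / (n_perm + 1)
    q = bh_adjust(p)
    return replace(cd, p=p, q=q)


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------

def project_samples(
    cd: CharacteristicDirection,
    X: ExpressionMatrix,
    subset: Optional[GeneSet] = None,
) -> ProjectionScores:
    """Project each sample of *X* onto the characteristic direction.

    score_s = Σ_i b_i (x_is − x̄_i·), the sum running over the genes shared
    by the direction and the matrix, optionally restricted to *subset*.
    Genes are centered by their mean over X's own samples, so independently
    normalized matrices can be projected without leaking parameters across
    datasets. The restricted direction is not renormalized: a regulon's
    score keeps its relative magnitude within the global direction.
    """
    gene_to_b = dict(zip(cd.gene_ids, cd.b))
    shared = [g for g in X.gene_ids if g in gene_to_b]
    if not shared:
        raise DirectionError("direction and matrix share no genes")
    if subset is not None:
        shared_sub = [g for g in shared if g in subset.genes]
        if not shared_sub:
            raise DirectionError(
                f"gene set {subset.name!r} shares no genes with the projection space"
            )
        shared = shared_sub
    sub = X.subset_genes(shared)
    V = sub.values
    centered = V - V.mean(axis=1, keepdims=True)
    bvec = np.array([gene_to_b[g] for g in shared])
    scores = bvec @ centered
    return ProjectionScores(
        sample_ids=X.sample_ids,
        scores=scores,
        gene_subset=subset.name if subset is not None else None,
    )


# ---------------------------------------------------------------------------
# Exploratory PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    coords: pd.DataFrame            # samples × PC1..PCk
    explained_variance_ratio: np.ndarray


def pca_overview(X: ExpressionMatrix, k: int) -> PCAResult:
    """Per-sample coordinates on the top-k principal components.

    The matrix is gene-centered (each gene's mean over samples removed)
    before the SVD, so adding a per-gene constant leaves the coordinates
    unchanged.  Each component's sign is fixed by making its
    largest-magnitude gene loading positive.
    """
    V = X.values
    p, n = V.shape
    if k < 1 or k > min(p, n):
        raise DirectionError(f"k must be in [1, min(genes, samples)]; got {k}")
    C = V - V.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    tol = s[0] * max(p, n) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if k > rank:
        raise DirectionError(f"k={k} exceeds the rank ({rank}) of the centered matrix")
    for j in range(k):
        i_max = int(np.argmax(np.abs(U[:, j])))
        if U[i_max, j] < 0:
            U[:, j] *= -1
            Vt[j, :] *= -1
    coords = (s[:k, None] * Vt[:k, :]).T
    var = s**2
    evr = var[:k] / var.sum()
    frame = pd.DataFrame(coords, index=X.sample_ids, columns=[f"PC{j+1}" for j in range(k)])
    return PCAResult(coords=frame, explained_variance_ratio=evr)
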