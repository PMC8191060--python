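"""Distance-based (PERMANOVA-style) matched-set test.

The squared distance matrix is Gower-centered to Δ = -1/2 C D∘D C and written
as Δ = Y S Yᵀ with S a ±1 diagonal (negative eigenvalues of non-Euclidean
distances such as Bray-Curtis are retained with sign -1, not truncated).
The pseudo-F statistic for submodel k,

    F_k = tr(X_kᵀ Δ X_k) / tr(R Δ R),   R = I - Σ_k' X_k' X_k'ᵀ,

is computed from the signed embedding without forming Δ.  Degrees-of-freedom
constants are omitted: permutation p-values are invariant to them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .design import MatchedDesign, ModelMatrix, build_design
from .permute import PermutationPlan, draw_permutations, permutation_pvalue
from .stats import permuted_trait_blocks

__all__ = [
    "DistanceMatrix",
    "DistanceDecomposition",
    "bray_curtis",
    "hellinger",
    "gower_center",
    "decompose",
    "pseudo_F",
    "permanova_test",
    "PermanovaResult",
]

#: Eigenvalues with |λ| below this fraction of max|λ| are discarded.
EIG_TOL = 1e-8


@dataclass
class DistanceMatrix:
    values: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(v < -1e-12):
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class DistanceDecomposition:
    """Signed eigen-embedding (Y, S) with Δ = Y diag(S) Yᵀ."""

    embedding: np.ndarray  # (n, r), columns scaled by sqrt(|λ|)
    signs: np.ndarray  # (r,), ±1
    eigenvalues: np.ndarray  # (r,), retained |λ|


def _relative_abundance(table) -> np.ndarray:
    counts = np.asarray(table.counts, dtype=float)
    totals = counts.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("every sample must have a positive total count")
    return counts / totals[:, None]


def bray_curtis(table) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on relative abundances, d in [0, 1]."""
    f = _relative_abundance(table)
    return DistanceMatrix(squareform(pdist(f, metric="braycurtis")), "bray-curtis")


def hellinger(table) -> DistanceMatrix:
    """Hellinger distance sqrt(Σ_j (√f_aj - √f_bj)²) on relative abundances."""
    f = _relative_abundance(table)
    return DistanceMatrix(squareform(pdist(np.sqrt(f), metric="euclidean")), "hellinger")


def gower_center(D: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Δ = -1/2 C (D∘D) C with C = I - (1/n)11ᵀ; rows and columns sum to zero."""
    values = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    sq = values * values
    # centering applied from both sides without forming C explicitly
    row = sq.mean(axis=1, keepdims=True)
    col = sq.mean(axis=0, keepdims=True)
    return -0.5 * (sq - row - col + sq.mean())


def decompose(delta: np.ndarray) -> DistanceDecomposition:
    """Signed eigendecomposition of a symmetric Gower-centered matrix."""
    delta = np.asarray(delta, dtype=float)
    if not np.allclose(delta, delta.T, atol=1e-10):
        raise ValueError("Gower-centered matrix must be symmetric")
    w, V = np.linalg.eigh(delta)
    amax = np.abs(w).max() if w.size else 0.0
    if amax == 0.0:
        n = delta.shape[0]
        return DistanceDecomposition(np.empty((n, 0)), np.empty(0), np.empty(0))
    keep = np.abs(w) > EIG_TOL * amax
    w, V = w[keep], V[:, keep]
    return DistanceDecomposition(V * np.sqrt(np.abs(w)), np.sign(w), np.abs(w))


def pseudo_F(model: ModelMatrix, decomp: DistanceDecomposition, k) -> float:
    """Pseudo-F for one tested submodel (name or block index).

    Numerator tr(X_kᵀΔX_k) = Σ_s S_s ||X_kᵀ y_s||²; the residual trace uses
    the projection off the full model.  Degrees-of-freedom constants omitted.
    """
    idx = model.tested_index(k) if isinstance(k, str) else int(k)
    Xk = model.blocks[idx]
    if Xk.shape[1] == 0:
        raise ValueError("submodel has no retained columns; statistic undefined")
    Z, S = decomp.embedding, decomp.signs
    if Xk.shape[0] != Z.shape[0]:
        raise ValueError("model and decomposition disagree on sample count")
    total = float(((Z * Z) @ S).sum())
    explained = [float((((B.T @ Z) ** 2) @ S).sum()) for B in model.blocks]
    num = explained[idx]
    den = total - sum(explained)
    return num / den


class PermanovaResult(dict):
    """Mapping submodel name -> dict(F=..., p=...), plus .n_perm."""

    n_perm: int = 0


_DISTANCES = {"bray-curtis": bray_curtis, "hellinger": hellinger}


def permanova_test(
    table,
    design: MatchedDesign,
    plan: PermutationPlan,
    distance_name: str = "bray-curtis",
    submodels: list[str] | None = None,
) -> PermanovaResult:
    """Matched-set PERMANOVA with restricted (or free) permutation.

    Permutations act on the rows of the orthonormalized tested block; the
    permuted block is re-orthogonalized against the preceding blocks so the
    statistic remains a proper variance ratio under every rearrangement.
    """
    if distance_name not in _DISTANCES:
        raise ValueError(f"unknown distance {distance_name!r}")
    decomp = decompose(gower_center(_DISTANCES[distance_name](table)))
    model = build_design(design)
    perms = draw_permutations(plan, model.n_samples)
    # within-set permutations are re-orthogonalized against preceding blocks
    # (needed when sample-level confounders are adjusted; a no-op w.r.t. the
    # set indicators).  Free permutation reproduces the naive strategy: the
    # orthonormalized trait rows are permuted as-is.
    reproject = plan.mode == "within_set"

    Z, S = decomp.embedding, decomp.signs
    total = float(((Z * Z) @ S).sum())
    explained = [float((((B.T @ Z) ** 2) @ S).sum()) for B in model.blocks]

    result = PermanovaResult()
    result.n_perm = perms.shape[0]
    tested = submodels or [nm for nm in model.block_names if nm != "_nuisance"]
    for name in tested:
        idx = model.tested_index(name)
        obs_num = explained[idx]
        obs_den = total - sum(explained)
        obs = obs_num / obs_den
        other = sum(explained) - obs_num
        stats = np.empty(perms.shape[0])
        for b, (Xp, ok) in enumerate(
            permuted_trait_blocks(model, idx, perms, reproject=reproject)
        ):
            if not ok:  # degenerate permuted block: explains nothing
                stats[b] = 0.0
                continue
            num = float((((Xp.T @ Z) ** 2) @ S).sum())
            den = total - other - num
            stats[b] = num / den if den > 0 else np.inf
        result[name] = {
            "F": obs,
            "p": permutation_pvalue(obs, stats, enumerated=plan.exhaustive),
        }
    return result
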