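"""Shared permutation machinery for the PERMANOVA and LDM statistics.

Both tests reduce to quantities of the form ||X_kᵀ Y||² for an orthonormal
tested block X_k.  The permutation null permutes the rows of the
orthonormalized tested block; the permuted block is then re-orthogonalized
against the preceding blocks (a no-op under within-set permutation when only
set indicators precede it, but required when sample-level confounders are
adjusted) and renormalized, so that every permuted statistic is a proper
variance ratio.
"""

from __future__ import annotations

import numpy as np

from .design import ModelMatrix

__all__ = ["permuted_trait_blocks", "block_numerators"]

_NORM_TOL = 1e-10


def block_numerators(block: np.ndarray, Z: np.ndarray, signs=None) -> np.ndarray:
    """Per-response-column explained quantity Σ_cols (X_kᵀ z)², optionally signed.

    For the LDM, ``Z`` is the centered response table and the result is the
    per-OTU numerator vector.  For PERMANOVA, ``Z`` is the signed embedding
    and the caller sums the result against the signs.
    """
    A = block.T @ Z
    num = (A * A).sum(axis=0)
    if signs is not None:
        return num * signs
    return num


def permuted_trait_blocks(
    model: ModelMatrix, idx: int, perms: np.ndarray, reproject: bool = True
):
    """Yield (permuted block, ok) for each row ordering in ``perms``.

    The tested block's rows are permuted; with ``reproject`` the result is
    projected off all preceding blocks and its columns renormalized (columns
    that become numerically zero are left at zero and contribute nothing).
    ``ok`` is False when every column vanished.
    """
    Xk = model.blocks[idx]
    prior = [B for B in model.blocks[:idx] if B.shape[1]]
    n, q = Xk.shape

    if q == 1:
        x = Xk[:, 0]
        M = x[perms]  # (B, n)
        if reproject:
            for B_ in prior:
                M = M - (M @ B_) @ B_.T
            nrm = np.linalg.norm(M, axis=1)
            ok = nrm > _NORM_TOL
            safe = np.where(ok, nrm, 1.0)
            M = M / safe[:, None]
        else:
            ok = np.ones(M.shape[0], dtype=bool)
        for b in range(M.shape[0]):
            yield M[b][:, None], bool(ok[b])
        return

    for b in range(perms.shape[0]):
        Xp = Xk[perms[b]]
        if reproject:
            cols = []
            for j in range(q):
                c = Xp[:, j]
                for B_ in prior:
                    c = c - B_ @ (B_.T @ c)
                for kept in cols:
                    c = c - kept * (kept @ c)
                nrm = np.linalg.norm(c)
                if nrm > _NORM_TOL:
                    cols.append(c / nrm)
            if not cols:
                yield np.zeros((n, 1)), False
                continue
            Xp = np.column_stack(cols)
        yield Xp, True
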