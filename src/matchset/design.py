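"""Design-matrix construction for matched-set linear models.

Both the distance-based (PERMANOVA) and OTU-table (LDM) tests operate on a
column-centered design matrix partitioned into ordered submodel blocks
``X = (X_1, ..., X_K)`` whose columns are made mutually orthonormal by a
sequential Gram-Schmidt process.  The test of submodel ``k`` is therefore
adjusted for all preceding submodels.

For matched sets, the first block holds one indicator column per set (plus
any sample-level confounders), so that every later block is orthogonal to
the set indicators.  A tested contrast orthogonal to the set indicators sums
to zero within every set, which removes the set-level means of the response
from the test statistic and confines the comparison to within-set deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MatchedDesign",
    "ModelMatrix",
    "Submodel",
    "InestimableTraitError",
    "center_columns",
    "make_set_indicators",
    "project_off",
    "build_design",
    "check_balance",
]

#: Columns whose norm after projection falls below DROP_TOL times their
#: pre-projection norm are treated as numerically zero and removed.
DROP_TOL = 1e-8

#: Tolerance for within-set zero-sum assertions.
ZERO_SUM_TOL = 1e-10


class InestimableTraitError(ValueError):
    """A tested variable lies entirely in the span of earlier blocks.

    This occurs, for example, when a trait is constant within every set and
    set indicators are adjusted for: the effect of a variable that has been
    matched on cannot be determined from within-set comparisons.
    """


@dataclass
class Submodel:
    """A named group of per-sample numeric columns tested (or adjusted) jointly."""

    name: str
    values: np.ndarray  # (n_samples, n_columns)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if v.ndim != 2 or v.shape[0] < 1:
            raise ValueError(f"submodel {self.name!r}: need a non-empty 2-D array")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"submodel {self.name!r}: non-finite values")
        self.values = v


@dataclass
class MatchedDesign:
    """Samples with set membership and an ordered list of submodels.

    Parameters
    ----------
    sample_ids
        Identifiers, one per sample (row order is authoritative).
    set_ids
        Per-sample set label ``s(i)``; every sample belongs to exactly one set.
    submodels
        Ordered tested variable groups (traits, interactions).  The test of
        submodel ``k`` is adjusted for submodels ``< k``.
    confounders
        Sample-level confounding covariates, adjusted in the first block.
    adjust_set_id
        If true (the recommended strategy), one indicator per set is placed at
        the head of the first block.  Set-level confounders are then
        automatically controlled for and need not be supplied.
    """

    sample_ids: list
    set_ids: np.ndarray
    submodels: list[Submodel]
    confounders: list[Submodel] = field(default_factory=list)
    adjust_set_id: bool = True

    def __post_init__(self) -> None:
        self.set_ids = np.asarray(self.set_ids)
        n = len(self.sample_ids)
        if self.set_ids.shape != (n,):
            raise ValueError("set_ids must have one label per sample")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if not self.submodels:
            raise ValueError("at least one tested submodel is required")
        for sm in list(self.submodels) + list(self.confounders):
            if sm.values.shape[0] != n:
                raise ValueError(f"submodel {sm.name!r} has wrong number of rows")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def set_labels(self) -> list:
        """Distinct set labels in first-appearance order."""
        seen: dict = {}
        for s in self.set_ids:
            seen.setdefault(s, None)
        return list(seen)


@dataclass
class ModelMatrix:
    """Sequentially orthonormalized design blocks ready for X_k'Y statistics.

    ``blocks[0]`` is the nuisance block (set indicators and/or confounders)
    when ``has_nuisance`` is true; tested submodels follow in order.
    """

    blocks: list[np.ndarray]
    block_names: list[str]
    n_samples: int
    has_nuisance: bool
    dropped_columns: list[tuple[str, int]]
    set_ids: np.ndarray

    @property
    def nuisance(self) -> np.ndarray | None:
        return self.blocks[0] if self.has_nuisance else None

    def tested_index(self, name: str) -> int:
        return self.block_names.index(name)

    def all_columns(self) -> np.ndarray:
        return np.hstack(self.blocks)


def center_columns(M: np.ndarray) -> np.ndarray:
    """Subtract per-column means so that every column sums to zero."""
    M = np.asarray(M, dtype=float)
    if M.size == 0 or M.shape[0] < 1:
        raise ValueError("cannot center an empty matrix")
    if M.ndim == 1:
        return M - M.mean()
    return M - M.mean(axis=0)


def make_set_indicators(set_ids: np.ndarray) -> np.ndarray:
    """0/1 indicator matrix with one column per set, first-appearance order.

    Centering and orthonormalization are applied later by :func:`build_design`;
    with S sets only S-1 centered columns are independent and the last one is
    dropped there.
    """
    set_ids = np.asarray(set_ids)
    if set_ids.size == 0:
        raise ValueError("need at least one set")
    labels: dict = {}
    for s in set_ids:
        labels.setdefault(s, len(labels))
    ind = np.zeros((set_ids.size, len(labels)))
    for i, s in enumerate(set_ids):
        ind[i, labels[s]] = 1.0
    return ind


def project_off(v: np.ndarray, basis) -> np.ndarray:
    """Remove from ``v`` its projection onto the span of orthonormal columns.

    ``basis`` may be a single 2-D array of orthonormal columns or a list of
    such arrays (e.g. ``ModelMatrix.blocks``).
    """
    v = np.asarray(v, dtype=float)
    out = v.copy()
    if isinstance(basis, np.ndarray):
        basis = [basis]
    for B in basis:
        if B.size == 0:
            continue
        out = out - B @ (B.T @ out)
    return out


def _orthonormalize_block(
    cols: np.ndarray, prior: list[np.ndarray], name: str, dropped: list
) -> np.ndarray:
    """Modified Gram-Schmidt of one block against prior blocks and itself."""
    kept: list[np.ndarray] = []
    for j in range(cols.shape[1]):
        c = center_columns(cols[:, j])
        ref = np.linalg.norm(c)
        c = project_off(c, prior)
        if kept:
            c = project_off(c, np.column_stack(kept))
        nrm = np.linalg.norm(c)
        if nrm < DROP_TOL * max(ref, 1.0):
            dropped.append((name, j))
            continue
        kept.append(c / nrm)
    return np.column_stack(kept) if kept else np.empty((cols.shape[0], 0))


def build_design(design: MatchedDesign) -> ModelMatrix:
    """Center and sequentially orthonormalize all design blocks.

    With ``adjust_set_id``, block 1 holds the centered and orthonormalized set
    indicators followed by any sample-level confounders; tested submodels are
    then orthonormalized against everything before them.  Numerically zero
    columns (e.g. the redundant last set indicator) are dropped and recorded.

    Raises
    ------
    InestimableTraitError
        If every column of a tested submodel is removed, i.e. the variable
        lies in the span of the earlier blocks.
    """
    dropped: list[tuple[str, int]] = []
    blocks: list[np.ndarray] = []
    names: list[str] = []

    nuis_cols = []
    if design.adjust_set_id:
        nuis_cols.append(make_set_indicators(design.set_ids))
    for cf in design.confounders:
        nuis_cols.append(cf.values)
    has_nuisance = bool(nuis_cols)
    if has_nuisance:
        raw = np.hstack(nuis_cols)
        blk = _orthonormalize_block(raw, [], "_nuisance", dropped)
        blocks.append(blk)
        names.append("_nuisance")

    for sm in design.submodels:
        blk = _orthonormalize_block(sm.values, blocks, sm.name, dropped)
        if blk.shape[1] == 0:
            raise InestimableTraitError(
                f"trait {sm.name!r} inestimable under matching: it lies in the "
                "span of the set indicators / preceding submodels"
            )
        blocks.append(blk)
        names.append(sm.name)

    return ModelMatrix(
        blocks=blocks,
        block_names=names,
        n_samples=design.n_samples,
        has_nuisance=has_nuisance,
        dropped_columns=dropped,
        set_ids=np.asarray(design.set_ids),
    )


def check_balance(v: np.ndarray, set_ids: np.ndarray, tol: float = ZERO_SUM_TOL) -> bool:
    """True iff the within-set mean of ``v`` is the same in every set.

    A balanced variable's centered values already sum to zero within each
    set, so its test is identical with and without set-indicator adjustment
    under within-set permutation.
    """
    v = np.asarray(v, dtype=float).ravel()
    set_ids = np.asarray(set_ids)
    means = []
    for s in dict.fromkeys(set_ids):
        mask = set_ids == s
        means.append(v[mask].sum() / mask.sum())
    means = np.asarray(means)
    return bool(np.all(np.abs(means - means[0]) <= tol * max(1.0, np.abs(means).max())))
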