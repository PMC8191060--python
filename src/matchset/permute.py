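"""Restricted (within-set) and free row permutations, and permutation p-values.

Samples within a matched set are assumed exchangeable once covariates are
accounted for, so the permutation null rearranges trait rows only among
samples of the same set.  Free permutation over all rows is also provided,
chiefly so that its miscalibration on matched data can be demonstrated.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

__all__ = ["PermutationPlan", "draw_permutations", "permutation_pvalue"]

#: Refuse exhaustive enumeration beyond this many distinct permutations.
ENUMERATION_CAP = 10**6


@dataclass
class PermutationPlan:
    """How to generate the permutation null.

    mode
        ``"within_set"`` permutes rows only within sets (requires ``set_ids``);
        ``"free"`` permutes all rows.
    n_perm
        Number B of random permutations (ignored when ``exhaustive``).
    seed
        Master seed; the draw sequence is reproducible given the seed.
    exhaustive
        Enumerate all distinct within-set permutations instead of sampling;
        the identity is included and handled by the enumerated p-value rule.
    """

    mode: str = "within_set"
    n_perm: int = 10_000
    seed: int = 0
    set_ids: np.ndarray | None = None
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("within_set", "free"):
            raise ValueError(f"unknown permutation mode {self.mode!r}")
        if self.mode == "within_set" and self.set_ids is None:
            raise ValueError("within_set permutation requires set_ids")
        if self.set_ids is not None:
            self.set_ids = np.asarray(self.set_ids)


def _set_index_groups(set_ids: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(set_ids == s) for s in dict.fromkeys(set_ids)]


def n_within_set_permutations(set_ids: np.ndarray) -> int:
    """Product of factorials of the set sizes."""
    return math.prod(math.factorial(len(g)) for g in _set_index_groups(np.asarray(set_ids)))


def draw_permutations(plan: PermutationPlan, n_samples: int) -> np.ndarray:
    """Return a (B, n) array of row orderings.

    In ``within_set`` mode every ordering maps each sample to a sample of the
    same set.  In ``exhaustive`` mode all distinct within-set orderings are
    returned (identity included), provided their number does not exceed
    ``ENUMERATION_CAP``.
    """
    if plan.set_ids is not None and plan.set_ids.size != n_samples:
        raise ValueError("set_ids length does not match n_samples")

    if plan.exhaustive:
        if plan.mode != "within_set":
            raise ValueError("exhaustive enumeration is defined for within_set mode")
        total = n_within_set_permutations(plan.set_ids)
        if total > ENUMERATION_CAP:
            raise ValueError(
                f"{total} within-set permutations exceed the enumeration cap "
                f"({ENUMERATION_CAP}); use random sampling"
            )
        groups = _set_index_groups(plan.set_ids)
        per_set = [list(itertools.permutations(g)) for g in groups]
        out = np.empty((total, n_samples), dtype=np.intp)
        for b, combo in enumerate(itertools.product(*per_set)):
            for g, pg in zip(groups, combo):
                out[b, g] = pg
        return out

    rng = np.random.default_rng(plan.seed)
    B = plan.n_perm
    if B < 1:
        raise ValueError("n_perm must be >= 1")
    idx = np.tile(np.arange(n_samples, dtype=np.intp), (B, 1))
    if plan.mode == "free":
        return rng.permuted(idx, axis=1)
    for g in _set_index_groups(plan.set_ids):
        if len(g) > 1:
            idx[:, g] = rng.permuted(idx[:, g], axis=1)
    return idx


def permutation_pvalue(
    observed: float, permuted: np.ndarray, enumerated: bool = False
) -> float:
    """Convert permuted statistics to a p-value; ties count as exceedances.

    Random sampling uses the add-one estimator p = (1 + #{perm >= obs})/(1 + B),
    which is valid for any B.  For an exhaustive enumeration (identity
    included among the permutations) the p-value is the exact proportion
    #{perm >= obs} / #permutations.
    """
    permuted = np.asarray(permuted, dtype=float)
    if permuted.size < 1:
        raise ValueError("need at least one permuted statistic")
    if not np.isfinite(observed) or not np.all(np.isfinite(permuted)):
        raise ValueError("non-finite test statistic")
    count = int(np.sum(permuted >= observed))
    if enumerated:
        return count / permuted.size
    return (1 + count) / (1 + permuted.size)
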