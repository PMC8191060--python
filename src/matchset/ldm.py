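"""Linear decomposition model (LDM) style tests on the OTU table.

The centered OTU table Y (frequency or arcsin-root-transformed frequency
scale) is regressed on the orthonormalized design blocks; submodel k is
summarized per OTU j by

    F_kj = ||X_kᵀ y_j||² / ||y_j - Σ_k' X_k' X_k'ᵀ y_j||²

(full-model residual) and globally by the ratio of summed numerators to
summed residuals.  Global, per-OTU and omnibus (min-p over scales) p-values
all come from one shared permutation stream, so community-level findings can
be resolved at the OTU level coherently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .design import MatchedDesign, ModelMatrix, build_design, center_columns
from .io import CountTable
from .permute import PermutationPlan, draw_permutations, permutation_pvalue
from .stats import permuted_trait_blocks

__all__ = [
    "ResponseMatrix",
    "LdmResult",
    "to_frequency",
    "arcsin_root",
    "filter_otus",
    "ldm_statistics",
    "ldm_test",
    "detect_otus",
]

SCALES = ("freq", "arcsin")


@dataclass
class ResponseMatrix:
    """Column-centered samples x features response with identifiers."""

    values: np.ndarray
    feature_ids: list
    scale: str = "freq"


def relative_abundance(table: CountTable) -> np.ndarray:
    totals = table.counts.sum(axis=1).astype(float)
    if np.any(totals <= 0):
        raise ValueError("every sample needs a positive total count")
    return table.counts / totals[:, None]


def to_frequency(table: CountTable) -> ResponseMatrix:
    """Relative abundances (rows sum to 1), then column-centered."""
    return ResponseMatrix(center_columns(relative_abundance(table)), list(table.otu_ids), "freq")


def arcsin_root(freqs, feature_ids=None) -> ResponseMatrix:
    """Elementwise asin(sqrt(f)) of frequencies in [0, 1], column-centered.

    The arcsin-root transform is variance-stabilizing for proportions and
    complements the raw frequency scale, which is dominated by abundant OTUs.
    Accepts a CountTable or an array of frequencies.
    """
    if isinstance(freqs, CountTable):
        f = relative_abundance(freqs)
        feature_ids = list(freqs.otu_ids)
    else:
        f = np.asarray(freqs, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("frequencies must lie in [0, 1]")
    vals = np.arcsin(np.sqrt(f))
    if feature_ids is None:
        feature_ids = list(range(vals.shape[1]))
    return ResponseMatrix(center_columns(vals), feature_ids, "arcsin")


def filter_otus(table: CountTable, min_nonzero: int = 5) -> CountTable:
    """Keep OTUs with at least ``min_nonzero`` samples having positive count."""
    keep = (table.counts > 0).sum(axis=0) >= min_nonzero
    if not keep.any():
        raise ValueError("no OTUs pass the prevalence filter")
    return CountTable(
        table.counts[:, keep],
        table.sample_ids,
        [o for o, k in zip(table.otu_ids, keep) if k],
    )


def _block_numerators(block: np.ndarray, Y: np.ndarray) -> np.ndarray:
    A = block.T @ Y
    return (A * A).sum(axis=0)


def ldm_statistics(model: ModelMatrix, Y: ResponseMatrix, k) -> tuple[float, np.ndarray]:
    """(global statistic, per-OTU statistics) for one tested submodel."""
    idx = model.tested_index(k) if isinstance(k, str) else int(k)
    vals = Y.values
    if vals.shape[0] != model.n_samples:
        raise ValueError("response and model disagree on sample count")
    tot = (vals * vals).sum(axis=0)
    nums = [_block_numerators(B, vals) for B in model.blocks]
    den = tot - sum(nums)
    den = np.where(den < 0, 0.0, den)
    if den.sum() <= 0:
        raise ValueError("zero residual for every OTU; statistics undefined")
    num = nums[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        per_otu = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)
        per_otu = np.where((den <= 0) & (num <= 0), 0.0, per_otu)
    return float(num.sum() / den.sum()), per_otu


@dataclass
class LdmResult:
    """Global, per-OTU and omnibus permutation test results.

    All dictionaries are keyed by tested submodel name; per-scale entries are
    nested dicts keyed by scale label.
    """

    feature_ids: list
    scales: tuple
    n_perm: int
    nominal_fdr: float
    global_stat: dict = field(default_factory=dict)
    global_p: dict = field(default_factory=dict)
    omnibus_p: dict = field(default_factory=dict)
    otu_stats: dict = field(default_factory=dict)
    otu_p: dict = field(default_factory=dict)
    otu_omnibus_p: dict = field(default_factory=dict)
    qvalues: dict = field(default_factory=dict)
    detected: dict = field(default_factory=dict)


def detect_otus(pvalues: np.ndarray, nominal_fdr: float = 0.10):
    """Benjamini-Hochberg step-up on per-OTU permutation p-values.

    Returns (detected boolean mask, q-values).  Per-OTU p-value resolution is
    bounded below by 1/(1+B), which coarsens the BH threshold at small B.
    """
    pvalues = np.asarray(pvalues, dtype=float)
    if np.any(pvalues <= 0) or np.any(pvalues > 1):
        raise ValueError("p-values must lie in (0, 1]")
    detected, qvals = multipletests(pvalues, alpha=nominal_fdr, method="fdr_bh")[:2]
    return detected, qvals


def _scale_responses(table: CountTable, scales) -> list[ResponseMatrix]:
    out = []
    for sc in scales:
        if sc == "freq":
            out.append(to_frequency(table))
        elif sc == "arcsin":
            out.append(arcsin_root(table))
        else:
            raise ValueError(f"unknown scale {sc!r}")
    return out


def ldm_test(
    table: CountTable,
    design: MatchedDesign,
    plan: PermutationPlan,
    scales=SCALES,
    nominal_fdr: float = 0.10,
    test_otus: bool = True,
    submodels: list[str] | None = None,
) -> LdmResult:
    """Community-level and OTU-level LDM tests with a shared permutation stream.

    Per scale, the global and per-OTU statistics are referred to the
    permutation distribution obtained by permuting rows of the orthonormalized
    tested block.  The omnibus p-value is the permutation p-value of the
    minimum across scales of the per-scale p-value ranks, computed from the
    same stream, so ``scales=("freq",)`` reduces the omnibus to the
    frequency-scale test.
    """
    scales = tuple(scales)
    model = build_design(design)
    perms = draw_permutations(plan, model.n_samples)
    B = perms.shape[0]
    responses = _scale_responses(table, scales)
    reproject = plan.mode == "within_set"

    result = LdmResult(
        feature_ids=list(table.otu_ids),
        scales=scales,
        n_perm=B,
        nominal_fdr=nominal_fdr,
    )
    tested = submodels or [nm for nm in model.block_names if nm != "_nuisance"]
    J = table.n_otus

    for name in tested:
        idx = model.tested_index(name)
        obs_global, obs_perotu, perm_global, perm_perotu = {}, {}, {}, {}
        for resp in responses:
            vals = resp.values
            tot = (vals * vals).sum(axis=0)
            nums = [_block_numerators(Bk, vals) for Bk in model.blocks]
            other = sum(nums) - nums[idx]
            obs_num = nums[idx]
            obs_den = np.maximum(tot - other - obs_num, 0.0)
            obs_global[resp.scale] = float(obs_num.sum() / obs_den.sum())
            with np.errstate(divide="ignore", invalid="ignore"):
                obs_perotu[resp.scale] = np.where(
                    obs_den > 0, obs_num / np.where(obs_den > 0, obs_den, 1.0), np.inf
                )
            g = np.empty(B)
            po = np.empty((B, J)) if test_otus else None
            for b, (Xp, ok) in enumerate(
                permuted_trait_blocks(model, idx, perms, reproject=reproject)
            ):
                if not ok:
                    g[b] = 0.0
                    if test_otus:
                        po[b] = 0.0
                    continue
                num = _block_numerators(Xp, vals)
                den = np.maximum(tot - other - num, 0.0)
                g[b] = num.sum() / den.sum()
                if test_otus:
                    with np.errstate(divide="ignore", invalid="ignore"):
                        po[b] = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)
            perm_global[resp.scale] = g
            perm_perotu[resp.scale] = po

        result.global_stat[name] = obs_global
        result.global_p[name] = {
            sc: permutation_pvalue(obs_global[sc], perm_global[sc], plan.exhaustive)
            for sc in obs_global
        }
        # omnibus: min over scales of per-permutation p-value ranks
        minp_perm = np.ones(B)
        minp_obs = 1.0
        for sc in obs_global:
            g = perm_global[sc]
            p_perm = rankdata(-g, method="max") / B
            minp_perm = np.minimum(minp_perm, p_perm)
            minp_obs = min(minp_obs, (1 + np.sum(g >= obs_global[sc])) / (1 + B))
        result.omnibus_p[name] = (1 + np.sum(minp_perm <= minp_obs)) / (1 + B)

        if test_otus:
            result.otu_stats[name] = obs_perotu
            result.otu_p[name] = {}
            minp_perm_o = np.ones((B, J))
            minp_obs_o = np.ones(J)
            for sc in obs_perotu:
                po = perm_perotu[sc]
                counts = (po >= obs_perotu[sc][None, :]).sum(axis=0)
                p_obs = (1 + counts) / (1 + B)
                result.otu_p[name][sc] = p_obs
                p_perm = rankdata(-po, method="max", axis=0) / B
                minp_perm_o = np.minimum(minp_perm_o, p_perm)
                minp_obs_o = np.minimum(minp_obs_o, p_obs)
            p_omni = (1 + (minp_perm_o <= minp_obs_o[None, :]).sum(axis=0)) / (1 + B)
            result.otu_omnibus_p[name] = p_omni
            det, qv = detect_otus(p_omni, nominal_fdr)
            result.qvalues[name] = qv
            result.detected[name] = det
    return result
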