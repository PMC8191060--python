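"""Replicate-level evaluation harness: type I error, power, sensitivity, FDR.

Each replicate simulates a matched-set dataset, applies an analysis strategy
(the proposed set-indicator + within-set-permutation strategy or one of the
deliberately degraded alternatives) and records the global p-value and, for
OTU-level analyses, the detected-OTU set against the simulation truth.
Causal OTU sets are drawn once from a dedicated substream so that all
scenarios and designs under one master seed share them; replicate data use
independent per-replicate substreams, so results do not depend on execution
order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import MatchedDesign, Submodel
from .ldm import filter_otus, ldm_test
from .permanova import permanova_test
from .permute import PermutationPlan
from .simulate import (
    CausalSets,
    SimConfig,
    assign_causal_sets,
    make_baseline_composition,
    simulate_dataset,
    substream,
)

__all__ = ["EvalConfig", "EvalResult", "run_calibration", "run_power", "compare_designs"]

STRATEGIES = ("proposed", "no_set_id", "free_permutation", "no_confounder")

_TAG_REPLICATE = 2


@dataclass
class EvalConfig:
    """One evaluation cell: simulation conditions x method x analysis strategy."""

    sim: SimConfig
    method: str = "ldm"
    strategy: str = "proposed"
    n_replicates: int = 1000
    alpha: float = 0.05
    nominal_fdr: float = 0.10
    n_perm: int = 1000
    seed: int = 0
    distance: str = "bray-curtis"
    scales: tuple = ("freq", "arcsin")
    min_nonzero: int = 5
    test_otus: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("permanova", "ldm"):
            raise ValueError("method must be 'permanova' or 'ldm'")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if not (0 < self.alpha < 1 and 0 < self.nominal_fdr < 1):
            raise ValueError("alpha and nominal_fdr must lie in (0, 1)")


@dataclass
class EvalResult:
    """Monte-Carlo summary over replicates."""

    rejection_rate: float
    se: float
    n_replicates: int
    alpha: float
    pvalues: np.ndarray
    mean_sensitivity: float | None = None
    mean_fdr: float | None = None
    records: pd.DataFrame | None = None

    def summary(self) -> dict:
        out = {
            "rejection_rate": self.rejection_rate,
            "se": self.se,
            "n_replicates": self.n_replicates,
        }
        if self.mean_sensitivity is not None:
            out["mean_sensitivity"] = self.mean_sensitivity
            out["mean_fdr"] = self.mean_fdr
        return out


def _design_for_strategy(data, config: EvalConfig) -> tuple[MatchedDesign, str]:
    """Build the MatchedDesign a given strategy implies; returns (design, tested)."""
    meta = data.metadata
    submodels = [Submodel("trait", meta["trait"].to_numpy(dtype=float))]
    tested = "trait"
    if config.sim.beta_int is not None:
        inter = meta["trait"].to_numpy(dtype=float) * meta["x_set"].to_numpy(dtype=float)
        submodels.append(Submodel("interaction", inter))
        tested = "interaction"
    confounders = []
    if config.sim.beta_sam is not None and config.strategy != "no_confounder":
        confounders.append(Submodel("x_sam", meta["x_sam"].to_numpy(dtype=float)))
    design = MatchedDesign(
        sample_ids=list(meta["sample_id"]),
        set_ids=meta["set_id"].to_numpy(),
        submodels=submodels,
        confounders=confounders,
        adjust_set_id=config.strategy != "no_set_id",
    )
    return design, tested


def _one_replicate(config: EvalConfig, causal: CausalSets, rep: int, sim: SimConfig | None = None):
    sim = sim or config.sim
    rng = substream_pair(config.seed, rep)
    data = simulate_dataset(sim, causal=causal, rng=rng)
    table = filter_otus(data.table, config.min_nonzero)
    design, tested = _design_for_strategy(data, config)
    mode = "free" if config.strategy == "free_permutation" else "within_set"
    plan = PermutationPlan(
        mode=mode,
        n_perm=config.n_perm,
        seed=int(rng.integers(2**31)),
        set_ids=design.set_ids if mode == "within_set" else None,
    )
    rec = {"replicate": rep}
    if config.method == "permanova":
        res = permanova_test(table, design, plan, config.distance, submodels=[tested])
        rec["p"] = res[tested]["p"]
        return rec
    res = ldm_test(
        table,
        design,
        plan,
        scales=config.scales,
        nominal_fdr=config.nominal_fdr,
        test_otus=config.test_otus,
        submodels=[tested],
    )
    rec["p"] = res.omnibus_p[tested]
    if config.test_otus:
        truth = (
            data.causal.interaction_causal
            if tested == "interaction"
            else data.causal.trait_causal
        )
        causal_ids = {f"otu{j + 1}" for j in truth}
        detected_ids = {
            fid for fid, d in zip(res.feature_ids, res.detected[tested]) if d
        }
        tp = len(detected_ids & causal_ids)
        rec["sensitivity"] = tp / len(causal_ids)
        rec["fdp"] = (len(detected_ids) - tp) / max(1, len(detected_ids))
    return rec


def substream_pair(seed: int, rep: int) -> np.random.Generator:
    """Per-replicate generator, independent of execution order."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_TAG_REPLICATE, rep)))


def _causal_for(config: EvalConfig, sim: SimConfig | None = None) -> CausalSets:
    sim = sim or config.sim
    baseline = (
        sim.baseline
        if sim.baseline is not None
        else make_baseline_composition(sim.n_otus, sim.baseline_shape)
    )
    return assign_causal_sets(
        baseline,
        sim.mechanism,
        substream(config.seed, 0),
        with_set_covariate=sim.beta_set is not None,
        with_sample_confounder=sim.beta_sam is not None,
        with_interaction=sim.beta_int is not None,
    )


def _run(config: EvalConfig, sim: SimConfig | None = None) -> EvalResult:
    causal = _causal_for(config, sim)
    records = [
        _one_replicate(config, causal, rep, sim=sim) for rep in range(config.n_replicates)
    ]
    frame = pd.DataFrame(records)
    p = frame["p"].to_numpy()
    rate = float(np.mean(p <= config.alpha))
    se = float(np.sqrt(rate * (1 - rate) / len(p))) if len(p) > 1 else float("nan")
    res = EvalResult(
        rejection_rate=rate,
        se=se,
        n_replicates=len(p),
        alpha=config.alpha,
        pvalues=p,
        records=frame,
    )
    if "sensitivity" in frame:
        res.mean_sensitivity = float(frame["sensitivity"].mean())
        res.mean_fdr = float(frame["fdp"].mean())
    return res


def run_calibration(config: EvalConfig) -> EvalResult:
    """Type I error: fraction of null replicates with global p <= alpha.

    Requires a null simulation (trait effect zero; for interaction scenarios,
    interaction effect zero while main effects stay on).
    """
    null_beta = config.sim.beta_int if config.sim.beta_int is not None else config.sim.beta
    if null_beta != 0:
        raise ValueError("calibration requires a zero tested effect")
    return _run(config)


def run_power(config: EvalConfig) -> EvalResult:
    """Rejection rate under a non-zero effect; with ``test_otus`` also
    mean OTU-level sensitivity and empirical FDR (0/0 counted as 0)."""
    return _run(config)


def compare_designs(config: EvalConfig, designs: dict) -> dict:
    """Evaluate several matched designs under shared causal-OTU draws.

    ``designs`` maps a label to either a set-size list (e.g. ``[2]*50``) or
    the string ``"independent"``, which simulates pairs and keeps one sample
    per pair (half cases, half controls), analyzed unmatched with free
    permutation.
    """
    out = {}
    for label, spec in designs.items():
        if isinstance(spec, str) and spec == "independent":
            out[label] = _run_independent(config)
        else:
            sim = replace(config.sim, set_sizes=list(spec))
            out[label] = _run(config, sim=sim)
    return out


def _run_independent(config: EvalConfig) -> EvalResult:
    """Unmatched case-control arm: one sample kept per simulated pair."""
    n_sets = len(config.sim.set_sizes)
    sim = replace(config.sim, set_sizes=[2] * n_sets)
    causal = _causal_for(config, sim)
    records = []
    for rep in range(config.n_replicates):
        rng = substream_pair(config.seed, rep)
        data = simulate_dataset(sim, causal=causal, rng=rng)
        meta = data.metadata
        # half the pairs contribute their case, half their control
        keep_case = np.zeros(n_sets, dtype=bool)
        keep_case[rng.permutation(n_sets)[: n_sets // 2]] = True
        keep_rows = []
        for i, (label, grp) in enumerate(meta.groupby("set_id", sort=False)):
            want = 1.0 if keep_case[i] else 0.0
            keep_rows.append(grp.index[grp["trait"] == want][0])
        sub_meta = meta.loc[keep_rows]
        rows = [meta.index.get_loc(r) for r in keep_rows]
        from .io import CountTable

        table = CountTable(
            data.table.counts[rows],
            list(sub_meta["sample_id"]),
            data.table.otu_ids,
        )
        table = filter_otus(table, config.min_nonzero)
        design = MatchedDesign(
            sample_ids=list(sub_meta["sample_id"]),
            set_ids=np.arange(len(rows)),  # singletons: unmatched analysis
            submodels=[Submodel("trait", sub_meta["trait"].to_numpy(dtype=float))],
            adjust_set_id=False,
        )
        plan = PermutationPlan(mode="free", n_perm=config.n_perm, seed=int(rng.integers(2**31)))
        rec = {"replicate": rep}
        if config.method == "permanova":
            res = permanova_test(table, design, plan, config.distance)
            rec["p"] = res["trait"]["p"]
        else:
            res = ldm_test(
                table,
                design,
                plan,
                scales=config.scales,
                nominal_fdr=config.nominal_fdr,
                test_otus=config.test_otus,
            )
            rec["p"] = res.omnibus_p["trait"]
            if config.test_otus:
                causal_ids = {f"otu{j + 1}" for j in data.causal.trait_causal}
                detected_ids = {
                    fid for fid, d in zip(res.feature_ids, res.detected["trait"]) if d
                }
                tp = len(detected_ids & causal_ids)
                rec["sensitivity"] = tp / len(causal_ids)
                rec["fdp"] = (len(detected_ids) - tp) / max(1, len(detected_ids))
        records.append(rec)
    frame = pd.DataFrame(records)
    p = frame["p"].to_numpy()
    rate = float(np.mean(p <= config.alpha))
    res = EvalResult(
        rejection_rate=rate,
        se=float(np.sqrt(rate * (1 - rate) / len(p))),
        n_replicates=len(p),
        alpha=config.alpha,
        pvalues=p,
        records=frame,
    )
    if "sensitivity" in frame:
        res.mean_sensitivity = float(frame["sensitivity"].mean())
        res.mean_fdr = float(frame["fdp"].mean())
    return res
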