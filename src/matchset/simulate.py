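"""Dirichlet-multinomial simulator for matched-set microbiome count data.

The hierarchy mirrors a matched case-control (or pre/post) 16S study:

1. a population mean composition π̄ (by default a synthetic geometric-decay
   composition standing in for an estimated real-data composition),
2. set-level compositions π̄_i ~ Dir(π̄, θ1) capturing between-set
   heterogeneity,
3. sample-level baseline compositions π⁰_ij ~ Dir(π̄_i, θ2) capturing
   within-set heterogeneity,
4. a trait effect that moves mass from "decreased" causal OTUs to
   "increased" ones (half evenly, half proportionally), interpolated by the
   trait value: π_ij = (1-x) π⁰_ij + x π^trait_ij,
5. multinomial read counts at Poisson(depth) library sizes with a floor.

Optional set-level covariates, sample-level confounders and trait-by-covariate
interactions perturb the compositions with the same reduce/redistribute
mechanics.  All Dirichlet distributions use the mean/overdispersion
parameterization α = mean · (1-θ)/θ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountTable

__all__ = [
    "SimConfig",
    "CausalSets",
    "SimulatedDataset",
    "make_baseline_composition",
    "dirichlet_from_mean",
    "assign_traits",
    "assign_causal_sets",
    "apply_trait_effect",
    "apply_set_covariate",
    "apply_sample_confounder",
    "apply_interaction",
    "draw_counts",
    "simulate_dataset",
    "scenario_config",
    "design_fixed_total",
    "design_fixed_sets",
]

SIMPLEX_TOL = 1e-10


@dataclass
class SimConfig:
    """Parameters of one simulated matched-set dataset.

    ``set_sizes`` lists samples per set (a 1:m design has sets of size m+1).
    ``theta1``/``theta2`` are the between-set and within-set Dirichlet
    overdispersions; ``beta`` is the trait effect size (multiplication of
    decreased-OTU frequencies by 1-beta).  Covariate effects are enabled by
    setting ``beta_set``/``beta_sam``/``beta_int`` to non-None.
    """

    n_otus: int = 856
    set_sizes: list[int] = field(default_factory=lambda: [2] * 50)
    trait_type: str = "binary"
    theta1: float = 0.02
    theta2: float = 0.007
    beta: float = 0.0
    beta_set: float | None = None
    beta_sam: float | None = None
    beta_int: float | None = None
    mechanism: str = "S1"
    depth_mean: float = 10_000
    depth_floor: int = 500
    baseline_shape: float = 0.985
    baseline: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.theta1 < 1 and 0 < self.theta2 < 1):
            raise ValueError("theta1 and theta2 must lie in (0, 1)")
        for nm in ("beta", "beta_set", "beta_sam", "beta_int"):
            v = getattr(self, nm)
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"{nm} must lie in [0, 1]")
        if self.depth_floor > self.depth_mean:
            raise ValueError("depth_floor must not exceed depth_mean")
        if self.trait_type not in ("binary", "continuous"):
            raise ValueError("trait_type must be 'binary' or 'continuous'")
        if self.mechanism not in ("S1", "S2"):
            raise ValueError("mechanism must be 'S1' or 'S2'")
        if min(self.set_sizes) < 1:
            raise ValueError("every set needs at least one sample")
        if self.baseline is not None:
            b = np.asarray(self.baseline, dtype=float)
            if abs(b.sum() - 1) > SIMPLEX_TOL or np.any(b <= 0):
                raise ValueError("user baseline must be strictly positive and sum to 1")
            self.baseline = b
            self.n_otus = b.size

    @property
    def n_samples(self) -> int:
        return sum(self.set_sizes)


@dataclass
class CausalSets:
    """Index sets of OTUs tied to the trait, covariates and interaction."""

    trait_minus: np.ndarray
    trait_plus_additive: np.ndarray
    trait_plus_multiplicative: np.ndarray
    set_minus: np.ndarray | None = None
    set_plus: np.ndarray | None = None
    sam_minus: np.ndarray | None = None
    sam_plus: np.ndarray | None = None
    int_minus: np.ndarray | None = None
    int_plus: np.ndarray | None = None

    @property
    def trait_causal(self) -> np.ndarray:
        return np.concatenate(
            [self.trait_minus, self.trait_plus_additive, self.trait_plus_multiplicative]
        )

    @property
    def interaction_causal(self) -> np.ndarray | None:
        if self.int_minus is None:
            return None
        return np.concatenate([self.int_minus, self.int_plus])


@dataclass
class SimulatedDataset:
    table: CountTable
    metadata: pd.DataFrame
    causal: CausalSets
    pi_bar: np.ndarray  # (n_sets, J) set-level means after any set-covariate effect
    pi0: np.ndarray  # (n, J) sample baseline compositions
    pi: np.ndarray  # (n, J) final true compositions


def substream(seed: int, tag: int) -> np.random.Generator:
    """Named child stream of the master seed (stable across platforms)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(tag,)))


# substream tags: causal-OTU draws are kept separate so the same causal sets
# can be reused across scenarios and replicates by fixing the master seed.
_TAG_CAUSAL = 0
_TAG_DATA = 1


def make_baseline_composition(n_otus: int, shape: float = 0.985) -> np.ndarray:
    """Synthetic mean composition: normalized geometric decay, ratio ``shape``.

    A decay ratio just below 1 over several hundred OTUs yields the skewed,
    long-tailed rank-abundance profile typical of real 16S communities.
    ``shape=1`` gives the uniform composition.
    """
    if n_otus < 2:
        raise ValueError("need at least two OTUs")
    if not 0 < shape <= 1:
        raise ValueError("shape must lie in (0, 1]")
    pi = shape ** np.arange(n_otus, dtype=float)
    return pi / pi.sum()


def dirichlet_from_mean(mean: np.ndarray, theta: float) -> np.ndarray:
    """Concentration α = mean (1-θ)/θ; Σα = (1-θ)/θ.

    Under this parameterization a Dirichlet draw has expectation ``mean`` and
    Var(p_j) = θ mean_j (1-mean_j), so θ is the overdispersion of the
    Dirichlet-multinomial model.
    """
    if not 0 < theta < 1:
        raise ValueError("theta must lie in (0, 1)")
    return np.asarray(mean, dtype=float) * (1 - theta) / theta


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    # gamma-based draw tolerating zero concentrations (component stays zero)
    g = rng.standard_gamma(np.maximum(alpha, 0.0))
    s = g.sum()
    if s <= 0:
        raise ValueError("degenerate Dirichlet draw: all concentrations zero")
    return g / s


def assign_traits(set_sizes: list[int], trait_type: str, rng: np.random.Generator) -> np.ndarray:
    """Per-sample trait: one case (1) per set for binary designs, U[0,1] else."""
    if trait_type == "binary":
        parts = []
        for m in set_sizes:
            x = np.zeros(m)
            x[rng.integers(m)] = 1.0
            parts.append(x)
        return np.concatenate(parts)
    return rng.random(sum(set_sizes))


def _split_halves(idx: np.ndarray, rng: np.random.Generator):
    idx = rng.permutation(idx)
    half = idx.size // 2
    return idx[:half], idx[half:]


def assign_causal_sets(
    baseline: np.ndarray,
    mechanism: str,
    rng: np.random.Generator,
    with_set_covariate: bool = False,
    with_sample_confounder: bool = False,
    with_interaction: bool = False,
) -> CausalSets:
    """Draw the causal / covariate-associated OTU index sets.

    Mechanism S1 takes half of all OTUs, sampled from the non-top-3 by
    abundance; S2 takes the ten most abundant.  Causal OTUs split equally into
    decreased / increased, and the increased half equally into additive and
    multiplicative receivers.  Covariate sets are fresh uniform draws of half
    the OTUs; interaction OTUs are a fresh half under S1 and abundance ranks
    1-5 and 11-15 under S2.
    """
    J = baseline.size
    order = np.argsort(-baseline, kind="stable")  # abundance ranks
    if mechanism == "S1":
        n_causal = J // 2 - (J // 2) % 2
        pool = order[3:]
        causal = rng.choice(pool, size=n_causal, replace=False)
    else:
        if J < 15:
            raise ValueError("mechanism S2 needs at least 15 OTUs")
        causal = order[:10]
    minus, plus = _split_halves(causal, rng)
    plus_a, plus_m = _split_halves(plus, rng)

    kw = {}
    if with_set_covariate:
        pick = rng.choice(J, size=J // 2, replace=False)
        kw["set_minus"], kw["set_plus"] = _split_halves(pick, rng)
    if with_sample_confounder:
        pick = rng.choice(J, size=J // 2, replace=False)
        kw["sam_minus"], kw["sam_plus"] = _split_halves(pick, rng)
    if with_interaction:
        if mechanism == "S1":
            pick = rng.choice(J, size=J // 2, replace=False)
        else:
            pick = np.concatenate([order[0:5], order[10:15]])
        kw["int_minus"], kw["int_plus"] = _split_halves(pick, rng)

    return CausalSets(minus, plus_a, plus_m, **kw)


def _check_simplex(pi: np.ndarray) -> np.ndarray:
    if np.any(pi < -SIMPLEX_TOL) or abs(pi.sum() - 1) > SIMPLEX_TOL:
        raise ValueError("composition left the simplex")
    return np.clip(pi, 0.0, None)


def _reduce_redistribute(
    pi: np.ndarray, minus: np.ndarray, plus: np.ndarray, beta: float
) -> np.ndarray:
    """Multiply ``minus`` OTUs by 1-beta, give the removed mass to ``plus``
    OTUs in proportion to their current frequencies."""
    out = pi.copy()
    removed = beta * out[minus].sum()
    out[minus] *= 1 - beta
    if removed > 0:
        if plus.size == 0:
            raise ValueError("no receiving OTUs for redistributed mass")
        w = pi[plus]
        out[plus] += removed * (w / w.sum() if w.sum() > 0 else np.full(plus.size, 1 / plus.size))
    return _check_simplex(out)


def apply_trait_effect(
    pi0: np.ndarray, beta: float, causal: CausalSets, x: float
) -> np.ndarray:
    """Trait-modified composition, interpolated by the trait value x in [0,1].

    Decreased OTUs are multiplied by 1-beta; half the removed mass goes evenly
    to the additive receivers and half proportionally (to baseline frequency)
    to the multiplicative receivers; the result is mixed with the baseline as
    (1-x) π⁰ + x π^trait.
    """
    if beta == 0 or x == 0:
        return pi0
    pt = pi0.copy()
    removed = beta * pt[causal.trait_minus].sum()
    pt[causal.trait_minus] *= 1 - beta
    if removed > 0:
        a, m = causal.trait_plus_additive, causal.trait_plus_multiplicative
        if a.size == 0 or m.size == 0:
            raise ValueError("empty receiver set with non-zero removed mass")
        pt[a] += removed / (2 * a.size)
        wm = pi0[m]
        pt[m] += (removed / 2) * (
            wm / wm.sum() if wm.sum() > 0 else np.full(m.size, 1 / m.size)
        )
    return _check_simplex((1 - x) * pi0 + x * pt)


def apply_set_covariate(
    mean_i: np.ndarray, x_set: float, causal: CausalSets, beta_set: float = 0.2
) -> np.ndarray:
    """Set-level covariate effect on the set mean composition (all-proportional)."""
    if x_set == 0 or beta_set == 0:
        return mean_i
    mod = _reduce_redistribute(mean_i, causal.set_minus, causal.set_plus, beta_set)
    return _check_simplex((1 - x_set) * mean_i + x_set * mod)


def apply_sample_confounder(
    pi: np.ndarray, x_sam: float, causal: CausalSets, beta_sam: float = 0.5
) -> np.ndarray:
    """Sample-level confounder effect on the final composition (all-proportional)."""
    if x_sam == 0 or beta_sam == 0:
        return pi
    mod = _reduce_redistribute(pi, causal.sam_minus, causal.sam_plus, beta_sam)
    return _check_simplex((1 - x_sam) * pi + x_sam * mod)


def apply_interaction(
    pi: np.ndarray, x_set: float, x_trait: float, causal: CausalSets, beta_int: float
) -> np.ndarray:
    """Extra trait-by-covariate effect, active when both indicators are 1."""
    w = x_set * x_trait
    if w == 0 or beta_int == 0:
        return pi
    mod = _reduce_redistribute(pi, causal.int_minus, causal.int_plus, beta_int)
    return _check_simplex((1 - w) * pi + w * mod)


def draw_counts(
    pi: np.ndarray,
    rng: np.random.Generator,
    depth_mean: float = 10_000,
    depth_floor: int = 500,
) -> np.ndarray:
    """Multinomial counts at library size max(Poisson(depth_mean), depth_floor)."""
    N = int(rng.poisson(depth_mean))
    if N < depth_floor:
        N = depth_floor
    return rng.multinomial(N, pi / pi.sum())


def simulate_dataset(
    config: SimConfig,
    causal: CausalSets | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Generate one matched-set dataset under the full hierarchy.

    ``causal`` may be supplied to reuse the same causal OTU sets across
    scenarios/replicates (otherwise drawn from a dedicated substream of
    ``config.seed``); ``rng`` likewise overrides the data substream.
    """
    baseline = (
        config.baseline
        if config.baseline is not None
        else make_baseline_composition(config.n_otus, config.baseline_shape)
    )
    if causal is None:
        causal = assign_causal_sets(
            baseline,
            config.mechanism,
            substream(config.seed, _TAG_CAUSAL),
            with_set_covariate=config.beta_set is not None,
            with_sample_confounder=config.beta_sam is not None,
            with_interaction=config.beta_int is not None,
        )
    if rng is None:
        rng = substream(config.seed, _TAG_DATA)

    J = baseline.size
    sizes = list(config.set_sizes)
    n = sum(sizes)
    x_trait = assign_traits(sizes, config.trait_type, rng)

    x_set = None
    if config.beta_set is not None or config.beta_int is not None:
        x_set = rng.binomial(1, 0.5, size=len(sizes)).astype(float)

    alpha1 = dirichlet_from_mean(baseline, config.theta1)
    counts = np.empty((n, J), dtype=int)
    pi_bar = np.empty((len(sizes), J))
    pi0_all = np.empty((n, J))
    pi_all = np.empty((n, J))
    x_sam = np.zeros(n)

    row = 0
    for i, m in enumerate(sizes):
        mean_i = _dirichlet(rng, alpha1)
        if config.beta_set is not None and x_set is not None:
            mean_i = apply_set_covariate(mean_i, x_set[i], causal, config.beta_set)
        pi_bar[i] = mean_i
        alpha2 = dirichlet_from_mean(mean_i, config.theta2)
        for _ in range(m):
            x = x_trait[row]
            pi0 = _dirichlet(rng, alpha2)
            pi = apply_trait_effect(pi0, config.beta, causal, x)
            if config.beta_sam is not None:
                xs = float(rng.random() < (0.2 - 0.1 * x))
                x_sam[row] = xs
                pi = apply_sample_confounder(pi, xs, causal, config.beta_sam)
            if config.beta_int is not None and x_set is not None:
                pi = apply_interaction(pi, x_set[i], x, causal, config.beta_int)
            pi0_all[row], pi_all[row] = pi0, pi
            counts[row] = draw_counts(pi, rng, config.depth_mean, config.depth_floor)
            row += 1

    sample_ids = [f"s{i + 1}" for i in range(n)]
    set_labels = np.concatenate([[f"set{i + 1}"] * m for i, m in enumerate(sizes)])
    meta = pd.DataFrame({"sample_id": sample_ids, "set_id": set_labels, "trait": x_trait})
    if x_set is not None:
        meta["x_set"] = np.concatenate([[x_set[i]] * m for i, m in enumerate(sizes)])
    if config.beta_sam is not None:
        meta["x_sam"] = x_sam

    table = CountTable(counts, sample_ids, [f"otu{j + 1}" for j in range(J)])
    return SimulatedDataset(table, meta, causal, pi_bar, pi0_all, pi_all)


def design_fixed_total(m: int) -> list[int]:
    """1:m designs holding the total sample count at 90."""
    grids = {1: [2] * 45, 2: [3] * 30, 3: [4] * 22 + [2], 4: [5] * 18, 5: [6] * 15}
    if m not in grids:
        raise ValueError("m must be in 1..5")
    return grids[m]


def design_fixed_sets(m: int, n_sets: int = 50) -> list[int]:
    """1:m designs holding the number of sets fixed."""
    return [m + 1] * n_sets


def scenario_config(scenario: int, seed: int = 0, beta: float = 0.0, **overrides) -> SimConfig:
    """Presets for the seven evaluation scenarios.

    1 matched pairs; 2 unbalanced (25 pairs + 25 1:2 sets); 3 pairs with a
    sample-level confounder; 4 pairs with a set-level covariate; 5 unbalanced
    with a set-level covariate; 6 pairs with a continuous trait; 7 pairs with
    a trait-by-set-covariate interaction (trait and covariate main effects
    always present; ``beta`` is the interaction effect size there).
    """
    pairs = [2] * 50
    unbalanced = [2] * 25 + [3] * 25
    presets = {
        1: dict(set_sizes=pairs),
        2: dict(set_sizes=unbalanced),
        3: dict(set_sizes=pairs, beta_sam=0.5),
        4: dict(set_sizes=pairs, beta_set=0.2),
        5: dict(set_sizes=unbalanced, beta_set=0.2),
        6: dict(set_sizes=pairs, trait_type="continuous"),
        7: dict(set_sizes=pairs, beta_set=0.2, beta_int=beta),
    }
    if scenario not in presets:
        raise ValueError("scenario must be in 1..7")
    kw = presets[scenario]
    if scenario == 7:
        kw["beta"] = 0.5  # trait main effect always present alongside interaction
    else:
        kw["beta"] = beta
    kw.update(overrides)
    return SimConfig(seed=seed, **kw)
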