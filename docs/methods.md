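# Methods

## The problem

Matched-set microbiome studies — pre/post samples from the same participant,
or cases matched to one or more controls — cluster samples into sets whose
community compositions are far more similar within than between sets. The
scientific question ("is the microbiome associated with the trait?") concerns
only the *within-set* contrasts; the set-level means are nuisance. `matchset`
implements two permutation tests that respect this structure:

* a **distance-based PERMANOVA-style test** at the community level, and
* an **LDM-style test** (linear decomposition model) that produces coherent
  community-level and per-OTU results from one framework,

together with a **Dirichlet-multinomial simulator** of matched-set count data
and a replicate-level **evaluation harness**.

## Model and statistics

Both tests are linear models with a column-centered design matrix partitioned
into ordered submodels X = (X₁, …, X_K) whose columns are made mutually
orthonormal by sequential (modified) Gram-Schmidt; the test of submodel k is
thereby adjusted for everything before it.

**Set-indicator projection.** Writing the response as
Y_ij = Ȳ_{s(i)j} + δ_ij (set mean plus within-set deviation), the statistic
X_kᵀY depends only on the δ_ij whenever the columns of X_k sum to zero within
every set — which holds exactly when X_k is orthogonal to the per-set
indicator columns. The recommended design therefore puts one indicator per
set (plus any sample-level confounders) in block 1. Set-level covariates are
linear combinations of the indicators and are automatically controlled; the
effect of anything constant within sets is inestimable by construction and is
reported as such.

**Balanced variables.** If a variable's within-set mean is the same in every
set ("balanced", e.g. one case and m controls per set), column centering alone
zeroes its within-set sums, so test results are identical with and without
the indicator block under within-set permutation. The package exploits
nothing special here — the identity falls out of the algebra — but
`check_balance` diagnoses it, and the test suite asserts the identity
bitwise on simulated balanced designs.

**PERMANOVA.** The squared distance matrix (Bray-Curtis or Hellinger on
relative abundances) is Gower-centered, Δ = −½ C (D∘D) C, and decomposed as
Δ = Y S Yᵀ with S = diag(±1); negative-eigenvalue axes of non-Euclidean
distances are retained with sign −1, not truncated. The statistic is

    F_k = tr(X_kᵀ Δ X_k) / tr(R Δ R),  R = I − Σ_k' X_k' X_k'ᵀ,

computed from the signed embedding as Σ_s S_s‖X_kᵀy_s‖² without forming Δ.
Degrees-of-freedom constants are omitted — permutation p-values are invariant
to them.

**LDM.** Y is the column-centered OTU table on the frequency scale and/or
the arcsin-root scale (variance-stabilizing for proportions, sensitive to
rarer OTUs). Per OTU j, F_kj = ‖X_kᵀy_j‖² / ‖y_j − Σ_k' X_k'X_k'ᵀ y_j‖²
with the full-model residual; the global statistic is the ratio of summed
numerators to summed residuals. The residual convention (full model vs
preceding-submodels-only) is a monotone choice that cannot change permutation
p-values under a fixed permutation stream; we fix full-model and verify the
algebraic invariants rather than chase digit equality with other
implementations.

**Omnibus.** With both scales requested, each permutation's per-scale
statistic is converted to a rank-based p-value within the shared stream; the
omnibus p-value is the permutation p-value of the minimum across scales
(standard min-p construction). With one scale it reduces to that scale's
p-value. The same construction is applied per OTU.

## Permutation scheme

Within-set permutation draws rearrange rows independently inside each set
(uniformly over the product group); exhaustive enumeration is available when
the product of set-size factorials is at most 10⁶. Random-mode p-values use
the add-one estimator p = (1 + #{perm ≥ obs})/(1 + B), valid for any B;
enumerated mode uses the exact proportion with the identity included. Draws
come from a single seeded PCG64 generator, permuted set-by-set, so results
are reproducible across platforms and identical across analysis strategies
sharing a seed.

Permutations act on the rows of the *orthonormalized* tested block
(equivalent to a Freedman-Lane residual permutation for these statistics).
In within-set mode the permuted block is re-orthogonalized against the
preceding blocks and renormalized — a no-op with respect to the set
indicators (within-set rearrangement preserves within-set zero sums) but
required when sample-level confounders are adjusted. In free mode the rows
are permuted as-is: free permutation exists in the package to demonstrate the
*naive* strategy, and permuting the already-projected trait without
re-orthogonalization is exactly the naive analysis — the permuted contrast
picks up the large between-set variance the observed (projected) contrast has
removed, which makes the free-permutation test severely conservative for
matched binary traits. Users analyzing genuinely unmatched data should
simply not supply sets (or use singleton sets) rather than use free mode.

Adaptive/sequential stopping is not implemented; B is fixed per run
(default 10,000 for global tests). Per-OTU p-value resolution is bounded by
1/(1+B); small B coarsens the Benjamini-Hochberg threshold accordingly.

**OTU discovery.** Per-OTU omnibus p-values enter Benjamini-Hochberg step-up
at the nominal FDR (default 10%). This is a deliberate, documented deviation
from permutation-plug-in FDR estimators used elsewhere; the empirical-FDR
behavior is what the evaluation harness checks.

## Simulator

The generator emulates a 16S amplicon study of matched sets:

1. Population composition π̄: synthetic normalized geometric decay with ratio
   0.985 over 856 OTUs by default — a skewed, long-tailed rank-abundance
   profile standing in for an estimated real-data composition; any
   user-supplied probability vector may replace it.
2. Set-level composition π̄_i ~ Dir(π̄, θ₁) with the mean/overdispersion
   parameterization α = mean·(1−θ)/θ. Default θ₁ = 0.02 (between-set
   heterogeneity).
3. Sample baseline π⁰_ij ~ Dir(π̄_i, θ₂), default θ₂ = 0.007 (within-set
   heterogeneity). θ₁ > θ₂ is what makes matching worthwhile.
4. Trait effect: the causal "decreased" OTUs are multiplied by (1−β); half
   the removed mass goes evenly to the "additive" receivers and half
   proportionally (to baseline frequency) to the "multiplicative" receivers;
   the final composition interpolates linearly in the trait value,
   π_ij = (1−x)π⁰_ij + xπ^trait_ij, which covers binary (x ∈ {0,1}) and
   continuous (x ∈ [0,1]) traits with one formula. "Reducing by a factor β"
   is implemented as multiplication by (1−β) so that β = 0 is the null and
   effect strength increases in β.
5. Counts ~ Multinomial(N, π) with N ~ Poisson(10,000), floored at 500 reads.

Causal mechanisms: S1 samples half of all OTUs (rounded down to an even
count) from everything but the three most abundant; S2 takes the ten most
abundant. Causal OTUs split randomly into equal decreased/increased halves,
and the increased half into additive/multiplicative receivers. Optional
set-level covariates (Bernoulli(0.5), effect 0.2), sample-level confounders
(Bernoulli(0.2 − 0.1·x), effect 0.5 — deliberately correlated with the trait)
and trait-by-covariate interactions use the same reduce/redistribute
mechanics, all-proportional, on their own OTU sets. Interaction effect size
defaults to 0.5 where enabled and is a config knob.

Randomness is split into named substreams of the master seed: causal-OTU
draws use a dedicated substream so the same causal sets are shared across
scenarios, designs and replicates; per-replicate data use independent
substreams keyed by replicate index, so harness results are independent of
execution order.

**What the simulator does not emulate:** zero-inflation beyond what the DM
hierarchy produces, sequencing error, taxonomic misassignment, phylogenetic
correlation among OTUs, and longitudinal (non-exchangeable) within-set
correlation. Passing calibration/power checks on these simulations therefore
demonstrates correctness of the inferential machinery under exchangeable
within-set sampling, not robustness to those real-data features.

## Evaluation harness

`run_calibration` / `run_power` evaluate a (scenario, method, strategy) cell
over replicates: rejection rate of the global test at α = 0.05 with binomial
standard errors, and, for OTU-level LDM runs, mean sensitivity
(TP / #truly-causal, with filtered-out causal OTUs counted as missed) and
mean false-discovery proportion (0/0 := 0) at the nominal FDR. Strategies:
`proposed` (indicators + confounders, within-set permutation), `no_set_id`,
`free_permutation`, `no_confounder`. `compare_designs` runs several set-size
layouts — including an unmatched arm that keeps one sample per simulated
pair — under shared causal draws.

Default harness scale is deliberately reduced relative to a cluster-scale
study: 200 OTUs, 1,000 replicates for calibration, 200 for power, B = 1,000
permutations. These are configuration knobs; the package's own checks use
these sizes and report Monte-Carlo uncertainty alongside every rate. Effect
sizes for the shipped power comparisons were chosen so that rejection rates
sit mid-range at this scale (a saturated arm at power 1.0 carries no ordering
information): β = 0.3 for the proposed-vs-naive contrast, β = 0.10 / 0.12 /
0.04 for the matched-vs-independent, fixed-total-90 and fixed-50-sets grids.
Because causal and covariate-associated OTU sets are drawn once per master
seed and shared across replicates (so designs are compared on identical
biology), run-level Monte-Carlo variance exceeds the binomial component in
scenarios whose covariate effects are active.

## Numerical choices

* Gram-Schmidt drop rule: a column whose post-projection norm falls below
  1e−8 × its pre-projection norm is treated as numerically zero, recorded in
  `dropped_columns`; with S sets the redundant centered indicator is always
  the last set in first-appearance order (deterministic rank handling).
* Within-set zero-sum and simplex assertions use 1e−10; orthonormality is
  verified to 1e−8; eigenvalues below 1e−8 × max|λ| are discarded.
* A permuted trait block that vanishes after re-orthogonalization contributes
  a zero statistic; a non-positive residual trace yields +inf (counted as an
  exceedance, i.e. conservatively).
* Ties in permutation p-values count as exceedances (≥).
* Interaction columns are elementwise products of the raw (pre-centering)
  variables, then centered and orthogonalized like any submodel.
* Sample-level confounders are orthonormalized after the set indicators
  inside block 1; the two orderings span the same nuisance space, so tested
  statistics are unaffected.

## Known limitations

* Only Bray-Curtis and Hellinger distances ship; phylogenetic (UniFrac-type)
  distances are out of scope.
* The LDM per-OTU machinery holds the full B × J permutation statistic
  matrix per scale in memory; at the default B = 10,000 and ~1,000 OTUs this
  is ~160 MB. Reduce B or scales for very large tables.
* Free-permutation mode is a deliberately naive reference strategy, not a
  recommended analysis (see above).
* No sequential stopping: very small p-values cost the full B permutations.
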