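# matchset

Association tests for **matched-set microbiome data**: community-level
distance-based PERMANOVA and OTU-level linear decomposition model (LDM)
tests that constrain comparisons to within matched sets, plus a
Dirichlet-multinomial simulator and an evaluation harness for calibration
and power studies.

## Why

Pre/post samples from the same participant, or cases matched to m controls,
cluster into *sets*: microbiome composition varies far more between sets than
within them. Analyzing such data as if samples were independent either leaks
between-set nuisance variance into the test (invalid p-values) or drowns the
within-set signal (needless power loss). `matchset` implements the projection
strategy for both PERMANOVA and the LDM:

* put one **indicator variable per set** in the first design block, so every
  tested contrast X_k is orthogonal to the set indicators and the statistic
  X_kᵀY depends only on within-set deviations δ_ij = Y_ij − Ȳ_{s(i)j};
* **permute trait rows only within sets**, matching the exchangeability the
  design actually supports.

Set-level confounders are automatically controlled (they lie in the indicator
span); sample-level confounders join block 1; unbalanced designs (unequal
cases:controls per set), continuous traits and interactions are all handled
by the same machinery.

## Core statistics

With orthonormalized design blocks X₁,…,X_K and R = I − Σ X_k X_kᵀ:

* **PERMANOVA**: F_k = tr(X_kᵀ Δ X_k)/tr(R Δ R) on the Gower-centered squared
  distance matrix Δ = Y S Yᵀ (signed embedding; negative eigenvalues of
  Bray-Curtis retained with S = −1).
* **LDM**: per OTU j, F_kj = ‖X_kᵀy_j‖²/‖Ry_j‖² on the centered frequency
  and/or arcsin-root-transformed OTU table; a min-p **omnibus** combines the
  scales through one shared permutation stream; per-OTU discoveries are
  declared by Benjamini-Hochberg at a nominal FDR.

## Worked example

```python
from matchset import (MatchedDesign, PermutationPlan, Submodel, filter_otus,
                      ldm_test, permanova_test, scenario_config, simulate_dataset)

# 50 matched case-control pairs, 200 OTUs, moderate effect
data = simulate_dataset(scenario_config(1, seed=7, beta=0.3, n_otus=200))
table = filter_otus(data.table, min_nonzero=5)

design = MatchedDesign(
    sample_ids=table.sample_ids,
    set_ids=data.metadata["set_id"].to_numpy(),
    submodels=[Submodel("trait", data.metadata["trait"].to_numpy())],
)
plan = PermutationPlan(mode="within_set", n_perm=2000, seed=1,
                       set_ids=design.set_ids)

perm = permanova_test(table, design, plan, distance_name="bray-curtis")
print(perm["trait"])           # {'F': 0.1213, 'p': 0.0005}

ldm = ldm_test(table, design, plan, nominal_fdr=0.10)
print(ldm.omnibus_p["trait"])  # 0.0005
print(int(ldm.detected["trait"].sum()), "OTUs detected at 10% FDR")  # 26
```

The pseudo-F of 0.1213 says the trait explains roughly 12% of the residual
distance variance within sets; its permutation p-value (0.0005, the smallest
possible at B = 2000) and the LDM omnibus p-value reject no-association at
the community level, and the per-OTU BH step flags 26 taxa driving it
(100 of the 200 OTUs are truly causal at this effect size). Rerunning with
`mode="free"` shows the naive unrestricted permutation losing the signal
entirely — the point of the matched analysis.

More narrative scripts live in `examples/` (simulation structure, PERMANOVA
vs naive permutation, OTU discovery, matched-vs-unmatched design power).
A thin CLI mirrors the library: `matchset simulate|test-permanova|test-ldm|evaluate --help`.

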