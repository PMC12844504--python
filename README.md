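# bmca-bench

Bayesian metabolic control analysis (BMCA) with a synthetic benchmarking
harness.

Metabolic control analysis asks which enzymes control the fluxes and
metabolite concentrations of a pathway. Its system-level quantities — flux
control coefficients `C^J` (rows sum to 1) and concentration control
coefficients `C^S` (rows sum to 0) — are functions of the *elasticities*
`ε(r,s) = (s/v_r) ∂v_r/∂s`, the scaled local sensitivities of each reaction
rate to each metabolite. Elasticities are rarely measurable directly. BMCA
infers them from steady-state perturbation data by combining Bayesian priors
with the linear-logarithmic rate-law approximation

```
v̂ = ê ∘ (1 + ε_x χᵀ + ε_y γᵀ)
```

where `v̂ = v/v*`, `ê = e/e*` are fluxes and enzyme activities relative to an
unperturbed reference state, and `χ = ln(x/x*)`, `γ = ln(y/y*)` are
log-relative internal and external metabolite concentrations. Posterior
draws of the elasticities are then pushed through the reduced-stoichiometry
MCA identities

```
C^S = −L̃ (N_R diag(v*) ε_x L̃)⁻¹ N_R diag(v*),    C^J = ε_x C^S + I
```

to obtain posterior control coefficients (with a `+2` correction of the raw
estimator's self-perturbation FCC entries, whose uncorrected form deviates
from the truth by exactly `−2`).

The package is aimed at people who want to know *when BMCA can be trusted*:
it ships synthetic kinetic networks with fully known ground truth, the
enzyme-perturbation protocol that generates benchmark datasets, two
independent ground-truth routes (finite differences over re-simulated steady
states, and the analytic matrix identities), ADVI and NUTS inference for the
lin-log model, and an evaluation harness that scores every data-omission arm
(fluxes / enzymes / internal metabolites / external metabolites) against the
truth — elasticity error, posterior support, control-coefficient error, and
top-k ranking fidelity of the most promising enzyme targets.

## Worked example

```python
import numpy as np, pandas as pd
from bmca_bench import (
    NetworkSpec, build_network, decompose_stoichiometry,
    generate_perturbation_dataset, normalize_dataset, solve_steady_state,
    ObservationMask, apply_omission,
    gt_elasticities, mca_from_elasticities,
    build_priors, build_linlog_model, fit_advi, hdi_point_estimates,
)
from bmca_bench.control_coefficients import posterior_control_coefficients
from bmca_bench.evaluation import rank_metrics

model = build_network(NetworkSpec("linear_branched", seed=1))
reference = solve_steady_state(model)
truth = gt_elasticities(model, reference)

dataset = normalize_dataset(generate_perturbation_dataset(model, levels=[1.5])[0])
obs = apply_omission(dataset, ObservationMask())          # all data observed
linlog = build_linlog_model(obs, build_priors(model, obs))
posterior = fit_advi(linlog, iterations=30_000, seed=7, draws=1_000)

est = pd.DataFrame(hdi_point_estimates(posterior)["eps_x"],
                   index=linlog.rxn_ids, columns=linlog.int_ids)
mask = truth.eps_x != 0
rmse = float(np.sqrt(np.mean(((est - truth.eps_x)[mask]).stack() ** 2)))
print(f"elasticity RMSE vs ground truth: {rmse:.3f}")
print("substrate elasticity of r02 (truth vs estimate):",
      f"{truth.eps_x.loc['r02', 'M01']:.3f} vs {est.loc['r02', 'M01']:.3f}")

decomp = decompose_stoichiometry(model)
cc_true = mca_from_elasticities(decomp, truth,
                                pd.Series(reference.fluxes),
                                pd.Series(reference.concentrations))
fcc = posterior_control_coefficients(posterior, obs, decomp).summary()
ranks = rank_metrics(fcc.CJ.loc["r16"], cc_true.CJ.loc["r16"], k=10)
print(f"top-10 FCC overlap for the output flux: {ranks.overlap_posterior}/10 "
      f"(Spearman {ranks.spearman_posterior:.2f})")
```

Output:

```
elasticity RMSE vs ground truth: 0.074
substrate elasticity of r02 (truth vs estimate): 0.638 vs 0.665
top-10 FCC overlap for the output flux: 10/10 (Spearman 0.99)
```

With every data type observed on this 14-metabolite / 16-reaction network,
the posterior recovers the participating elasticities to under 0.1 RMSE and
identifies all ten of the enzymes with the highest flux control over the
terminal output reaction. Omission arms behave very differently — run
`bmca_bench.evaluation.run_benchmark` (or `bmca-bench run`) to reproduce the
full five-arm comparison.

## Command line

```
bmca-bench make-model --preset branched --seed 1 --out model.xml
bmca-bench simulate --model model.xml --out-dir data/
bmca-bench ground-truth --model model.xml
bmca-bench fit --model model.xml --data data/dataset_level_1.5.csv --seed 11
bmca-bench run --config bench.yaml --out report/
```

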