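# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `bmca-bench`.

## Synthetic kinetic networks

Three presets emulate common benchmark topology classes:

* `linear_branched` — 14 metabolites (10 internal, 4 boundary), 16
  reactions: a linear trunk with several branch exits; the terminal
  reaction `r16` is the "optimized output" whose FCC row is ranked.
* `branched` — 17 metabolites (12 internal, 5 boundary), 19 reactions: two
  sources, repeated branch/convergence points, terminal output `v19`.
* `core_like` — 10 metabolites, 10 reactions: a compact
  central-metabolism-like network with an ATP/ADP conserved moiety, a
  three-step cycle with anaplerotic input and drain, and an ATPase. It
  exercises the conserved-moiety (link-matrix) code paths at desk scale.

Every reaction uses a reversible Michaelis–Menten law

```
v = e · (Vf / Π Km_s) · (Π s − Π p / Keq) / (Π(1 + s/Km_s) + Π(1 + p/Km_p) − 1)
```

optionally multiplied by Hill modifiers (`1/(1+(J/K)^n)` for inhibitors,
`(J/K)^n/(1+(J/K)^n)` for activators). The form has two properties the rest
of the package relies on: the rate vanishes exactly at chemical equilibrium
(mass-action ratio Γ = Keq), and it is linear in the enzyme multiplier `e`,
so the scaled enzyme elasticity is exactly 1 as the lin-log model assumes.

Kinetic parameters are drawn from seeded ranges (Km log-uniform on
[0.3, 3], Keq log-uniform on [8, 60], trunk Vf uniform on [1.5, 3], branch
Vf on [0.35, 0.9]; boundary sources at 2.0, sinks at 0.2). Equilibrium
constants are then calibrated iteratively (damped updates of
`Keq ← Γ*/ρ_target`) so that every reaction's reference disequilibrium
ratio `ρ = Γ/Keq` lands in a preset band — [0.08, 0.35] for
`linear_branched` (small elasticities, all within ±1.5), [0.08, 0.80] for
`branched` (elasticities up to ≈ ±7), [0.08, 0.85] for `core_like`. A draw
whose calibration fails validation (ρ stuck outside the band, or a
near-vanishing flux) is deterministically retried with a derived sub-seed,
so a `NetworkSpec` always maps to one model.

`NetworkSpec.near_equilibrium` designates reactions operated as
near-equilibrium steps: their ρ is driven to `rho_near` (default 0.9, true
substrate elasticities ≈ 1/(1−ρ) ≈ 10) and their capacity is raised 25-fold,
since a near-equilibrium enzyme is operationally a high-capacity reversible
reaction. See "Limitations" for what this regime does and does not
reproduce.

## Steady states and the perturbation protocol

`solve_steady_state` integrates the ODEs (LSODA) in stages up to t = 5·10⁴,
refining after each stage with a Newton solve (`hybr`) in log coordinates of
the independent species; conserved moieties are handled through the link
matrix `L` from the rank-revealing row reduction `N = L·N_R` (tolerance
1e-9). A state is accepted only if the relative residual `‖N_R v‖/‖v‖` is
below 1e-9. Concentrations exceeding 1e9 are treated as divergence: a
reversible network formally always has a root somewhere, but a pool running
away to astronomical values (constant influx into a saturated efflux) is a
"no steady state" failure in any meaningful sense, and is reported as such.

The perturbation protocol solves a reference state, then one state per
enzyme with that enzyme's multiplier scaled to the level, always restarting
from the pristine model. The default level grid is 10%, 20%, 30%, 40%, 50%,
150%, 300%, 500%, 700% and 1000% of wild type. Perturbations with no steady
state are excluded and recorded. Normalization divides fluxes and enzyme
multipliers by their (signed, nonzero) reference values and takes natural
logs of concentration ratios; a zero reference flux is an error naming the
reaction. An optional flag additionally perturbs each boundary metabolite
by the level factor; it is off by default, since the benchmark design uses
enzyme perturbations only.

## Ground truth

Scaled elasticities are local derivatives of the rate laws at the reference
state, computed with the 5-point backward stencil

```
f'(x) ≈ [25 f(x) − 48 f(x−h) + 36 f(x−2h) − 16 f(x−3h) + 3 f(x−4h)] / 12h
```

with relative step `h = 0.01·x` (the stencil is exact through degree 4, so
1% steps leave errors far below the comparison tolerances for these smooth
rate laws). Control coefficients come from two independent routes that are
cross-checked in the tests: the same stencil applied to re-simulated steady
states as each enzyme is perturbed, and the scaled matrix identities

```
C^S = −L̃ (N_R diag(v*) ε L̃)⁻¹ N_R diag(v*),    C^J = ε C^S + I
```

where `L̃ = diag(1/x*) L diag(x*_ind)` is the concentration-scaled link
matrix (the identity when there are no conserved moieties, in which case no
reference concentrations are needed at all — the scaling cancels). Both
routes satisfy the summation theorems (FCC rows sum to 1, CCC rows to 0) and
agree to ~1e-5 on all presets.

Disequilibrium diagnostics expose `Γ`, `ρ = Γ/Keq` and the implied
single-substrate elasticity `1/(1−ρ)`, flagged as undefined at ρ = 1.

## The probabilistic model

Observed blocks enter the likelihood; omitted blocks become latent
variables:

| quantity | prior |
|---|---|
| ε_x, species in the rate law | skew-normal, α = 5, scale 1, location shared per matrix ~ Uniform[0.1, 1.1], sign-flipped for products |
| ε_x, species absent from the rate law | Laplace(0, 0.05) sparse slab (the latent-allostery channel) |
| ε_y | Laplace, b = 0.05, same shared sign-oriented location |
| latent ê | Normal(center, 1) truncated at 0; center = applied perturbation factor (experimental design, known even when unmeasured) |
| latent χ, γ | Normal(0, 10) |
| flux likelihood | Normal(v̂ \| ê∘(1 + ε_xχᵀ + ε_yγᵀ), σ = 0.1) |

Table-level choices the source construction leaves open, decided here: the
skew-normal scale is 1; the Uniform[0.1, 1.1] location is one shared
hyperparameter per elasticity matrix; regulator metabolites of the
data-generating model are *not* given participant priors — detection of
latent allostery must come through the sparse slab, which is the point of
the allostery experiments. The reference row of every latent block is fixed
at its structural value (ê = 1, χ = γ = 0): normalization defines it, so it
is not an unknown.

When fluxes are omitted, only the reference fluxes are supplied and the
lin-log relation is read in its inverted form
`ê = v̂ ⊘ (1 + ε_xχᵀ + ε_yγᵀ)`: the unobserved flux block becomes a latent
leaf whose conditional prior is centered on the lin-log prediction. A
latent leaf with nothing downstream marginalizes out exactly, so in this
mode the elasticity posterior *equals the prior* — the structural reason
flux data are indispensable — and the package fits the prior-only model and
reports latent-flux draws ancestrally (prediction plus σ = 0.1 noise). Two
published findings fall out exactly: prior and posterior FCC rankings
coincide under flux omission, and the top-10 overlap is identical across
all perturbation levels (SD = 0).

### Parameterization for inference

Three reparameterizations shape the unconstrained space; none changes the
model, all target sampling geometry:

* ε_y participants are sampled *non-centered*, as offsets from the shared
  location. With clamped boundary metabolites, γ ≡ 0 in enzyme-perturbation
  data, so this block is prior-dominated; the centered form is a tightly
  correlated ridge (b = 0.05 around a mobile location) that mixes poorly.
* Every Laplace-prior coordinate (slabs and ε_y offsets) is sampled as a
  standard normal pushed through the Laplace quantile transform
  `ε = −sign(u)·b·(ln 2 + ln Φ(−|u|))`. The marginal prior is exactly
  Laplace, but the sampled space has no density kink at zero. Without this,
  NUTS split-chain r-hat stalled around 1.013 on slab entries; with it,
  bulk ESS is in the thousands at the default settings.
* The Uniform hyperprior locations are logit-transformed; latent ê is
  log-transformed (enforcing the truncation at 0).

### Inference engines

Both engines consume one analytic log-density-plus-gradient function
(verified against finite differences in every observation mode).

*ADVI* — mean-field Gaussian, one reparameterized sample per iteration,
Adam (rate 0.01), 30 000 iterations and 1 000 posterior draws by default;
the noisy ELBO trace is retained. Fixed seeds give bit-identical draws.

*NUTS* — multinomial No-U-Turn sampler with biased progressive sampling,
dual-averaging step size (target acceptance 0.8, 10% step-size jitter per
transition), diagonal mass adaptation in a Welford window spanning 15–75%
of warmup, and divergence flagged at energy error 1000. Chains are
initialized from a short variational pre-fit whose scales seed the mass
matrix (the usual `advi+adapt_diag` strategy). Defaults: 4 chains ×
1 000 draws after 1 000 warmup. Bulk ESS and split-chain r-hat come from
ArviZ.

Point estimates are the mean of draws inside the highest-density interval
(default mass 0.94; the source procedure does not state a mass). Posterior
support for ground truth is the natural-log Gaussian-KDE density at the
true value (Scott's rule bandwidth).

## Posterior control coefficients

Each elasticity draw is pushed through the scaled MCA identities. The raw
estimator uses the system-response term minus the direct-effect identity,
`C^J_unc = ε C^S − I`, whose self-perturbation (diagonal) entries deviate
from the truth by exactly −2; the +2 correction restores
`C^J = ε C^S + I` and is applied per draw, before summarization, guarded
against double application. Draws with a singular system matrix are skipped
and counted (an error if they exceed half). Reference fluxes are always
available for the scaling (they are supplied even in the flux-omission
mode); reference concentrations are needed only for networks with conserved
moieties.

## Evaluation harness

`run_benchmark` executes generate → normalize → fit → score for every
(variant, omission arm, level) cell: elasticity RMSE and sign agreement
(zero-truth entries count as agreeing when |estimate| < 0.05), KDE log
density of the truth, FCC/CCC RMSE, Spearman correlation and top-10 overlap
of the output reaction's FCC row for both prior and posterior (ranking by
signed value descending, ties broken by reaction id; a magnitude mode is
available behind a flag), and a Brown–Forsythe (median-centered Levene)
test of prediction variance across levels. Arms get independent seeds
derived from the master seed, shared across the levels of an arm. Stage
failures are recorded and the run continues.

Two RMSE columns are reported. With enzyme-only perturbations the boundary
metabolites never move (γ ≡ 0 in every dataset), so external elasticities
are unidentifiable in *every* arm and their error reflects the prior, not
the data; under external-metabolite omission the mean-field ELBO even has a
collapse mode (location to the 0.1 bound, ε_y → 0, paid for by the latent-γ
entropy). Arm-to-arm comparisons and the metabolite-sensitivity deltas
therefore use the internal-block RMSE (`elasticity_rmse_internal`), with
the all-entries value (`elasticity_rmse`) kept alongside.

`metabolite_sensitivity` refits with one metabolite's concentration column
latent at a time and reports the change in (internal) elasticity RMSE,
classifying each metabolite as internal linear (one consuming reaction),
internal branching (several) or external (boundary species).

## What the generator does and does not emulate

The synthetic data are exact: steady states to 1e-9, no measurement noise,
no model misspecification beyond the lin-log approximation itself. Passing
benchmarks therefore demonstrate *identifiability and algorithmic*
properties, not robustness to noise — real metabolomics/fluxomics data add
measurement error, incomplete coverage and non-steady-state artifacts that
the harness deliberately excludes. Allosteric regulation enters only the
data-generating model; the inference model is always structure-blind to it.

## Known limitations

* Elasticity capping for near-equilibrium reactions reproduces only
  partially. At the mildest perturbation (150%) estimates for reactions
  with true |ε| ≈ 7–10 sit near ±2, as reported for weak perturbations; but
  under strong knockdowns the estimates track the truth. This is structural
  in the reversible-MM family: a near-equilibrium reaction has
  v ∝ (1−ρ), so flux changes and mass-action-ratio changes are
  log-linearly tied and the secant slope of the lin-log regression equals
  the local elasticity — any perturbation that moves the reaction's flux
  identifies it. A systematic cap at ±2 across all levels would require
  kinetics in which flux and Γ decouple (or extreme perturbations that fail
  to reach steady state), which this rate-law family does not produce.
* The mean-field ADVI mean for skew-normal-prior coordinates carries a
  small systematic offset (≈ 0.1) in the no-data limit; a Gaussian factor
  cannot represent the skewed prior exactly.
* SBML round-tripping preserves values to double-precision text (≈ 15
  significant digits), so model equality after IO is numeric, not
  bit-exact. Antimony text is not supported; SBML Level 3 is the only
  serialization.
* `core_like` is a deliberately compact stand-in for a genome-scale-like
  network: it exercises conserved moieties and a cycle, not realism of
  central metabolism.
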