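"""Benchmark harness: score inferred elasticities and control coefficients.

The benchmark mirrors a five-arm omission design: for each network variant
and perturbation level, inference runs once with all data observed and once
per omitted data type (fluxes, enzymes, internal metabolites, external
metabolites).  Each arm is scored against the network's ground truth:
elasticity RMSE and sign agreement, posterior support (KDE log density at
the truth), FCC/CCC error, Spearman rank correlation of the output
reaction's FCCs, and top-k overlap of the highest-FCC enzymes, for both the
prior and the posterior.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import levene as _scipy_levene
from scipy.stats import spearmanr

from ._exceptions import ConfigurationError
from .model_factory import (
    KineticModel,
    NetworkSpec,
    RegulatorSpec,
    add_regulator,
    build_network,
    decompose_stoichiometry,
)
from .simulation import (
    DEFAULT_LEVELS,
    NormalizedDataset,
    ObservationMask,
    apply_omission,
    generate_perturbation_dataset,
    normalize_dataset,
    solve_steady_state,
)
from .ground_truth import gt_elasticities, mca_from_elasticities
from .bmca_inference import (
    build_linlog_model,
    build_priors,
    fit_advi,
    hdi_point_estimates,
    logp_ground_truth,
)
from .control_coefficients import posterior_control_coefficients

__all__ = [
    "AccuracyMetrics",
    "RankComparison",
    "BenchmarkConfig",
    "EvaluationReport",
    "accuracy_metrics",
    "rank_metrics",
    "levene_across_groups",
    "metabolite_sensitivity",
    "run_benchmark",
    "OUTPUT_REACTIONS",
]

# the reaction whose flux is "optimized" per preset: its FCC row is ranked
OUTPUT_REACTIONS = {
    "linear_branched": "r16",
    "branched": "v19",
    "core_like": "c05",
}

_ARMS = ("none", "fluxes", "enzymes", "internal_metabolites", "external_metabolites")


@dataclass(frozen=True)
class AccuracyMetrics:
    rmse: float
    sign_agreement: float
    residuals: pd.Series  # estimate - truth over the matched index


@dataclass(frozen=True)
class RankComparison:
    spearman_posterior: float
    spearman_prior: float
    overlap_posterior: int
    overlap_prior: int
    k: int


def accuracy_metrics(
    estimates: pd.Series | pd.DataFrame,
    truth: pd.Series | pd.DataFrame,
    zero_tol: float = 0.05,
) -> AccuracyMetrics:
    """RMSE and sign agreement over the matched entries.

    A zero-truth entry counts as a sign agreement iff |estimate| < zero_tol.
    """
    est = estimates.stack() if isinstance(estimates, pd.DataFrame) else estimates
    tru = truth.stack() if isinstance(truth, pd.DataFrame) else truth
    idx = est.index.intersection(tru.index)
    if len(idx) == 0:
        raise ConfigurationError("no matched entries between estimates and truth")
    e = est.loc[idx].astype(float)
    t = tru.loc[idx].astype(float)
    resid = e - t
    rmse = float(np.sqrt(np.mean(resid**2)))
    agree = np.where(
        t == 0, np.abs(e) < zero_tol, np.sign(e) == np.sign(t)
    )
    return AccuracyMetrics(
        rmse=rmse, sign_agreement=float(np.mean(agree)), residuals=resid
    )


def rank_metrics(
    predicted: pd.Series, truth: pd.Series, k: int = 10,
    predicted_prior: pd.Series | None = None,
    by_magnitude: bool = False,
) -> RankComparison:
    """Spearman correlation and top-k overlap of FCC vectors.

    Ranking is by signed value descending (``by_magnitude`` switches to
    absolute values); ties break on the reaction id, so the ranking is
    deterministic.
    """
    if k <= 0:
        raise ConfigurationError("k must be positive")
    idx = sorted(predicted.index.intersection(truth.index))
    if k > len(idx):
        raise ConfigurationError(f"k={k} exceeds the {len(idx)} shared reactions")
    pred = predicted.loc[idx]
    tru = truth.loc[idx]

    def top_set(s: pd.Series) -> set[str]:
        vals = s.abs() if by_magnitude else s
        order = sorted(idx, key=lambda r: (-vals[r], r))
        return set(order[:k])

    rho_post = float(spearmanr(pred.values, tru.values).statistic)
    overlap_post = len(top_set(pred) & top_set(tru))
    rho_prior, overlap_prior = float("nan"), -1
    if predicted_prior is not None:
        prior = predicted_prior.loc[idx]
        rho_prior = float(spearmanr(prior.values, tru.values).statistic)
        overlap_prior = len(top_set(prior) & top_set(tru))
    return RankComparison(
        spearman_posterior=rho_post,
        spearman_prior=rho_prior,
        overlap_posterior=overlap_post,
        overlap_prior=overlap_prior,
        k=k,
    )


def levene_across_groups(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Levene's test with median centering (Brown-Forsythe variant)."""
    if len(groups) < 2:
        raise ConfigurationError("Levene's test needs at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ConfigurationError("each group needs at least two values")
    res = _scipy_levene(*[np.asarray(g, dtype=float) for g in groups], center="median")
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------- #
# arm execution helpers
# --------------------------------------------------------------------------- #

def _participating_truth(model: KineticModel, eps, internal_only: bool = False) -> pd.Series:
    """Ground-truth elasticities over entries present in a rate law.

    ``internal_only`` restricts to the ε_x block.  With enzyme-only
    perturbation data the external concentrations never move (γ ≡ 0), so
    external elasticities are not identifiable in any arm and their errors
    reflect the prior, not the data; arm comparisons therefore use the
    internal block.
    """
    blocks = (eps.eps_x,) if internal_only else (eps.eps_x, eps.eps_y)
    frames = []
    for block in blocks:
        s = block.stack()
        frames.append(s[s != 0])
    return pd.concat(frames)


def _estimate_series(est: Mapping[str, np.ndarray], model_ll) -> pd.Series:
    ex = pd.DataFrame(est["eps_x"], index=model_ll.rxn_ids, columns=model_ll.int_ids)
    ey = pd.DataFrame(est["eps_y"], index=model_ll.rxn_ids, columns=model_ll.ext_ids)
    return pd.concat([ex.stack(), ey.stack()])


def _fit_one_arm(
    model: KineticModel,
    normalized: NormalizedDataset,
    mask: ObservationMask,
    seed: int,
    iterations: int,
    draws: int,
):
    """ADVI fit of one omission arm; returns (samples, model_ll, observations)."""
    obs = apply_omission(normalized, mask)
    priors = build_priors(model, obs)
    model_ll = build_linlog_model(obs, priors)
    samples = fit_advi(model_ll, iterations=iterations, seed=seed, draws=draws)
    return samples, model_ll, obs


@dataclass(frozen=True)
class BenchmarkConfig:
    """Configuration of one benchmark run (a network, its variants, the arms)."""

    network: NetworkSpec
    levels: tuple[float, ...] = DEFAULT_LEVELS
    arms: tuple[str, ...] = _ARMS
    variants: Mapping[str, tuple[tuple[str, RegulatorSpec], ...]] = field(
        default_factory=lambda: {"noReg": ()}
    )
    seed: int = 0
    advi_iterations: int = 30_000
    draws: int = 1_000
    top_k: int = 10
    output_reaction: str | None = None  # preset default when None
    rank_by_magnitude: bool = False

    def __post_init__(self) -> None:
        for arm in self.arms:
            if arm not in _ARMS:
                raise ConfigurationError(f"unknown omission arm {arm!r}")


@dataclass
class EvaluationReport:
    """All per-arm records of one benchmark run plus aggregates."""

    records: pd.DataFrame  # one row per (variant, arm, level)
    levene: pd.DataFrame  # one row per (variant, arm)
    failures: list[dict]
    config: BenchmarkConfig

    def overlap_stats(self) -> pd.DataFrame:
        """Mean and SD of top-k overlap across levels, per variant and arm."""
        g = self.records.groupby(["variant", "arm"])["overlap_posterior"]
        return g.agg(["mean", "std"]).rename(columns={"mean": "overlap_mean", "std": "overlap_sd"})

    def to_json(self) -> str:
        payload = {
            "records": self.records.to_dict(orient="records"),
            "levene": self.levene.to_dict(orient="records"),
            "failures": self.failures,
            "config": {
                "preset": self.config.network.preset,
                "seed": self.config.seed,
                "levels": list(self.config.levels),
                "arms": list(self.config.arms),
                "variants": list(self.config.variants),
                "advi_iterations": self.config.advi_iterations,
                "draws": self.config.draws,
                "top_k": self.config.top_k,
            },
        }
        return json.dumps(payload, indent=2, default=float)


def _arm_seed(master: int, variant_idx: int, arm_idx: int) -> int:
    # independent, deterministic per-arm seeds; shared across levels of an arm
    return int((master * 1_000_003 + variant_idx * 7_919 + arm_idx * 101) % (2**31 - 1))


def run_benchmark(config: BenchmarkConfig) -> EvaluationReport:
    """Execute the full generate → normalize → fit → score pipeline.

    Any stage failure marks the (variant, arm, level) record as failed and
    the run continues.  Fully reproducible under the config and its seed.
    """
    base_model = build_network(config.network)
    out_rxn = config.output_reaction or OUTPUT_REACTIONS[config.network.preset]
    rows: list[dict] = []
    failures: list[dict] = []
    levene_rows: list[dict] = []

    for v_idx, (variant, regs) in enumerate(config.variants.items()):
        model = base_model
        for rid, reg in regs:
            model = add_regulator(model, rid, reg)
        reference = solve_steady_state(model)
        eps_true = gt_elasticities(model, reference)
        decomp = decompose_stoichiometry(model)
        v_star = pd.Series(reference.fluxes).reindex(list(model.reaction_ids))
        x_star = pd.Series(reference.concentrations).reindex(list(model.internal_ids))
        cc_true = mca_from_elasticities(decomp, eps_true, v_star, x_star)
        truth_series = _participating_truth(model, eps_true)
        truth_internal = _participating_truth(model, eps_true, internal_only=True)
        fcc_truth_row = cc_true.CJ.loc[out_rxn]

        datasets = generate_perturbation_dataset(model, levels=config.levels)
        for a_idx, arm in enumerate(config.arms):
            mask = ObservationMask() if arm == "none" else ObservationMask.omit(arm)
            seed = _arm_seed(config.seed, v_idx, a_idx)
            arm_estimates: list[pd.Series] = []
            for ds in datasets:
                level = ds.level
                try:
                    normalized = normalize_dataset(ds)
                    samples, model_ll, obs = _fit_one_arm(
                        model, normalized, mask, seed,
                        config.advi_iterations, config.draws,
                    )
                    est = hdi_point_estimates(samples)
                    est_series = _estimate_series(est, model_ll)
                    acc = accuracy_metrics(est_series, truth_series)
                    acc_int = accuracy_metrics(est_series, truth_internal)
                    logp = logp_ground_truth(
                        samples, {"eps_x": eps_true.eps_x.to_numpy()}
                    )["eps_x"]
                    part_mask = eps_true.eps_x.to_numpy() != 0
                    pcc = posterior_control_coefficients(samples, obs, decomp)
                    cc_summary = pcc.summary()
                    fcc_acc = accuracy_metrics(cc_summary.CJ, cc_true.CJ)
                    ccc_acc = accuracy_metrics(cc_summary.CS, cc_true.CS)
                    prior_samples = model_ll.sample_prior(config.draws, seed=seed)
                    prior_cc = posterior_control_coefficients(
                        prior_samples, obs, decomp
                    ).summary()
                    ranks = rank_metrics(
                        cc_summary.CJ.loc[out_rxn],
                        fcc_truth_row,
                        k=config.top_k,
                        predicted_prior=prior_cc.CJ.loc[out_rxn],
                        by_magnitude=config.rank_by_magnitude,
                    )
                    rows.append(
                        {
                            "variant": variant,
                            "arm": arm,
                            "level": level,
                            "seed": seed,
                            "elasticity_rmse": acc.rmse,
                            "elasticity_rmse_internal": acc_int.rmse,
                            "sign_agreement": acc.sign_agreement,
                            "mean_abs_estimate": float(
                                est_series.loc[truth_internal.index].abs().mean()
                            ),
                            "mean_abs_truth": float(truth_internal.abs().mean()),
                            "logp_mean": float(np.mean(logp[part_mask])),
                            "logp_median": float(np.median(logp[part_mask])),
                            "fcc_rmse": fcc_acc.rmse,
                            "ccc_rmse": ccc_acc.rmse,
                            "spearman_posterior": ranks.spearman_posterior,
                            "spearman_prior": ranks.spearman_prior,
                            "overlap_posterior": ranks.overlap_posterior,
                            "overlap_prior": ranks.overlap_prior,
                            "skipped_draws": pcc.skipped_draws,
                            "excluded_experiments": len(ds.excluded),
                        }
                    )
                    arm_estimates.append(est_series)
                except Exception as exc:  # noqa: BLE001 - stage failure is a record
                    failures.append(
                        {"variant": variant, "arm": arm, "level": level, "error": str(exc)}
                    )
            if len(arm_estimates) >= 2:
                f_stat, p_val = levene_across_groups(
                    [s.to_numpy() for s in arm_estimates]
                )
                levene_rows.append(
                    {"variant": variant, "arm": arm, "F": f_stat, "p": p_val}
                )

    return EvaluationReport(
        records=pd.DataFrame(rows),
        levene=pd.DataFrame(levene_rows),
        failures=failures,
        config=config,
    )


def metabolite_sensitivity(
    model: KineticModel,
    normalized: NormalizedDataset,
    metabolites: Sequence[str] | None = None,
    seed: int = 0,
    advi_iterations: int = 30_000,
    draws: int = 1_000,
) -> pd.DataFrame:
    """Per-metabolite impact of omitting its concentration data.

    Runs a baseline (full-data) fit, then one fit per metabolite with only
    that species' concentration column latent, and reports the change in
    elasticity RMSE against ground truth.  Each metabolite is classified as
    internal linear (one consuming reaction), internal branching (several),
    or external (boundary species).
    """
    reference = solve_steady_state(model)
    eps_true = gt_elasticities(model, reference)
    truth_series = _participating_truth(model, eps_true, internal_only=True)
    decomp = decompose_stoichiometry(model)

    def consuming(sid: str) -> int:
        return sum(
            1 for r in model.reactions if sid in {sp for sp, _ in r.substrates}
        )

    def classify(sid: str) -> str:
        if model.species_spec(sid).role == "external":
            return "external"
        return "internal branching" if consuming(sid) > 1 else "internal linear"

    all_ids = list(model.internal_ids) + list(model.external_ids)
    metabolites = list(all_ids if metabolites is None else metabolites)
    for sid in metabolites:
        if sid not in all_ids:
            raise ConfigurationError(f"metabolite {sid} absent from the dataset")

    def rmse_for(mask: ObservationMask) -> float:
        samples, model_ll, _ = _fit_one_arm(
            model, normalized, mask, seed, advi_iterations, draws
        )
        est = _estimate_series(hdi_point_estimates(samples), model_ll)
        return accuracy_metrics(est, truth_series).rmse

    baseline = rmse_for(ObservationMask())
    rows = []
    for sid in metabolites:
        rmse = rmse_for(ObservationMask(species_overrides={sid: "latent"}))
        rows.append(
            {
                "metabolite": sid,
                "class": classify(sid),
                "rmse": rmse,
                "baseline_rmse": baseline,
                "delta_rmse": rmse - baseline,
            }
        )
    return pd.DataFrame(rows).set_index("metabolite")
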