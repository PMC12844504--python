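"""Steady-state solving and the enzyme-perturbation protocol.

Datasets are generated by solving the network to steady state once per
experiment: a reference (unperturbed) run plus one run per enzyme with that
enzyme's multiplier scaled to the perturbation level.  The model is rebuilt
from its pristine definition for every perturbation, so each experiment
reflects the response to a single enzyme change only.  Experiments whose
perturbed model has no steady state are excluded and the reason recorded.

The default perturbation grid is 10%, 20%, 30%, 40%, 50%, 150%, 300%, 500%,
700% and 1000% of the wild-type enzyme level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from ._exceptions import ConfigurationError, NormalizationError, SteadyStateError
from .model_factory import KineticModel, decompose_stoichiometry

__all__ = [
    "DEFAULT_LEVELS",
    "SteadyState",
    "PerturbationDataset",
    "NormalizedDataset",
    "ObservationMask",
    "ObservationSet",
    "solve_steady_state",
    "generate_perturbation_dataset",
    "normalize_dataset",
    "apply_omission",
]

DEFAULT_LEVELS: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 1.5, 3.0, 5.0, 7.0, 10.0)

_SS_RTOL = 1e-9  # relative steady-state residual tolerance


@dataclass(frozen=True)
class SteadyState:
    """One solved steady state: concentrations, clamped externals, fluxes."""

    concentrations: dict[str, float]  # internal species
    external: dict[str, float]  # clamped boundary species
    fluxes: dict[str, float]  # per reaction
    enzymes: dict[str, float]  # enzyme multipliers used, per reaction
    residual: float  # relative ||N_R v|| / ||v||


@dataclass(frozen=True)
class PerturbationDataset:
    """All experiments at one perturbation level."""

    level: float
    experiments: tuple[tuple[str, SteadyState], ...]  # ("reference" | enzyme id, state)
    excluded: tuple[tuple[str, str], ...] = ()  # (experiment, reason)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.experiments]
        if names.count("reference") != 1:
            raise ConfigurationError("dataset must contain exactly one reference row")


@dataclass(frozen=True)
class NormalizedDataset:
    """Reference-normalized dataset: v̂ = v/v*, ê = e/e*, χ = ln(x/x*), γ = ln(y/y*)."""

    level: float
    v_hat: pd.DataFrame  # experiments x reactions
    e_hat: pd.DataFrame  # experiments x reactions
    chi: pd.DataFrame  # experiments x internal species
    gamma: pd.DataFrame  # experiments x external species
    v_star: pd.Series
    e_star: pd.Series
    x_star: pd.Series
    y_star: pd.Series
    excluded: tuple[tuple[str, str], ...] = ()


_DATA_TYPES = ("fluxes", "enzymes", "internal_metabolites", "external_metabolites")


@dataclass(frozen=True)
class ObservationMask:
    """Which data blocks are observed vs latent; per-species overrides allowed."""

    fluxes: str = "observed"
    enzymes: str = "observed"
    internal_metabolites: str = "observed"
    external_metabolites: str = "observed"
    species_overrides: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in _DATA_TYPES:
            if getattr(self, name) not in ("observed", "latent"):
                raise ConfigurationError(f"mask flag {name} must be observed|latent")
        for sid, flag in self.species_overrides.items():
            if flag not in ("observed", "latent"):
                raise ConfigurationError(f"override for {sid} must be observed|latent")

    @classmethod
    def omit(cls, *data_types: str) -> "ObservationMask":
        """Mask with the named data types latent (e.g. ``omit("fluxes")``)."""
        flags = {}
        for dt in data_types:
            if dt not in _DATA_TYPES:
                raise ConfigurationError(f"unknown data type {dt!r}")
            flags[dt] = "latent"
        return cls(**flags)


@dataclass(frozen=True)
class ObservationSet:
    """Observed blocks plus descriptors of the latent blocks.

    ``mode`` is ``"v_based"`` when fluxes are observed (likelihood on v̂) and
    ``"e_based"`` when fluxes are latent, in which case only the reference
    fluxes ``v_star`` are supplied and the lin-log relation is inverted to
    predict enzyme levels.
    """

    mode: str
    experiments: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    internal_ids: tuple[str, ...]
    external_ids: tuple[str, ...]
    v_hat: pd.DataFrame | None
    e_hat: pd.DataFrame | None
    chi: pd.DataFrame  # observed columns only (may be empty)
    gamma: pd.DataFrame  # observed columns only (may be empty)
    latent_chi: tuple[str, ...]
    latent_gamma: tuple[str, ...]
    e_centers: pd.DataFrame  # prior centers from the perturbation design
    v_star: pd.Series
    e_star: pd.Series
    x_star: pd.Series | None
    y_star: pd.Series | None
    level: float


# --------------------------------------------------------------------------- #
# steady-state solver
# --------------------------------------------------------------------------- #

def solve_steady_state(
    model: KineticModel,
    t_stages: Sequence[float] = (50.0, 500.0, 5000.0, 50000.0),
    rtol: float = _SS_RTOL,
    max_conc: float = 1e9,
) -> SteadyState:
    """Integrate the ODEs toward stationarity, then refine with a Newton solve.

    The Newton refinement works in log coordinates of the independent species
    (conserved moieties handled through the link matrix), which keeps the
    iterates positive.  Raises :class:`SteadyStateError` when no steady state
    is found within the integration/iteration budget, or when concentrations
    run away beyond ``max_conc`` (a diverging pool, e.g. constant influx into
    a saturated efflux, has no biochemically meaningful steady state even if
    the reversible rate laws admit a root at astronomical concentrations).
    """
    internal = list(model.internal_ids)
    decomp = decompose_stoichiometry(model)
    nr = decomp.Nr.to_numpy(dtype=float)
    l_mat = decomp.L.to_numpy(dtype=float)
    ind_idx = [internal.index(s) for s in decomp.independent]

    x0 = np.array([model.species_spec(s).initial for s in internal], dtype=float)
    x0 = np.maximum(x0, 1e-9)
    n_full = model.stoichiometric_matrix().to_numpy(dtype=float)

    def odes(_t: float, x: np.ndarray) -> np.ndarray:
        v = model.rates(model.full_state(np.maximum(x, 0.0)))
        return n_full @ v

    def residual_rel(x: np.ndarray) -> float:
        v = model.rates(model.full_state(np.maximum(x, 0.0)))
        return float(np.linalg.norm(nr @ v) / max(np.linalg.norm(v), 1e-12))

    def refine(x: np.ndarray) -> np.ndarray | None:
        x = np.maximum(x, 1e-12)
        x_ind0 = x[ind_idx]
        offset = x - l_mat @ x_ind0

        def f(u: np.ndarray) -> np.ndarray:
            x_full = offset + l_mat @ np.exp(np.clip(u, -700.0, 60.0))
            if np.any(x_full < 0):
                x_full = np.maximum(x_full, 0.0)
            v = model.rates(model.full_state(x_full))
            return nr @ v

        sol = root(f, np.log(x_ind0), method="hybr")
        x_full = offset + l_mat @ np.exp(np.clip(sol.x, -700.0, 60.0))
        if (
            np.all(np.isfinite(x_full))
            and np.all(x_full > -1e-12)
            and np.max(x_full, initial=0.0) <= max_conc
        ):
            x_full = np.maximum(x_full, 0.0)
            if residual_rel(x_full) < rtol:
                return x_full
        return None

    x = x0
    t_prev = 0.0
    for t_end in t_stages:
        try:
            with warnings.catch_warnings():
                warnings.filterwarnings("ignore", message=".*lsoda.*")
                sol = solve_ivp(
                    odes, (t_prev, t_end), x, method="LSODA", rtol=1e-8, atol=1e-10
                )
        except (OverflowError, FloatingPointError) as exc:  # pragma: no cover
            raise SteadyStateError(f"integration failed: {exc}") from exc
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            raise SteadyStateError(f"integration failed: {sol.message}")
        x = sol.y[:, -1]
        if np.max(x, initial=0.0) > max_conc:
            raise SteadyStateError(
                f"concentrations diverged beyond {max_conc:g} at t={t_end}"
            )
        t_prev = t_end
        refined = refine(x)
        if refined is not None:
            x = refined
            break
    else:
        raise SteadyStateError(
            f"no steady state within t={t_stages[-1]}: residual "
            f"{residual_rel(x):.3g} above tolerance {rtol}"
        )

    state = model.full_state(x)
    v = model.rates(state)
    return SteadyState(
        concentrations={s: float(state[s]) for s in internal},
        external={s: float(state[s]) for s in model.external_ids},
        fluxes={r: float(val) for r, val in zip(model.reaction_ids, v)},
        enzymes={r.id: float(r.enzyme) for r in model.reactions},
        residual=residual_rel(x),
    )


# --------------------------------------------------------------------------- #
# perturbation protocol
# --------------------------------------------------------------------------- #

def generate_perturbation_dataset(
    model: KineticModel,
    levels: Sequence[float] | None = None,
    enzymes: Sequence[str] | None = None,
    perturb_external: bool = False,
) -> list[PerturbationDataset]:
    """Run the enzyme-perturbation protocol at each level.

    Per level: one reference experiment plus one per enzyme, resetting the
    model between perturbations.  Failed steady states are excluded with
    their reason.  With ``perturb_external`` set, each external metabolite is
    additionally perturbed by the same factor (rows named ``ext:<species>``).
    """
    levels = tuple(DEFAULT_LEVELS if levels is None else levels)
    if any(l <= 0 for l in levels):
        raise ConfigurationError("perturbation levels must be > 0")
    enzymes = tuple(model.reaction_ids if enzymes is None else enzymes)
    if not enzymes:
        raise ConfigurationError("empty enzyme list")
    for e in enzymes:
        model.reaction(e)  # raises on unknown id

    reference = solve_steady_state(model)
    datasets = []
    for level in levels:
        experiments: list[tuple[str, SteadyState]] = [("reference", reference)]
        excluded: list[tuple[str, str]] = []
        for e in enzymes:
            perturbed = model.with_enzyme(e, level)  # reset: pristine model each time
            try:
                experiments.append((e, solve_steady_state(perturbed)))
            except SteadyStateError as exc:
                excluded.append((e, str(exc)))
        if perturb_external:
            for sid in model.external_ids:
                base = model.species_spec(sid).initial
                perturbed = model.with_initial(sid, base * level)
                try:
                    experiments.append((f"ext:{sid}", solve_steady_state(perturbed)))
                except SteadyStateError as exc:
                    excluded.append((f"ext:{sid}", str(exc)))
        datasets.append(
            PerturbationDataset(level, tuple(experiments), tuple(excluded))
        )
    return datasets


def normalize_dataset(
    dataset: PerturbationDataset, reference: str = "reference"
) -> NormalizedDataset:
    """Normalize all experiments against the reference state (natural logs)."""
    states = dict(dataset.experiments)
    if reference not in states:
        raise ConfigurationError(f"reference experiment {reference!r} not present")
    ref = states[reference]
    for rid, vstar in ref.fluxes.items():
        if abs(vstar) < 1e-12:
            raise NormalizationError(
                f"reference flux for reaction {rid} is below 1e-12"
            )
    for sid, xstar in {**ref.concentrations, **ref.external}.items():
        if xstar <= 0:
            raise NormalizationError(
                f"reference concentration for species {sid} is not positive"
            )

    names = [n for n, _ in dataset.experiments]
    rxn_ids = list(ref.fluxes)
    int_ids = list(ref.concentrations)
    ext_ids = list(ref.external)
    v = pd.DataFrame(
        [[states[n].fluxes[r] for r in rxn_ids] for n in names],
        index=names, columns=rxn_ids,
    )
    e = pd.DataFrame(
        [[states[n].enzymes[r] for r in rxn_ids] for n in names],
        index=names, columns=rxn_ids,
    )
    x = pd.DataFrame(
        [[states[n].concentrations[s] for s in int_ids] for n in names],
        index=names, columns=int_ids,
    )
    y = pd.DataFrame(
        [[states[n].external[s] for s in ext_ids] for n in names],
        index=names, columns=ext_ids,
    )
    v_star = v.loc[reference].copy()
    e_star = e.loc[reference].copy()
    x_star = x.loc[reference].copy()
    y_star = y.loc[reference].copy()
    return NormalizedDataset(
        level=dataset.level,
        v_hat=v / v_star,
        e_hat=e / e_star,
        chi=np.log(x / x_star),
        gamma=np.log(y / y_star),
        v_star=v_star,
        e_star=e_star,
        x_star=x_star,
        y_star=y_star,
        excluded=dataset.excluded,
    )


def apply_omission(
    normalized: NormalizedDataset, mask: ObservationMask
) -> ObservationSet:
    """Split a normalized dataset into observed blocks and latent descriptors.

    When fluxes are latent only the reference fluxes are retained and the
    model mode switches to ``e_based``.  Per-species overrides turn single
    metabolite columns latent (used by the metabolite sensitivity analysis).
    """
    int_ids = tuple(normalized.chi.columns)
    ext_ids = tuple(normalized.gamma.columns)

    def species_flag(sid: str, block_flag: str) -> str:
        return mask.species_overrides.get(sid, block_flag)

    latent_chi = tuple(
        s for s in int_ids
        if species_flag(s, mask.internal_metabolites) == "latent"
    )
    latent_gamma = tuple(
        s for s in ext_ids
        if species_flag(s, mask.external_metabolites) == "latent"
    )
    flux_latent = mask.fluxes == "latent"
    enz_latent = mask.enzymes == "latent"
    return ObservationSet(
        mode="e_based" if flux_latent else "v_based",
        experiments=tuple(normalized.v_hat.index),
        reaction_ids=tuple(normalized.v_hat.columns),
        internal_ids=int_ids,
        external_ids=ext_ids,
        v_hat=None if flux_latent else normalized.v_hat,
        e_hat=None if enz_latent else normalized.e_hat,
        chi=normalized.chi.drop(columns=list(latent_chi)),
        gamma=normalized.gamma.drop(columns=list(latent_gamma)),
        latent_chi=latent_chi,
        latent_gamma=latent_gamma,
        e_centers=normalized.e_hat,  # perturbation design is known even when unmeasured
        v_star=normalized.v_star,  # reference fluxes always supplied
        e_star=normalized.e_star,
        x_star=None if mask.internal_metabolites == "latent" else normalized.x_star,
        y_star=None if mask.external_metabolites == "latent" else normalized.y_star,
        level=normalized.level,
    )
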