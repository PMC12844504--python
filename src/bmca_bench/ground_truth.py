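"""Reference elasticities, control coefficients and disequilibrium diagnostics.

Elasticities are scaled local derivatives of the rate laws at the reference
steady state, ε(r,s) = (s*/v_r*) ∂v_r/∂s.  Control coefficients come from two
independent routes that must agree: a 5-point backward finite-difference
derivative of re-simulated steady states with respect to enzyme multipliers,
and the reduced-stoichiometry matrix identities

    C^S = -L̃ (N_R diag(v*) ε L̃)^{-1} N_R diag(v*),   C^J = ε C^S + I

(all quantities scaled; L̃ is the concentration-scaled link matrix).  Both
obey the summation theorems: FCC rows sum to 1, CCC rows sum to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from ._exceptions import BmcaError, DomainError, SteadyStateError
from .model_factory import KineticModel, StoichiometryDecomposition
from .simulation import SteadyState, solve_steady_state

__all__ = [
    "ElasticityMatrix",
    "ControlCoefficientSet",
    "DisequilibriumInfo",
    "five_point_backward",
    "gt_elasticities",
    "gt_control_coefficients_fd",
    "mca_from_elasticities",
    "disequilibrium",
]


@dataclass(frozen=True)
class ElasticityMatrix:
    """Scaled elasticities split into internal (ε_x) and external (ε_y) blocks."""

    eps_x: pd.DataFrame  # reactions x internal species
    eps_y: pd.DataFrame  # reactions x external species
    reference: SteadyState


@dataclass(frozen=True)
class ControlCoefficientSet:
    """Scaled FCC (C^J) and CCC (C^S) matrices with provenance."""

    CJ: pd.DataFrame  # reactions x enzymes
    CS: pd.DataFrame  # internal species x enzymes
    provenance: str  # finite_difference | analytic | posterior
    CJ_low: pd.DataFrame | None = None  # HDI bounds, posterior provenance only
    CJ_high: pd.DataFrame | None = None
    CS_low: pd.DataFrame | None = None
    CS_high: pd.DataFrame | None = None


@dataclass(frozen=True)
class DisequilibriumInfo:
    """Mass-action ratio, disequilibrium ratio and the implied elasticity 1/(1-ρ)."""

    gamma: float
    Keq: float
    rho: float
    implied_elasticity: float | None  # None at equilibrium (rho = 1)

    @property
    def at_equilibrium(self) -> bool:
        return self.implied_elasticity is None


def five_point_backward(f: Callable[[float], float], x0: float, h: float) -> float:
    """5-point backward finite-difference first derivative, O(h^4).

    f'(x0) ≈ [25 f(x0) - 48 f(x0-h) + 36 f(x0-2h) - 16 f(x0-3h) + 3 f(x0-4h)] / (12 h)
    """
    if not h > 0:
        raise DomainError("step size h must be > 0")
    weights = (25.0, -48.0, 36.0, -16.0, 3.0)
    total = 0.0
    for k, w in enumerate(weights):
        try:
            total += w * f(x0 - k * h)
        except BmcaError as exc:
            raise type(exc)(f"stencil point {k} (x={x0 - k * h}): {exc}") from exc
    return total / (12.0 * h)


def gt_elasticities(
    model: KineticModel,
    reference: SteadyState | None = None,
    h_rel: float = 0.01,
) -> ElasticityMatrix:
    """Scaled rate-law elasticities at the reference steady state.

    Local derivatives of the rate law itself (no re-simulation), via the
    backward stencil with relative step ``h_rel``.  Entries for species not
    appearing in a rate law are exactly zero.
    """
    if reference is None:
        reference = solve_steady_state(model)
    conc = {**reference.concentrations, **reference.external}
    internal = list(model.internal_ids)
    external = list(model.external_ids)
    ex = pd.DataFrame(0.0, index=list(model.reaction_ids), columns=internal)
    ey = pd.DataFrame(0.0, index=list(model.reaction_ids), columns=external)
    for rxn in model.reactions:
        v_star = reference.fluxes[rxn.id]
        if v_star == 0:
            raise DomainError(f"reference flux of {rxn.id} is zero")
        for sid in rxn.participants():
            s_star = conc[sid]

            def rate_at(s_val: float, _sid: str = sid) -> float:
                local = dict(conc)
                local[_sid] = s_val
                return rxn.rate(local)

            deriv = five_point_backward(rate_at, s_star, h_rel * s_star)
            eps = (s_star / v_star) * deriv
            (ex if sid in ex.columns else ey).loc[rxn.id, sid] = eps
    return ElasticityMatrix(eps_x=ex, eps_y=ey, reference=reference)


def gt_control_coefficients_fd(
    model: KineticModel, h_rel: float = 0.01
) -> ControlCoefficientSet:
    """Scaled control coefficients by finite differences over steady states.

    C^J(r,k) = (e_k*/J_r*) dJ_r/de_k and C^S(s,k) = (e_k*/s*) ds/de_k, each
    derivative taken with the 5-point backward stencil on re-simulated steady
    states.  If a stencil point has no steady state, the step is halved once.
    """
    reference = solve_steady_state(model)
    rxn_ids = list(model.reaction_ids)
    int_ids = list(model.internal_ids)
    cj = pd.DataFrame(0.0, index=rxn_ids, columns=rxn_ids)
    cs = pd.DataFrame(0.0, index=int_ids, columns=rxn_ids)
    for k in rxn_ids:

        def solve_at(factor: float, _k: str = k) -> SteadyState:
            return solve_steady_state(model.with_enzyme(_k, factor))

        for h in (h_rel, h_rel / 2.0):
            try:
                states = {
                    i: solve_at(1.0 - i * h) for i in range(5)
                }
                break
            except SteadyStateError:
                if h == h_rel / 2.0:
                    raise
        weights = (25.0, -48.0, 36.0, -16.0, 3.0)
        # derivative w.r.t. the enzyme multiplier factor (e_k* = 1 in factor units)
        dj = {
            r: sum(w * states[i].fluxes[r] for i, w in enumerate(weights)) / (12.0 * h)
            for r in rxn_ids
        }
        dx = {
            s: sum(w * states[i].concentrations[s] for i, w in enumerate(weights))
            / (12.0 * h)
            for s in int_ids
        }
        for r in rxn_ids:
            cj.loc[r, k] = dj[r] / reference.fluxes[r]
        for s in int_ids:
            cs.loc[s, k] = dx[s] / reference.concentrations[s]
    return ControlCoefficientSet(CJ=cj, CS=cs, provenance="finite_difference")


def mca_from_elasticities(
    decomposition: StoichiometryDecomposition,
    elasticities: ElasticityMatrix | pd.DataFrame,
    v_star: pd.Series,
    x_star: pd.Series | None = None,
) -> ControlCoefficientSet:
    """Control coefficients from elasticities by the reduced MCA identities.

    Works directly with scaled elasticities; reference concentrations are
    only needed when the network has conserved moieties (they enter through
    the scaled link matrix).
    """
    eps = (
        elasticities.eps_x if isinstance(elasticities, ElasticityMatrix) else elasticities
    )
    cj, cs = _scaled_control_matrices(
        decomposition, eps.to_numpy(dtype=float), v_star.to_numpy(dtype=float),
        None if x_star is None else x_star.reindex(eps.columns).to_numpy(dtype=float),
    )
    rxn_ids = list(eps.index)
    return ControlCoefficientSet(
        CJ=pd.DataFrame(cj, index=rxn_ids, columns=rxn_ids),
        CS=pd.DataFrame(cs, index=list(eps.columns), columns=rxn_ids),
        provenance="analytic",
    )


def _scaled_link_matrix(
    decomposition: StoichiometryDecomposition, x_star: np.ndarray | None
) -> np.ndarray:
    """L̃ = diag(1/x*) L diag(x*_ind); identity-block structure is preserved."""
    l_mat = decomposition.L.to_numpy(dtype=float)
    if not decomposition.has_conservation:
        return l_mat
    if x_star is None:
        raise DomainError(
            "reference concentrations are required for networks with conserved moieties"
        )
    internal = list(decomposition.L.index)
    ind_idx = [internal.index(s) for s in decomposition.independent]
    return (l_mat * x_star[ind_idx][None, :]) / x_star[:, None]


def _scaled_control_matrices(
    decomposition: StoichiometryDecomposition,
    eps_scaled: np.ndarray,
    v_star: np.ndarray,
    x_star: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled (C^J, C^S) from scaled internal elasticities.

    Raises on a singular system matrix, reporting its rank deficiency.
    """
    nr = decomposition.Nr.to_numpy(dtype=float)
    # order N_R columns to match eps rows is guaranteed by construction
    lt = _scaled_link_matrix(decomposition, x_star)
    nv = nr * v_star[None, :]  # N_R diag(v*)
    m = nv @ eps_scaled @ lt
    rank = np.linalg.matrix_rank(m)
    if rank < m.shape[0]:
        raise DomainError(
            f"singular MCA system matrix: rank {rank} < {m.shape[0]}"
        )
    cs = -lt @ np.linalg.solve(m, nv)
    cj = eps_scaled @ cs + np.eye(eps_scaled.shape[0])
    return cj, cs


def disequilibrium(
    model: KineticModel, reaction_id: str, state: dict[str, float] | SteadyState
) -> DisequilibriumInfo:
    """Mass-action ratio Γ, disequilibrium ratio ρ = Γ/Keq, implied ε = 1/(1-ρ)."""
    if isinstance(state, SteadyState):
        conc = {**state.concentrations, **state.external}
    else:
        conc = dict(state)
    rxn = model.reaction(reaction_id)
    gamma = rxn.mass_action_ratio(conc)
    rho = gamma / rxn.Keq
    implied = None if abs(rho - 1.0) < 1e-12 else 1.0 / (1.0 - rho)
    return DisequilibriumInfo(
        gamma=gamma, Keq=rxn.Keq, rho=rho, implied_elasticity=implied
    )
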