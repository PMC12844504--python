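"""Posterior control coefficients from elasticity draws.

Each posterior draw of the scaled elasticities is pushed through the reduced
MCA identities.  The raw posterior estimator uses the system-response term
*minus* the direct-effect identity, C^J_unc = ε C^S - I, whose diagonal
(self-perturbation) entries deviate from the ground truth by exactly -2; the
``+2`` self-perturbation correction restores the standard C^J = ε C^S + I.
The correction is applied per draw, before summarization, and exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError, DomainError
from .ground_truth import ControlCoefficientSet, _scaled_control_matrices
from .model_factory import StoichiometryDecomposition
from .bmca_inference import PosteriorSamples, _hdi_interval
from .simulation import ObservationSet

__all__ = [
    "PosteriorControlCoefficients",
    "posterior_control_coefficients",
    "self_fcc_correction",
]


@dataclass
class PosteriorControlCoefficients:
    """Per-draw FCC/CCC matrices plus HDI summaries."""

    cj_draws: np.ndarray  # (draws, reactions, enzymes)
    cs_draws: np.ndarray  # (draws, internal species, enzymes)
    reaction_ids: list[str]
    species_ids: list[str]
    corrected: bool
    skipped_draws: int
    hdi_mass: float = 0.94

    def summary(self) -> ControlCoefficientSet:
        """Median and HDI bounds across draws."""
        cj_med = np.median(self.cj_draws, axis=0)
        cs_med = np.median(self.cs_draws, axis=0)

        def hdi_bounds(draws: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            lo = np.empty(draws.shape[1:])
            hi = np.empty(draws.shape[1:])
            for idx in np.ndindex(*draws.shape[1:]):
                lo[idx], hi[idx] = _hdi_interval(draws[(slice(None), *idx)], self.hdi_mass)
            return lo, hi

        cj_lo, cj_hi = hdi_bounds(self.cj_draws)
        cs_lo, cs_hi = hdi_bounds(self.cs_draws)
        r, s = self.reaction_ids, self.species_ids
        return ControlCoefficientSet(
            CJ=pd.DataFrame(cj_med, index=r, columns=r),
            CS=pd.DataFrame(cs_med, index=s, columns=r),
            provenance="posterior",
            CJ_low=pd.DataFrame(cj_lo, index=r, columns=r),
            CJ_high=pd.DataFrame(cj_hi, index=r, columns=r),
            CS_low=pd.DataFrame(cs_lo, index=s, columns=r),
            CS_high=pd.DataFrame(cs_hi, index=s, columns=r),
        )


def self_fcc_correction(
    cj_uncorrected: np.ndarray | pd.DataFrame,
    already_corrected: bool = False,
) -> np.ndarray | pd.DataFrame:
    """Add +2 to each self-perturbation (diagonal) FCC entry.

    One enzyme per reaction, so the reaction-to-enzyme mapping is the
    diagonal; a non-square matrix means that mapping is undefined.  Guards
    against double application via the ``already_corrected`` flag.
    """
    if already_corrected:
        raise ConfigurationError("self-FCC correction already applied")
    arr = cj_uncorrected.to_numpy() if isinstance(cj_uncorrected, pd.DataFrame) else cj_uncorrected
    if arr.shape[-1] != arr.shape[-2]:
        raise DomainError(
            "reaction-to-enzyme mapping undefined for non-square FCC matrix"
        )
    eye = 2.0 * np.eye(arr.shape[-1])
    out = arr + eye
    if isinstance(cj_uncorrected, pd.DataFrame):
        return pd.DataFrame(out, index=cj_uncorrected.index, columns=cj_uncorrected.columns)
    return out


def posterior_control_coefficients(
    samples: PosteriorSamples,
    observations: ObservationSet,
    decomposition: StoichiometryDecomposition,
    apply_correction: bool = True,
    max_draws: int | None = None,
    hdi_mass: float = 0.94,
) -> PosteriorControlCoefficients:
    """Transform elasticity draws into FCC/CCC posterior distributions.

    Reference fluxes are always available (supplied even when flux data are
    omitted); reference concentrations are only needed for networks with
    conserved moieties.  Draws with a singular system matrix are skipped and
    counted; more than half singular is an error.
    """
    eps_draws = samples.flat("eps_x")
    if max_draws is not None and eps_draws.shape[0] > max_draws:
        eps_draws = eps_draws[:: eps_draws.shape[0] // max_draws + 1]
    v_star = observations.v_star.reindex(list(observations.reaction_ids)).to_numpy(
        dtype=float
    )
    x_star = None
    if observations.x_star is not None:
        x_star = observations.x_star.reindex(
            list(observations.internal_ids)
        ).to_numpy(dtype=float)
    if decomposition.has_conservation and x_star is None:
        raise DomainError(
            "reference concentrations are required for networks with conserved moieties"
        )

    n_draws = eps_draws.shape[0]
    r_count = len(observations.reaction_ids)
    s_count = len(observations.internal_ids)
    cj_out = np.empty((n_draws, r_count, r_count))
    cs_out = np.empty((n_draws, s_count, r_count))
    skipped = 0
    kept = 0
    eye = np.eye(r_count)
    for d in range(n_draws):
        try:
            cj_plus, cs = _scaled_control_matrices(
                decomposition, eps_draws[d], v_star, x_star
            )
        except DomainError:
            skipped += 1
            continue
        # raw estimator: system response minus the direct-effect identity
        cj_unc = (cj_plus - eye) - eye
        cj = self_fcc_correction(cj_unc) if apply_correction else cj_unc
        cj_out[kept] = cj
        cs_out[kept] = cs
        kept += 1
    if kept < n_draws / 2:
        raise DomainError(
            f"singular MCA system in {skipped}/{n_draws} posterior draws"
        )
    return PosteriorControlCoefficients(
        cj_draws=cj_out[:kept],
        cs_draws=cs_out[:kept],
        reaction_ids=list(observations.reaction_ids),
        species_ids=list(observations.internal_ids),
        corrected=apply_correction,
        skipped_draws=skipped,
        hdi_mass=hdi_mass,
    )
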