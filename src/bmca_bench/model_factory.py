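"""Synthetic kinetic networks for benchmarking Bayesian metabolic control analysis.

The networks emulate the three benchmark topology classes used throughout the
package: a linear chain with branch points (``linear_branched``, 14 metabolites /
16 reactions), a more heavily branched network (``branched``, 17 metabolites /
19 reactions), and a compact central-metabolism-like network with a cycle and a
conserved cofactor pair (``core_like``).

Every reaction carries a reversible Michaelis–Menten rate law

    v = e * (Vf / prod Km_s) * (prod s - prod p / Keq) / D * prod(modifiers)

with ``D = prod(1 + s/Km_s) + prod(1 + p/Km_p) - 1``, multiplied by optional
Hill-type allosteric modifiers.  The rate is exactly linear in the enzyme
multiplier ``e`` (scaled enzyme elasticity 1, as the lin-log form assumes) and
vanishes exactly at chemical equilibrium (mass-action ratio equal to Keq).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import (
    ConfigurationError,
    DomainError,
    ModelLookupError,
    ModelParseError,
)

__all__ = [
    "RegulatorSpec",
    "ReactionSpec",
    "SpeciesSpec",
    "KineticModel",
    "NetworkSpec",
    "StoichiometryDecomposition",
    "build_network",
    "add_regulator",
    "calibrate_regulator",
    "reaction_rate",
    "decompose_stoichiometry",
    "tune_disequilibrium",
    "write_sbml",
    "read_sbml",
    "model_io",
    "DEFAULT_COUNTS",
]


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class RegulatorSpec:
    """Allosteric regulator attached multiplicatively to one reaction.

    ``inhibitor`` contributes ``1 / (1 + (J/K)^n)`` and ``activator``
    ``(J/K)^n / (1 + (J/K)^n)``, where ``J`` is the regulator concentration.
    """

    metabolite: str
    mode: str  # "inhibitor" | "activator"
    K: float
    n: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("inhibitor", "activator"):
            raise ConfigurationError(f"unknown regulator mode {self.mode!r}")
        if not (self.K > 0):
            raise ConfigurationError("regulator half-saturation K must be > 0")
        if not (math.isfinite(self.n) and self.n >= 1):
            raise ConfigurationError("Hill coefficient n must be finite and >= 1")

    def factor(self, conc: float) -> float:
        if conc < 0:
            raise DomainError(f"negative concentration for regulator {self.metabolite}")
        h = (conc / self.K) ** self.n
        return h / (1.0 + h) if self.mode == "activator" else 1.0 / (1.0 + h)

    def log_gradient(self, conc: float) -> float:
        """d ln(factor) / d ln(conc); -n/2 for an inhibitor at half-saturation."""
        h = (conc / self.K) ** self.n
        return self.n / (1.0 + h) if self.mode == "activator" else -self.n * h / (1.0 + h)


@dataclass(frozen=True)
class SpeciesSpec:
    id: str
    role: str  # "internal" | "external"
    initial: float = 1.0

    def __post_init__(self) -> None:
        if self.role not in ("internal", "external"):
            raise ConfigurationError(f"unknown species role {self.role!r}")
        if self.initial < 0:
            raise ConfigurationError(f"negative initial concentration for {self.id}")


@dataclass(frozen=True)
class ReactionSpec:
    """One enzyme-catalysed reversible reaction.

    ``substrates``/``products`` are (species id, stoichiometry) pairs; ``Km``
    maps every reactant id to its half-saturation constant.
    """

    id: str
    substrates: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    Vf: float
    Km: Mapping[str, float]
    Keq: float
    enzyme: float = 1.0
    modifiers: tuple[RegulatorSpec, ...] = ()

    def __post_init__(self) -> None:
        if not (self.Keq > 0):
            raise ConfigurationError(f"{self.id}: Keq must be > 0")
        if any(k <= 0 for k in self.Km.values()):
            raise ConfigurationError(f"{self.id}: all Km must be > 0")
        if self.enzyme < 0:
            raise ConfigurationError(f"{self.id}: enzyme multiplier must be >= 0")
        for sp, _ in (*self.substrates, *self.products):
            if sp not in self.Km:
                raise ConfigurationError(f"{self.id}: missing Km for reactant {sp}")

    @property
    def reactants(self) -> tuple[str, ...]:
        return tuple(sp for sp, _ in (*self.substrates, *self.products))

    def participants(self) -> dict[str, str]:
        """Map species id -> role in this rate law (substrate/product/modifier)."""
        roles: dict[str, str] = {}
        for sp, _ in self.substrates:
            roles[sp] = "substrate"
        for sp, _ in self.products:
            roles[sp] = "product"
        for m in self.modifiers:
            roles.setdefault(m.metabolite, "modifier")
        return roles

    def rate(self, conc: Mapping[str, float]) -> float:
        """Evaluate the rate law at the given concentrations."""
        num_s, num_p = 1.0, 1.0
        den_s, den_p = 1.0, 1.0
        for sp, st in self.substrates:
            c = conc[sp]
            if c < 0:
                raise DomainError(f"negative concentration for {sp}")
            num_s *= c ** st
            den_s *= (1.0 + c / self.Km[sp]) ** st
        for sp, st in self.products:
            c = conc[sp]
            if c < 0:
                raise DomainError(f"negative concentration for {sp}")
            num_p *= c ** st
            den_p *= (1.0 + c / self.Km[sp]) ** st
        kms = 1.0
        for sp, st in self.substrates:
            kms *= self.Km[sp] ** st
        v = self.enzyme * (self.Vf / kms) * (num_s - num_p / self.Keq)
        v /= den_s + den_p - 1.0
        for mod in self.modifiers:
            v *= mod.factor(conc[mod.metabolite])
        return v

    def mass_action_ratio(self, conc: Mapping[str, float]) -> float:
        """Gamma = prod(products^st) / prod(substrates^st)."""
        num, den = 1.0, 1.0
        for sp, st in self.products:
            num *= conc[sp] ** st
        for sp, st in self.substrates:
            c = conc[sp]
            if c <= 0:
                raise DomainError(f"zero or negative substrate concentration for {sp}")
            den *= c ** st
        return num / den


@dataclass(frozen=True)
class KineticModel:
    """A kinetic network: species, reactions, and derived stoichiometry."""

    species: tuple[SpeciesSpec, ...]
    reactions: tuple[ReactionSpec, ...]
    name: str = "model"

    def __post_init__(self) -> None:
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate species ids")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise ConfigurationError("duplicate reaction ids")
        declared = set(ids)
        for r in self.reactions:
            for sp in r.participants():
                if sp not in declared:
                    raise ModelLookupError(
                        f"reaction {r.id} references undeclared species {sp}"
                    )

    # -- structure ---------------------------------------------------------- #

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.species)

    @property
    def internal_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.species if s.role == "internal")

    @property
    def external_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.species if s.role == "external")

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.reactions)

    def species_spec(self, sid: str) -> SpeciesSpec:
        for s in self.species:
            if s.id == sid:
                return s
        raise ModelLookupError(f"unknown species {sid}")

    def reaction(self, rid: str) -> ReactionSpec:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise ModelLookupError(f"unknown reaction {rid}")

    def stoichiometric_matrix(self) -> pd.DataFrame:
        """N: internal species x reactions, integer entries."""
        internal = self.internal_ids
        n = pd.DataFrame(
            0, index=list(internal), columns=list(self.reaction_ids), dtype=int
        )
        iset = set(internal)
        for r in self.reactions:
            for sp, st in r.substrates:
                if sp in iset:
                    n.loc[sp, r.id] -= st
            for sp, st in r.products:
                if sp in iset:
                    n.loc[sp, r.id] += st
        return n

    # -- evaluation --------------------------------------------------------- #

    def full_state(self, internal: Sequence[float]) -> dict[str, float]:
        """Concentration mapping from an internal-species vector plus clamps."""
        state = {s.id: s.initial for s in self.species if s.role == "external"}
        state.update(dict(zip(self.internal_ids, internal)))
        return state

    def rates(self, conc: Mapping[str, float]) -> np.ndarray:
        return np.array([r.rate(conc) for r in self.reactions])

    def reference_concentrations(self) -> dict[str, float]:
        return {s.id: s.initial for s in self.species}

    # -- functional updates -------------------------------------------------- #

    def with_enzyme(self, rid: str, factor: float) -> "KineticModel":
        """Return a copy with reaction ``rid``'s enzyme multiplier scaled."""
        rxn = self.reaction(rid)
        new = replace(rxn, enzyme=rxn.enzyme * factor)
        return replace(
            self, reactions=tuple(new if r.id == rid else r for r in self.reactions)
        )

    def equals(self, other: "KineticModel", rtol: float = 1e-12) -> bool:
        """Structural equality with numeric tolerance (serialization loses ulps)."""
        if self.species != other.species:
            return False
        if len(self.reactions) != len(other.reactions):
            return False

        def close(a: float, b: float) -> bool:
            return math.isclose(a, b, rel_tol=rtol, abs_tol=rtol)

        for a, b in zip(self.reactions, other.reactions):
            if (a.id, a.substrates, a.products) != (b.id, b.substrates, b.products):
                return False
            if not (close(a.Vf, b.Vf) and close(a.Keq, b.Keq) and close(a.enzyme, b.enzyme)):
                return False
            if set(a.Km) != set(b.Km) or any(not close(a.Km[k], b.Km[k]) for k in a.Km):
                return False
            if len(a.modifiers) != len(b.modifiers):
                return False
            for ma, mb in zip(a.modifiers, b.modifiers):
                if (ma.metabolite, ma.mode) != (mb.metabolite, mb.mode):
                    return False
                if not (close(ma.K, mb.K) and close(ma.n, mb.n)):
                    return False
        return True

    def with_initial(self, sid: str, value: float) -> "KineticModel":
        sp = self.species_spec(sid)
        new = replace(sp, initial=value)
        return replace(
            self, species=tuple(new if s.id == sid else s for s in self.species)
        )


@dataclass(frozen=True)
class NetworkSpec:
    """Configuration for a synthetic network preset.

    ``near_equilibrium`` names reactions operated as near-equilibrium steps:
    their reference disequilibrium ratio is pushed toward ``rho_near`` (large
    true substrate elasticities) and their capacity is raised by
    ``near_equilibrium_capacity`` so that, like fast reversible enzymes in
    vivo, they re-equilibrate under perturbations (the substrate/product
    log-ratio stays pinned, buffering the observable response).
    """

    preset: str
    counts: tuple[int, int] | None = None  # (metabolites, reactions)
    seed: int = 0
    rho_band: tuple[float, float] | None = None
    near_equilibrium: tuple[str, ...] = ()
    rho_near: float = 0.9
    near_equilibrium_capacity: float = 25.0  # Vf multiplier for those reactions

    def __post_init__(self) -> None:
        if self.preset not in DEFAULT_COUNTS:
            raise ConfigurationError(f"unknown preset {self.preset!r}")
        if self.counts is not None and self.counts != DEFAULT_COUNTS[self.preset]:
            raise ConfigurationError(
                f"preset {self.preset} has fixed counts {DEFAULT_COUNTS[self.preset]},"
                f" got {self.counts}"
            )
        if not (0 < self.rho_near < 1):
            raise ConfigurationError("rho_near must lie in (0, 1)")


@dataclass(frozen=True)
class StoichiometryDecomposition:
    """Reduced stoichiometry: N = L @ N_R, plus conserved-moiety structure."""

    independent: tuple[str, ...]
    dependent: tuple[str, ...]
    Nr: pd.DataFrame  # independent species x reactions
    L: pd.DataFrame  # all internal species x independent species
    conservation: pd.DataFrame  # conserved relations x internal species
    totals: np.ndarray  # conserved totals at the model's initial state

    @property
    def has_conservation(self) -> bool:
        return len(self.dependent) > 0


# --------------------------------------------------------------------------- #
# operations
# --------------------------------------------------------------------------- #

DEFAULT_COUNTS: dict[str, tuple[int, int]] = {
    "linear_branched": (14, 16),
    "branched": (17, 19),
    "core_like": (10, 10),
}

_RHO_BANDS: dict[str, tuple[float, float]] = {
    "linear_branched": (0.08, 0.35),
    "branched": (0.08, 0.80),
    "core_like": (0.08, 0.85),
}


def _linear_branched_edges() -> tuple[list[SpeciesSpec], list[tuple[str, str, str]]]:
    """Linear chain with branch exits; 14 metabolites (10 internal), 16 reactions."""
    ext = [
        SpeciesSpec("X0", "external", 2.0),
        SpeciesSpec("X1", "external", 0.2),
        SpeciesSpec("X2", "external", 0.2),
        SpeciesSpec("X3", "external", 0.2),
    ]
    internal = [SpeciesSpec(f"M{i:02d}", "internal", 1.0) for i in range(1, 11)]
    edges = [
        ("r01", "X0", "M01"),
        ("r02", "M01", "M02"),
        ("r03", "M02", "M03"),
        ("r04", "M03", "M04"),
        ("r05", "M03", "X1"),
        ("r06", "M04", "M05"),
        ("r07", "M05", "M06"),
        ("r08", "M05", "X2"),
        ("r09", "M06", "M07"),
        ("r10", "M07", "M08"),
        ("r11", "M07", "X1"),
        ("r12", "M08", "M09"),
        ("r13", "M09", "M10"),
        ("r14", "M09", "X2"),
        ("r15", "M02", "X1"),
        ("r16", "M10", "X3"),  # terminal output reaction
    ]
    return ext + internal, edges


def _branched_edges() -> tuple[list[SpeciesSpec], list[tuple[str, str, str]]]:
    """Two sources, three sinks, repeated branch/convergence; 17 metabolites, 19 reactions."""
    ext = [
        SpeciesSpec("Y0", "external", 2.0),
        SpeciesSpec("Y1", "external", 1.5),
        SpeciesSpec("Z1", "external", 0.2),
        SpeciesSpec("Z2", "external", 0.2),
        SpeciesSpec("Z3", "external", 0.2),
    ]
    internal = [SpeciesSpec(f"B{i:02d}", "internal", 1.0) for i in range(1, 13)]
    edges = [
        ("v01", "Y0", "B01"),
        ("v02", "B01", "B02"),
        ("v03", "B02", "B03"),
        ("v04", "B02", "B04"),
        ("v05", "B03", "B05"),
        ("v06", "B04", "B06"),
        ("v07", "Y1", "B04"),
        ("v08", "B05", "B07"),
        ("v09", "B05", "B08"),
        ("v10", "B06", "B08"),
        ("v11", "B07", "B09"),
        ("v12", "B08", "B10"),
        ("v13", "B09", "B11"),
        ("v14", "B09", "Z1"),
        ("v15", "B10", "B12"),
        ("v16", "B10", "Z2"),
        ("v17", "B11", "B12"),
        ("v18", "B11", "Z1"),
        ("v19", "B12", "Z3"),  # terminal output reaction
    ]
    return ext + internal, edges


# main-trunk reactions get larger Vf so branch exits stay minor drains
_TRUNK = {
    "linear_branched": {
        "r01", "r02", "r03", "r04", "r06", "r07", "r09", "r10", "r12", "r13", "r16",
    },
    "branched": {
        "v01", "v02", "v03", "v04", "v05", "v06", "v07", "v08", "v09", "v10",
        "v11", "v12", "v13", "v15", "v17", "v19",
    },
}


def _core_like_model(rng: np.random.Generator) -> KineticModel:
    """Compact network with one conserved cofactor pair and a cycle.

    Scaled-down analogue of a central-metabolism topology: a kinase step
    consuming ATP, an ATP-regenerating step, and a three-step cycle that
    condenses with the linear branch and releases product to the boundary.
    """
    species = [
        SpeciesSpec("Cin", "external", 2.0),
        SpeciesSpec("Cout", "external", 0.2),
        *[SpeciesSpec(f"S{i}", "internal", 1.0) for i in range(1, 7)],
        SpeciesSpec("ATP", "internal", 1.5),
        SpeciesSpec("ADP", "internal", 0.5),
    ]
    # c03 yields 2 ATP so the ATPase c09 carries net flux; the anaplerotic
    # input c08 is paired with the cycle drain c10 so both carry net flux.
    # Only the ATP/ADP moiety remains conserved.
    stoich = [
        ("c01", [("Cin", 1), ("ATP", 1)], [("S1", 1), ("ADP", 1)]),
        ("c02", [("S1", 1)], [("S2", 1)]),
        ("c03", [("S2", 1), ("ADP", 2)], [("S3", 1), ("ATP", 2)]),
        ("c04", [("S3", 1), ("S6", 1)], [("S4", 1)]),
        ("c05", [("S4", 1)], [("S5", 1), ("Cout", 1)]),
        ("c06", [("S5", 1)], [("S6", 1), ("Cout", 1)]),
        ("c07", [("S3", 1)], [("Cout", 1)]),
        ("c08", [("S3", 1)], [("S6", 1)]),
        ("c09", [("ATP", 1)], [("ADP", 1)]),
        ("c10", [("S5", 1)], [("Cout", 1)]),
    ]
    minor = {"c07", "c08", "c10"}
    reactions = []
    for rid, subs, prods in stoich:
        parts = [sp for sp, _ in subs + prods]
        km = {sp: float(np.exp(rng.uniform(np.log(0.3), np.log(3.0)))) for sp in parts}
        keq = float(np.exp(rng.uniform(np.log(8.0), np.log(60.0))))
        vf = float(rng.uniform(0.3, 0.8)) if rid in minor else float(rng.uniform(1.5, 3.0))
        reactions.append(
            ReactionSpec(rid, tuple(subs), tuple(prods), Vf=vf, Km=km, Keq=keq)
        )
    return KineticModel(tuple(species), tuple(reactions), name="core_like")


def _chain_model(preset: str, rng: np.random.Generator) -> KineticModel:
    species, edges = (
        _linear_branched_edges() if preset == "linear_branched" else _branched_edges()
    )
    trunk = _TRUNK[preset]
    reactions = []
    for rid, sub, prod in edges:
        km = {
            sp: float(np.exp(rng.uniform(np.log(0.3), np.log(3.0))))
            for sp in (sub, prod)
        }
        keq = float(np.exp(rng.uniform(np.log(8.0), np.log(60.0))))
        vf = (
            float(rng.uniform(1.5, 3.0))
            if rid in trunk
            else float(rng.uniform(0.35, 0.9))
        )
        reactions.append(
            ReactionSpec(rid, ((sub, 1),), ((prod, 1),), Vf=vf, Km=km, Keq=keq)
        )
    return KineticModel(tuple(species), tuple(reactions), name=preset)


def build_network(spec: NetworkSpec) -> KineticModel:
    """Construct a preset network with seeded kinetic parameters.

    After drawing parameters, equilibrium constants are calibrated so every
    reaction's reference-state disequilibrium ratio falls in the preset's
    target band (net-forward flux, away from equilibrium), and reactions
    listed in ``spec.near_equilibrium`` are pushed toward ``spec.rho_near``.
    Deterministic under ``spec.seed``: the seed fixes the parameter draw, and
    a draw whose calibrated model fails validation (a disequilibrium ratio
    stuck outside the band, or a near-vanishing flux) is retried with a
    deterministic sub-seed, so the same spec always yields the same model.
    """
    from .simulation import solve_steady_state  # deferred: avoids module cycle

    lo, hi = spec.rho_band if spec.rho_band is not None else _RHO_BANDS[spec.preset]
    pinned = set(spec.near_equilibrium)
    last_err = "no attempt"
    for attempt in range(4):
        rng = np.random.default_rng(spec.seed + 99991 * attempt)
        if spec.preset == "core_like":
            model = _core_like_model(rng)
        else:
            model = _chain_model(spec.preset, rng)
        targets = {
            rid: float(rng.uniform(lo + 0.02, hi - 0.02)) for rid in model.reaction_ids
        }
        for rid in spec.near_equilibrium:
            rxn = model.reaction(rid)  # raises on unknown id
            targets[rid] = spec.rho_near
            # high capacity: the reaction re-equilibrates under perturbations
            model = replace(
                model,
                reactions=tuple(
                    replace(r, Vf=r.Vf * spec.near_equilibrium_capacity)
                    if r.id == rid
                    else r
                    for r in model.reactions
                ),
            )
        try:
            model = tune_disequilibrium(model, targets, band=(lo, hi), pinned=pinned)
            ss = solve_steady_state(model)
        except Exception as exc:  # retry with the next deterministic draw
            last_err = str(exc)
            continue
        conc = {**ss.concentrations, **ss.external}
        rho = {r.id: r.mass_action_ratio(conc) / r.Keq for r in model.reactions}
        flux = np.abs(np.array(list(ss.fluxes.values())))
        ok = all(
            abs(math.log(rho[rid] / spec.rho_near)) < 0.15
            if rid in pinned
            else 0.5 * lo <= rho[rid] <= hi + 0.05
            for rid in model.reaction_ids
        ) and flux.min() > 1e-3 * np.median(flux)
        if ok:
            break
        last_err = f"calibration left rho values {rho} outside [{lo}, {hi}]"
    else:
        raise ConfigurationError(
            f"could not calibrate preset {spec.preset} with seed {spec.seed}: {last_err}"
        )
    n_sp, n_rx = len(model.species), len(model.reactions)
    if (n_sp, n_rx) != DEFAULT_COUNTS[spec.preset]:  # pragma: no cover - guard
        raise ConfigurationError(
            f"preset {spec.preset} produced {(n_sp, n_rx)}, "
            f"expected {DEFAULT_COUNTS[spec.preset]}"
        )
    return model


def tune_disequilibrium(
    model: KineticModel,
    targets: Mapping[str, float],
    band: tuple[float, float] | None = None,
    pinned: set[str] | None = None,
    max_iter: int = 25,
) -> KineticModel:
    """Set Keq per reaction so the reference steady state hits target rho values.

    Iterates: solve the steady state, then move ``Keq`` toward
    ``Gamma*/rho_target`` with damping (the steady state shifts as Keq
    changes, so an undamped update can overshoot past equilibrium).
    ``pinned`` reactions are driven to their target within 5% in log space;
    others are accepted anywhere inside ``band``.
    """
    from .simulation import solve_steady_state  # deferred: avoids module cycle

    pinned = pinned or set()
    for it in range(max_iter):
        ss = solve_steady_state(model)
        conc = {**ss.concentrations, **ss.external}
        new_reactions = []
        changed = False
        for r in model.reactions:
            tgt = targets.get(r.id)
            if tgt is None:
                new_reactions.append(r)
                continue
            gamma = r.mass_action_ratio(conc)
            rho = gamma / r.Keq
            ok = (
                rho > 0 and abs(math.log(rho / tgt)) < 0.05
                if r.id in pinned
                else (band is not None and band[0] <= rho <= band[1])
            )
            if ok and it > 0:
                new_reactions.append(r)
            else:
                step = 1.0 if it == 0 else 0.6  # full first step, damped after
                keq_new = r.Keq * (gamma / (r.Keq * tgt)) ** step
                new_reactions.append(replace(r, Keq=keq_new))
                changed = True
        model = replace(model, reactions=tuple(new_reactions))
        if not changed and it > 0:
            break
    return model


def calibrate_regulator(
    model: KineticModel,
    reaction_id: str,
    metabolite: str,
    n: float,
    mode: str = "inhibitor",
    saturation: float = 0.65,
    iterations: int = 4,
) -> KineticModel:
    """Attach a Hill regulator whose reference-state elasticity is controlled.

    Sets the half-saturation K so the regulator sits at fractional saturation
    ``h/(1+h) = saturation`` at the resulting reference steady state (the
    state shifts when the regulator is added, so K is re-tuned iteratively).
    For an inhibitor the scaled elasticity is then ``-n * saturation``; e.g.
    n = 4 at saturation 0.65 gives an allosteric elasticity of -2.6.
    """
    from .simulation import solve_steady_state  # deferred: avoids module cycle

    if not (0 < saturation < 1):
        raise ConfigurationError("saturation must lie in (0, 1)")
    h = saturation / (1.0 - saturation)
    ratio = h ** (1.0 / n)  # J/K at the target saturation
    current = model
    for _ in range(iterations):
        ss = solve_steady_state(current)
        conc = {**ss.concentrations, **ss.external}
        k = conc[metabolite] / ratio
        current = add_regulator(
            model, reaction_id, RegulatorSpec(metabolite, mode, K=k, n=n)
        )
    return current


def add_regulator(model: KineticModel, reaction_id: str, reg: RegulatorSpec) -> KineticModel:
    """Return a new model with a Hill modifier attached to one reaction."""
    if reg.metabolite not in model.species_ids:
        raise ModelLookupError(f"unknown species {reg.metabolite}")
    rxn = model.reaction(reaction_id)
    new = replace(rxn, modifiers=(*rxn.modifiers, reg))
    return replace(
        model,
        reactions=tuple(new if r.id == reaction_id else r for r in model.reactions),
    )


def reaction_rate(
    model: KineticModel, reaction_id: str, state: Mapping[str, float] | Sequence[float]
) -> float:
    """Evaluate one reaction's rate law at a concentration state.

    ``state`` is either a mapping over species ids or a vector over the
    model's internal species (externals taken at their clamped values).
    """
    conc = state if isinstance(state, Mapping) else model.full_state(state)
    return model.reaction(reaction_id).rate(conc)


def decompose_stoichiometry(
    model: KineticModel, tol: float = 1e-9
) -> StoichiometryDecomposition:
    """Split N into independent rows N_R and a link matrix L with N = L @ N_R.

    Independent rows are found by rank-revealing row reduction; the link
    matrix carries an identity block over the independent species.  Conserved
    relations span the left null space of N.
    """
    ndf = model.stoichiometric_matrix()
    internal = list(ndf.index)
    n = ndf.to_numpy(dtype=float)

    # Gaussian elimination on N tracking which original rows are pivots
    a = n.copy()
    rows = list(range(a.shape[0]))
    piv_rows: list[int] = []
    col = 0
    r = 0
    while r < a.shape[0] and col < a.shape[1]:
        sub = np.abs(a[r:, col])
        if sub.size == 0 or sub.max() <= tol:
            col += 1
            continue
        k = r + int(np.argmax(sub))
        a[[r, k]] = a[[k, r]]
        rows[r], rows[k] = rows[k], rows[r]
        piv_rows.append(rows[r])
        a[r + 1:] -= np.outer(a[r + 1:, col] / a[r, col], a[r])
        r += 1
        col += 1

    independent = sorted(piv_rows)
    dependent = [i for i in range(len(internal)) if i not in independent]
    nr = n[independent]
    # L solves L @ N_R = N row-wise; exact for integer stoichiometry
    l_mat = np.linalg.lstsq(nr.T, n.T, rcond=None)[0].T
    l_mat[np.abs(l_mat) < 1e-12] = 0.0

    ind_ids = [internal[i] for i in independent]
    dep_ids = [internal[i] for i in dependent]
    from scipy.linalg import null_space

    g = null_space(n.T, rcond=tol).T  # conserved relations: g @ N = 0
    x0 = np.array([model.species_spec(s).initial for s in internal])
    return StoichiometryDecomposition(
        independent=tuple(ind_ids),
        dependent=tuple(dep_ids),
        Nr=pd.DataFrame(nr, index=ind_ids, columns=ndf.columns),
        L=pd.DataFrame(l_mat, index=internal, columns=ind_ids),
        conservation=pd.DataFrame(g, columns=internal),
        totals=g @ x0 if g.size else np.empty(0),
    )


# --------------------------------------------------------------------------- #
# SBML round trip
# --------------------------------------------------------------------------- #

def _rate_formula(rxn: ReactionSpec) -> str:
    kms = " * ".join(f"Km_{sp}^{st}" for sp, st in rxn.substrates) or "1"
    prod_num = " * ".join(f"{sp}^{st}" for sp, st in rxn.products) or "1"
    sub_num = " * ".join(f"{sp}^{st}" for sp, st in rxn.substrates) or "1"
    den_s = " * ".join(f"(1 + {sp}/Km_{sp})^{st}" for sp, st in rxn.substrates) or "1"
    den_p = " * ".join(f"(1 + {sp}/Km_{sp})^{st}" for sp, st in rxn.products) or "1"
    mods = ""
    for m in rxn.modifiers:
        h = f"({m.metabolite}/reg_{m.metabolite}_K)^reg_{m.metabolite}_n"
        mods += (
            f" * ({h}/(1 + {h}))" if m.mode == "activator" else f" * (1/(1 + {h}))"
        )
    return (
        f"e * (Vf/({kms})) * (({sub_num}) - ({prod_num})/Keq)"
        f" / (({den_s}) + ({den_p}) - 1){mods}"
    )


def write_sbml(model: KineticModel) -> str:
    """Serialize to SBML Level 3.  Kinetic constants live as local parameters;
    regulators are SBML modifier species with mode/K/n local parameters."""
    import libsbml

    doc = libsbml.SBMLDocument(3, 2)
    m = doc.createModel()
    m.setId(model.name)
    comp = m.createCompartment()
    comp.setId("cell")
    comp.setConstant(True)
    comp.setSize(1.0)
    for s in model.species:
        sp = m.createSpecies()
        sp.setId(s.id)
        sp.setCompartment("cell")
        sp.setInitialConcentration(s.initial)
        sp.setBoundaryCondition(s.role == "external")
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)
    for r in model.reactions:
        rx = m.createReaction()
        rx.setId(r.id)
        rx.setReversible(True)
        for sp, st in r.substrates:
            ref = rx.createReactant()
            ref.setSpecies(sp)
            ref.setStoichiometry(float(st))
            ref.setConstant(True)
        for sp, st in r.products:
            ref = rx.createProduct()
            ref.setSpecies(sp)
            ref.setStoichiometry(float(st))
            ref.setConstant(True)
        for mod in r.modifiers:
            ref = rx.createModifier()
            ref.setSpecies(mod.metabolite)
        kl = rx.createKineticLaw()
        params = {"Vf": r.Vf, "Keq": r.Keq, "e": r.enzyme}
        for sp, km in r.Km.items():
            params[f"Km_{sp}"] = km
        for mod in r.modifiers:
            params[f"reg_{mod.metabolite}_K"] = mod.K
            params[f"reg_{mod.metabolite}_n"] = mod.n
            params[f"reg_{mod.metabolite}_mode"] = (
                1.0 if mod.mode == "activator" else -1.0
            )
        for pid, val in params.items():
            p = kl.createLocalParameter()
            p.setId(pid)
            p.setValue(float(val))
        math = libsbml.parseL3Formula(_rate_formula(r))
        if math is not None:
            kl.setMath(math)
    return libsbml.writeSBMLToString(doc)


def read_sbml(text: str) -> KineticModel:
    """Parse an SBML document produced by :func:`write_sbml`."""
    import libsbml

    doc = libsbml.readSBMLFromString(text)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(
            f"SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    m = doc.getModel()
    if m is None:
        raise ModelParseError("document contains no model")
    species = tuple(
        SpeciesSpec(
            m.getSpecies(i).getId(),
            "external" if m.getSpecies(i).getBoundaryCondition() else "internal",
            m.getSpecies(i).getInitialConcentration(),
        )
        for i in range(m.getNumSpecies())
    )
    declared = {s.id for s in species}
    reactions = []
    for i in range(m.getNumReactions()):
        rx = m.getReaction(i)
        kl = rx.getKineticLaw()
        params = {}
        if kl is not None:
            for j in range(kl.getNumLocalParameters()):
                p = kl.getLocalParameter(j)
                params[p.getId()] = p.getValue()
        subs = []
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            if ref.getSpecies() not in declared:
                raise ModelParseError(
                    f"reaction {rx.getId()} references undeclared species "
                    f"{ref.getSpecies()}"
                )
            subs.append((ref.getSpecies(), int(ref.getStoichiometry())))
        prods = []
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            if ref.getSpecies() not in declared:
                raise ModelParseError(
                    f"reaction {rx.getId()} references undeclared species "
                    f"{ref.getSpecies()}"
                )
            prods.append((ref.getSpecies(), int(ref.getStoichiometry())))
        mods = []
        for j in range(rx.getNumModifiers()):
            sid = rx.getModifier(j).getSpecies()
            if sid not in declared:
                raise ModelParseError(
                    f"reaction {rx.getId()} references undeclared modifier {sid}"
                )
            mode = params.get(f"reg_{sid}_mode", -1.0)
            mods.append(
                RegulatorSpec(
                    sid,
                    "activator" if mode > 0 else "inhibitor",
                    K=params.get(f"reg_{sid}_K", 1.0),
                    n=params.get(f"reg_{sid}_n", 1.0),
                )
            )
        km = {
            pid[len("Km_"):]: val
            for pid, val in params.items()
            if pid.startswith("Km_")
        }
        missing = [sp for sp, _ in subs + prods if sp not in km]
        if missing:
            raise ModelParseError(
                f"reaction {rx.getId()} is missing Km parameters for {missing}"
            )
        reactions.append(
            ReactionSpec(
                rx.getId(),
                tuple(subs),
                tuple(prods),
                Vf=params.get("Vf", 1.0),
                Km=km,
                Keq=params.get("Keq", 1.0),
                enzyme=params.get("e", 1.0),
                modifiers=tuple(mods),
            )
        )
    return KineticModel(species, tuple(reactions), name=m.getId() or "model")


def model_io(obj: "KineticModel | str", direction: str) -> "str | KineticModel":
    """Round-trip entry point: ``direction`` is ``"write"`` or ``"read"``."""
    if direction == "write":
        if not isinstance(obj, KineticModel):
            raise ConfigurationError("write direction requires a KineticModel")
        return write_sbml(obj)
    if direction == "read":
        if not isinstance(obj, str):
            raise ConfigurationError("read direction requires SBML text")
        return read_sbml(obj)
    raise ConfigurationError(f"unknown direction {direction!r}")
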