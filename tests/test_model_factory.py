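import math

import numpy as np
import pytest

from bmca_bench import (
    ConfigurationError,
    ModelLookupError,
    ModelParseError,
    DomainError,
)
from bmca_bench.model_factory import (
    KineticModel,
    NetworkSpec,
    ReactionSpec,
    RegulatorSpec,
    SpeciesSpec,
    add_regulator,
    build_network,
    decompose_stoichiometry,
    model_io,
    reaction_rate,
    read_sbml,
    write_sbml,
)
from bmca_bench.simulation import solve_steady_state


@pytest.mark.parametrize(
    "preset,n_species,n_reactions",
    [("linear_branched", 14, 16), ("branched", 17, 19)],
)
def test_preset_counts(preset, n_species, n_reactions):
    model = build_network(NetworkSpec(preset, seed=1))
    assert len(model.species) == n_species
    assert len(model.reactions) == n_reactions
    n = model.stoichiometric_matrix()
    assert n.shape[1] == n_reactions
    assert n.shape[0] <= n_species  # internal species only


def test_seed_determinism():
    a = build_network(NetworkSpec("branched", seed=3))
    b = build_network(NetworkSpec("branched", seed=3))
    assert a == b


def test_wrong_counts_rejected():
    with pytest.raises(ConfigurationError):
        NetworkSpec("branched", counts=(12, 19))
    with pytest.raises(ConfigurationError):
        NetworkSpec("no_such_preset")


def test_reference_state_not_at_equilibrium(linear_model, linear_reference):
    """All reactions carry net forward flux away from equilibrium (rho < 1)."""
    conc = {**linear_reference.concentrations, **linear_reference.external}
    for rxn in linear_model.reactions:
        rho = rxn.mass_action_ratio(conc) / rxn.Keq
        assert 0.0 < rho < 1.0
        assert linear_reference.fluxes[rxn.id] > 0


class TestRateLaw:
    def test_equilibrium_flux_is_zero(self, chain3):
        rxn = chain3.reaction("r2")
        # put x2/x1 exactly at Keq -> zero net rate
        state = chain3.reference_concentrations()
        state["x1"] = 1.0
        state["x2"] = rxn.Keq
        assert reaction_rate(chain3, "r2", state) == pytest.approx(0.0, abs=1e-14)

    def test_flux_linear_in_enzyme(self, chain3):
        state = chain3.reference_concentrations()
        v1 = reaction_rate(chain3, "r1", state)
        doubled = chain3.with_enzyme("r1", 2.0)
        assert reaction_rate(doubled, "r1", state) == pytest.approx(2 * v1, rel=1e-12)

    def test_toy_mass_action_value(self):
        """v = e*k*(S - P/Keq) with e=k=1, S=2, P=1, Keq=1 gives v = 1."""
        big = 1e9
        model = KineticModel(
            species=(
                SpeciesSpec("S", "external", 2.0),
                SpeciesSpec("P", "internal", 1.0),
            ),
            reactions=(
                ReactionSpec(
                    "r", (("S", 1),), (("P", 1),),
                    Vf=big, Km={"S": big, "P": big}, Keq=1.0,
                ),
            ),
        )
        assert reaction_rate(model, "r", {"S": 2.0, "P": 1.0}) == pytest.approx(
            1.0, rel=1e-6
        )

    def test_negative_concentration_rejected(self, chain3):
        state = chain3.reference_concentrations()
        state["x1"] = -0.5
        with pytest.raises(DomainError):
            reaction_rate(chain3, "r2", state)


class TestRegulators:
    def test_zero_regulator_is_neutral(self):
        reg = RegulatorSpec("J", "inhibitor", K=1.0, n=4)
        assert reg.factor(0.0) == 1.0

    def test_half_saturation(self):
        reg = RegulatorSpec("J", "inhibitor", K=2.0, n=4)
        assert reg.factor(2.0) == pytest.approx(0.5)

    def test_scaled_elasticity_at_half_saturation(self, chain3):
        """d ln(1/(1+(J/K)^n)) / d ln J = -n/2 at J = K."""
        reg = RegulatorSpec("x2", "inhibitor", K=1.0, n=4)
        model = add_regulator(chain3, "r1", reg)
        state = model.reference_concentrations()
        state["x2"] = 1.0
        h = 1e-6
        up, down = dict(state), dict(state)
        up["x2"] = math.exp(h)
        down["x2"] = math.exp(-h)
        dlnv = (
            math.log(reaction_rate(model, "r1", up))
            - math.log(reaction_rate(model, "r1", down))
        ) / (2 * h)
        base = (
            math.log(reaction_rate(chain3, "r1", up))
            - math.log(reaction_rate(chain3, "r1", down))
        ) / (2 * h)
        assert dlnv - base == pytest.approx(-2.0, abs=1e-5)
        assert reg.log_gradient(1.0) == pytest.approx(-2.0)

    def test_add_regulator_is_functional(self, chain3):
        reg = RegulatorSpec("x2", "activator", K=0.5, n=2)
        new = add_regulator(chain3, "r1", reg)
        assert chain3.reaction("r1").modifiers == ()
        assert new.reaction("r1").modifiers == (reg,)
        with pytest.raises(ModelLookupError):
            add_regulator(chain3, "r1", RegulatorSpec("nope", "inhibitor", K=1.0))
        with pytest.raises(ModelLookupError):
            add_regulator(chain3, "nope", reg)


class TestDecomposition:
    def test_no_conservation_gives_identity_link(self, chain3):
        d = decompose_stoichiometry(chain3)
        assert not d.has_conservation
        np.testing.assert_allclose(d.L.to_numpy(), np.eye(2))
        np.testing.assert_allclose(
            d.Nr.to_numpy(), chain3.stoichiometric_matrix().to_numpy()
        )

    def test_two_species_moiety(self):
        """An ATP/ADP-style pair whose rows sum to zero: rank deficit one."""
        model = KineticModel(
            species=(
                SpeciesSpec("S", "external", 2.0),
                SpeciesSpec("P", "external", 0.1),
                SpeciesSpec("ATP", "internal", 1.5),
                SpeciesSpec("ADP", "internal", 0.5),
            ),
            reactions=(
                ReactionSpec(
                    "use", (("S", 1), ("ATP", 1)), (("P", 1), ("ADP", 1)),
                    Vf=1.0, Km={"S": 1, "ATP": 1, "P": 1, "ADP": 1}, Keq=10.0,
                ),
                ReactionSpec(
                    "regen", (("ADP", 1),), (("ATP", 1),),
                    Vf=1.0, Km={"ADP": 1, "ATP": 1}, Keq=10.0,
                ),
            ),
        )
        d = decompose_stoichiometry(model)
        assert len(d.dependent) == 1
        assert d.conservation.shape[0] == 1
        # the conserved relation is proportional to ATP + ADP
        rel = d.conservation.iloc[0]
        assert rel["ATP"] == pytest.approx(rel["ADP"], rel=1e-10)
        np.testing.assert_allclose(
            d.L.to_numpy() @ d.Nr.to_numpy(),
            model.stoichiometric_matrix().to_numpy(),
            atol=1e-10,
        )

    def test_link_identity_on_presets(self, core_model):
        d = decompose_stoichiometry(core_model)
        assert d.has_conservation
        np.testing.assert_allclose(
            d.L.to_numpy() @ d.Nr.to_numpy(),
            core_model.stoichiometric_matrix().to_numpy(),
            atol=1e-10,
        )
        # identity block over the independent species
        l_ind = d.L.loc[list(d.independent)].to_numpy()
        np.testing.assert_allclose(l_ind, np.eye(len(d.independent)), atol=1e-10)

    def test_conserved_totals_constant_at_steady_state(self, core_model):
        d = decompose_stoichiometry(core_model)
        ss = solve_steady_state(core_model)
        x = np.array([ss.concentrations[s] for s in core_model.internal_ids])
        totals = d.conservation.to_numpy() @ x
        np.testing.assert_allclose(totals, d.totals, atol=1e-8)


class TestModelIO:
    def test_round_trip_chain(self, chain3):
        text = model_io(chain3, "write")
        back = model_io(text, "read")
        assert back.equals(chain3)
        np.testing.assert_array_equal(
            back.stoichiometric_matrix().to_numpy(),
            chain3.stoichiometric_matrix().to_numpy(),
        )

    def test_round_trip_regulator(self, chain3):
        reg = RegulatorSpec("x2", "inhibitor", K=0.75, n=3)
        model = add_regulator(chain3, "r1", reg)
        back = read_sbml(write_sbml(model))
        (mod,) = back.reaction("r1").modifiers
        assert mod.metabolite == "x2" and mod.mode == "inhibitor"
        assert mod.K == pytest.approx(0.75) and mod.n == pytest.approx(3)

    def test_missing_species_is_parse_error(self, chain3):
        text = write_sbml(chain3).replace(
            '<species id="x2"', '<species id="x2_renamed"'
        )
        with pytest.raises(ModelParseError):
            read_sbml(text)

    def test_malformed_document(self):
        with pytest.raises(ModelParseError):
            read_sbml("<sbml this is not valid xml")


def test_undeclared_species_rejected():
    with pytest.raises(ModelLookupError):
        KineticModel(
            species=(SpeciesSpec("A", "external", 1.0),),
            reactions=(
                ReactionSpec(
                    "r", (("A", 1),), (("ghost", 1),),
                    Vf=1.0, Km={"A": 1.0, "ghost": 1.0}, Keq=1.0,
                ),
            ),
        )
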