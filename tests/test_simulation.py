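import numpy as np
import pandas as pd
import pytest

from bmca_bench import (
    ConfigurationError,
    NormalizationError,
    SteadyStateError,
)
from bmca_bench.model_factory import (
    KineticModel,
    ReactionSpec,
    SpeciesSpec,
)
from bmca_bench.simulation import (
    DEFAULT_LEVELS,
    ObservationMask,
    apply_omission,
    generate_perturbation_dataset,
    normalize_dataset,
    solve_steady_state,
)


class TestSolveSteadyState:
    def test_two_step_chain_closed_form(self, chain2):
        """v1 = 2 - x, v2 = x balance at x = 1 with flux J = 1."""
        ss = solve_steady_state(chain2)
        assert ss.concentrations["x"] == pytest.approx(1.0, rel=1e-6)
        assert ss.fluxes["v1"] == pytest.approx(1.0, rel=1e-6)
        assert ss.fluxes["v2"] == pytest.approx(1.0, rel=1e-6)

    def test_residual_contract(self, linear_model, linear_reference):
        n = linear_model.stoichiometric_matrix().to_numpy(dtype=float)
        v = np.array(
            [linear_reference.fluxes[r] for r in linear_model.reaction_ids]
        )
        assert np.linalg.norm(n @ v) / np.linalg.norm(v) < 1e-9
        assert linear_reference.residual < 1e-9
        assert all(c >= 0 for c in linear_reference.concentrations.values())

    def test_no_steady_state_reported(self):
        """Constant influx 2 into a saturating efflux with Vmax = 1: the pool
        grows without bound and the solver reports failure."""
        big = 1e15
        model = KineticModel(
            species=(
                SpeciesSpec("S", "external", 2.0),
                SpeciesSpec("x", "internal", 1.0),
                SpeciesSpec("P", "external", 1e-9),
            ),
            reactions=(
                # influx ~ S (clamped at 2) in the mass-action limit
                ReactionSpec(
                    "in", (("S", 1),), (("x", 1),),
                    Vf=big, Km={"S": big, "x": big}, Keq=big,
                ),
                # saturating efflux with Vmax = 1 (Km << x)
                ReactionSpec(
                    "out", (("x", 1),), (("P", 1),),
                    Vf=1.0, Km={"x": 1e-4, "P": 1e6}, Keq=1e12,
                ),
            ),
        )
        with pytest.raises(SteadyStateError):
            solve_steady_state(model, t_stages=(50.0, 500.0))


class TestPerturbationProtocol:
    def test_default_level_grid(self):
        assert DEFAULT_LEVELS == (0.1, 0.2, 0.3, 0.4, 0.5, 1.5, 3.0, 5.0, 7.0, 10.0)

    def test_structural_count(self, linear_model):
        ds = generate_perturbation_dataset(linear_model, levels=[1.5])[0]
        assert len(ds.experiments) + len(ds.excluded) == 17  # reference + 16 enzymes
        names = [n for n, _ in ds.experiments]
        assert names.count("reference") == 1

    def test_reset_and_determinism(self, linear_model):
        a = generate_perturbation_dataset(linear_model, levels=[0.5])[0]
        b = generate_perturbation_dataset(linear_model, levels=[0.5])[0]
        for (na, sa), (nb, sb) in zip(a.experiments, b.experiments):
            assert na == nb
            assert sa.fluxes == sb.fluxes
            assert sa.concentrations == sb.concentrations

    def test_internal_consistency(self, linear_model):
        """Re-evaluating rate laws at each recorded state reproduces the fluxes."""
        ds = generate_perturbation_dataset(linear_model, levels=[0.3])[0]
        for name, state in ds.experiments:
            model = (
                linear_model
                if name == "reference"
                else linear_model.with_enzyme(name, 0.3)
            )
            conc = {**state.concentrations, **state.external}
            for rid in model.reaction_ids:
                assert model.reaction(rid).rate(conc) == pytest.approx(
                    state.fluxes[rid], abs=1e-8, rel=1e-8
                )

    def test_failed_perturbation_excluded(self):
        """An enzyme whose perturbation removes the steady state is excluded."""
        big = 1e9
        model = KineticModel(
            species=(
                SpeciesSpec("S", "external", 2.0),
                SpeciesSpec("x", "internal", 1.0),
                SpeciesSpec("P", "external", 1e-9),
            ),
            reactions=(
                # constant influx ~ (Vf/Km)*S = 1.0 in the mass-action limit
                ReactionSpec(
                    "in", (("S", 1),), (("x", 1),),
                    Vf=0.5 * big, Km={"S": big, "x": big}, Keq=1e12,
                ),
                # near-saturating efflux: Vmax 1.2 at reference, 0.24 at 20%
                ReactionSpec(
                    "out", (("x", 1),), (("P", 1),),
                    Vf=1.2, Km={"x": 0.05, "P": 1e6}, Keq=1e12,
                ),
            ),
        )
        ds = generate_perturbation_dataset(
            model, levels=[0.2],
        )[0]
        excluded_names = [n for n, _ in ds.excluded]
        assert "out" in excluded_names
        present = [n for n, _ in ds.experiments]
        assert "out" not in present and "reference" in present

    def test_empty_enzyme_list_rejected(self, chain2):
        with pytest.raises(ConfigurationError):
            generate_perturbation_dataset(chain2, levels=[1.5], enzymes=[])

    def test_external_perturbation_rows(self, chain3):
        ds = generate_perturbation_dataset(
            chain3, levels=[1.5], perturb_external=True
        )[0]
        names = [n for n, _ in ds.experiments]
        assert any(n.startswith("ext:") for n in names)


class TestNormalization:
    def test_reference_row_identities(self, linear_dataset_150):
        nd = linear_dataset_150
        assert np.allclose(nd.v_hat.loc["reference"], 1.0)
        assert np.allclose(nd.e_hat.loc["reference"], 1.0)
        assert np.allclose(nd.chi.loc["reference"], 0.0)
        assert np.allclose(nd.gamma.loc["reference"], 0.0)

    def test_chi_is_natural_log_of_ratio(self, chain3):
        ds = generate_perturbation_dataset(chain3, levels=[3.0])[0]
        nd = normalize_dataset(ds)
        states = dict(ds.experiments)
        for name, state in states.items():
            for sid, x in state.concentrations.items():
                assert nd.chi.loc[name, sid] == pytest.approx(
                    np.log(x / states["reference"].concentrations[sid]), abs=1e-12
                )

    def test_round_trip(self, linear_dataset_150):
        nd = linear_dataset_150
        x = np.exp(nd.chi) * nd.x_star
        # recover raw concentrations for every experiment
        assert np.allclose(
            x.loc["reference"], nd.x_star, rtol=1e-12
        )

    def test_zero_reference_flux_error(self, chain2):
        ds = generate_perturbation_dataset(chain2, levels=[1.5])[0]
        # fabricate a zero reference flux
        ref = dict(ds.experiments)["reference"]
        broken = type(ref)(
            concentrations=ref.concentrations,
            external=ref.external,
            fluxes={**ref.fluxes, "v1": 0.0},
            enzymes=ref.enzymes,
            residual=ref.residual,
        )
        experiments = tuple(
            ("reference", broken) if n == "reference" else (n, s)
            for n, s in ds.experiments
        )
        with pytest.raises(NormalizationError, match="v1"):
            normalize_dataset(type(ds)(ds.level, experiments))

    def test_missing_reference_rejected(self, chain2):
        ds = generate_perturbation_dataset(chain2, levels=[1.5])[0]
        with pytest.raises(ConfigurationError):
            normalize_dataset(ds, reference="nope")


class TestOmission:
    def test_all_observed_passthrough(self, linear_dataset_150):
        obs = apply_omission(linear_dataset_150, ObservationMask())
        assert obs.mode == "v_based"
        pd.testing.assert_frame_equal(obs.v_hat, linear_dataset_150.v_hat)
        pd.testing.assert_frame_equal(obs.chi, linear_dataset_150.chi)
        assert obs.latent_chi == () and obs.latent_gamma == ()

    def test_flux_latent_keeps_reference(self, linear_dataset_150):
        obs = apply_omission(linear_dataset_150, ObservationMask.omit("fluxes"))
        assert obs.mode == "e_based"
        assert obs.v_hat is None
        pd.testing.assert_series_equal(obs.v_star, linear_dataset_150.v_star)

    def test_per_species_override(self, linear_dataset_150, linear_model):
        sid = linear_model.internal_ids[2]
        obs = apply_omission(
            linear_dataset_150, ObservationMask(species_overrides={sid: "latent"})
        )
        assert obs.latent_chi == (sid,)
        assert sid not in obs.chi.columns
        assert len(obs.chi.columns) == len(linear_model.internal_ids) - 1

    def test_invalid_mask_flag(self):
        with pytest.raises(ConfigurationError):
            ObservationMask(fluxes="maybe")
        with pytest.raises(ConfigurationError):
            ObservationMask.omit("momentum")
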