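import math

import numpy as np
import pandas as pd
import pytest

from bmca_bench import ConfigurationError, DegenerateDensityError
from bmca_bench.bmca_inference import (
    PosteriorSamples,
    _hdi_interval,
    build_linlog_model,
    build_priors,
    fit_advi,
    hdi_point_estimates,
    logp_ground_truth,
)
from bmca_bench.simulation import (
    NormalizedDataset,
    ObservationMask,
    apply_omission,
)


# --------------------------------------------------------------------------- #
# a tiny hand-built lin-log system: one metabolite, two reactions
# --------------------------------------------------------------------------- #

def _toy_linlog_dataset(eps_true: float = 1.0, n_exp: int = 8) -> NormalizedDataset:
    """Data generated from the lin-log relation itself (no MM kinetics)."""
    rng = np.random.default_rng(42)
    experiments = ["reference"] + [f"p{i}" for i in range(1, n_exp)]
    chi = np.zeros((n_exp, 1))
    chi[1:, 0] = rng.uniform(-0.8, 0.8, n_exp - 1)
    e_hat = np.ones((n_exp, 2))
    e_hat[1:, 0] = rng.uniform(0.5, 1.5, n_exp - 1)
    v_hat = e_hat * (1.0 + eps_true * chi)
    idx = pd.Index(experiments)
    return NormalizedDataset(
        level=1.5,
        v_hat=pd.DataFrame(v_hat, index=idx, columns=["rA", "rB"]),
        e_hat=pd.DataFrame(e_hat, index=idx, columns=["rA", "rB"]),
        chi=pd.DataFrame(chi, index=idx, columns=["m"]),
        gamma=pd.DataFrame(np.zeros((n_exp, 0)), index=idx),
        v_star=pd.Series({"rA": 1.0, "rB": 1.0}),
        e_star=pd.Series({"rA": 1.0, "rB": 1.0}),
        x_star=pd.Series({"m": 1.0}),
        y_star=pd.Series(dtype=float),
    )


class _ToyStructure:
    """Duck-typed stand-in for a KineticModel: reaction rA produces m, rB consumes it."""

    class _Rxn:
        def __init__(self, rid, roles):
            self.id = rid
            self._roles = roles

        def participants(self):
            return self._roles

    @property
    def reactions(self):
        return [
            self._Rxn("rA", {"m": "product"}),
            self._Rxn("rB", {"m": "substrate"}),
        ]


@pytest.fixture(scope="module")
def toy_obs():
    return apply_omission(_toy_linlog_dataset(), ObservationMask())


@pytest.fixture(scope="module")
def toy_model(toy_obs):
    return build_linlog_model(toy_obs, build_priors(_ToyStructure(), toy_obs))


class TestPriors:
    def test_role_orientation(self, linear_model, linear_dataset_150):
        obs = apply_omission(linear_dataset_150, ObservationMask())
        priors = build_priors(linear_model, obs)
        for rxn in linear_model.reactions:
            for sid, role in rxn.participants().items():
                block = (
                    priors.role_x if sid in priors.role_x.columns else priors.role_y
                )
                expected = {"substrate": 1, "product": -1, "modifier": 0}[role]
                assert block.loc[rxn.id, sid] == expected

    def test_enzyme_centers_follow_design(self, linear_model, linear_dataset_150):
        obs = apply_omission(linear_dataset_150, ObservationMask())
        priors = build_priors(linear_model, obs)
        rid = linear_model.reaction_ids[0]
        assert priors.e_centers.loc[rid, rid] == pytest.approx(1.5)
        assert priors.e_centers.loc["reference", rid] == pytest.approx(1.0)

    def test_regulator_entries_fall_in_slab(self, linear_model, linear_dataset_150):
        from bmca_bench.model_factory import RegulatorSpec, add_regulator

        reg_model = add_regulator(
            linear_model, "r04", RegulatorSpec("M07", "inhibitor", K=1.0, n=3)
        )
        obs = apply_omission(linear_dataset_150, ObservationMask())
        priors = build_priors(reg_model, obs)
        assert priors.role_x.loc["r04", "M07"] == 0  # stays in the sparse slab


class TestModelStructure:
    def test_reference_state_prediction_is_one(self, toy_model):
        params = toy_model.unpack(toy_model.initial_point())
        pred = toy_model.predict_linlog(params)
        ref = toy_model.experiments.index("reference")
        np.testing.assert_allclose(pred[ref], 1.0, atol=1e-12)

    def test_linlog_prediction_value(self, toy_model):
        """eps = 2, chi = ln 2, e = 1 predicts v = 1 + 2 ln 2 = 2.3863."""
        p = 1.0 + 2.0 * math.log(2.0)
        assert p == pytest.approx(2.3863, abs=1e-4)
        z = toy_model.initial_point()
        params = toy_model.unpack(z)
        params["eps_x"] = np.array([[0.0], [2.0]])
        model2 = toy_model
        chi_saved = model2.chi_base.copy()
        model2.chi_base = np.full_like(model2.chi_base, math.log(2.0))
        try:
            pred = model2.predict_linlog(params)
        finally:
            model2.chi_base = chi_saved
        assert pred[0, 1] == pytest.approx(1.0 + 2.0 * math.log(2.0), rel=1e-12)

    def test_flux_omission_switches_mode(self):
        nd = _toy_linlog_dataset()
        obs = apply_omission(nd, ObservationMask.omit("fluxes"))
        model = build_linlog_model(obs, build_priors(_ToyStructure(), obs))
        assert model.mode == "e_based"

    def test_all_omitted_is_configuration_error(self):
        nd = _toy_linlog_dataset()
        obs = apply_omission(
            nd,
            ObservationMask.omit(
                "fluxes", "enzymes", "internal_metabolites", "external_metabolites"
            ),
        )
        with pytest.raises(ConfigurationError):
            build_linlog_model(obs, build_priors(_ToyStructure(), obs))


class TestGradient:
    @pytest.mark.parametrize(
        "omit",
        [(), ("enzymes",), ("internal_metabolites",), ("external_metabolites",), ("fluxes",)],
    )
    def test_analytic_gradient_matches_finite_differences(
        self, linear_model, linear_dataset_150, omit
    ):
        mask = ObservationMask.omit(*omit) if omit else ObservationMask()
        obs = apply_omission(linear_dataset_150, mask)
        model = build_linlog_model(obs, build_priors(linear_model, obs))
        rng = np.random.default_rng(0)
        z = model.initial_point() + 0.1 * rng.standard_normal(model.dim)
        _, grad = model.logp_and_grad(z)
        for i in rng.choice(model.dim, size=25, replace=False):
            zp, zm = z.copy(), z.copy()
            zp[i] += 1e-6
            zm[i] -= 1e-6
            numeric = (model.logp_and_grad(zp)[0] - model.logp_and_grad(zm)[0]) / 2e-6
            assert grad[i] == pytest.approx(numeric, rel=1e-4, abs=1e-5)


class TestAdvi:
    def test_parameter_recovery_on_linlog_data(self, toy_model):
        post = fit_advi(toy_model, iterations=8_000, seed=7, draws=500)
        est = hdi_point_estimates(post)
        # true elasticities: +1 for the consumer (substrate), -1 for the producer
        assert est["eps_x"][1, 0] == pytest.approx(1.0, abs=0.2)

    def test_seed_determinism(self, toy_model):
        a = fit_advi(toy_model, iterations=500, seed=3, draws=50)
        b = fit_advi(toy_model, iterations=500, seed=3, draws=50)
        np.testing.assert_array_equal(a.draws["eps_x"], b.draws["eps_x"])

    def test_no_data_limit_posterior_matches_prior(self):
        """With fluxes latent the elasticity posterior stays at the prior.

        Gaussian-reparameterized coordinates (the Laplace slab and offsets)
        must match the prior tightly; skew-normal participant entries keep a
        small systematic offset because a Gaussian mean-field factor cannot
        represent the skewed prior exactly.
        """
        nd = _toy_linlog_dataset()
        obs = apply_omission(nd, ObservationMask.omit("fluxes"))
        model = build_linlog_model(obs, build_priors(_ToyStructure(), obs))
        post = fit_advi(model, iterations=8_000, seed=5, draws=2_000)
        prior = model.sample_prior(4_000, seed=6)
        part = model._part_x
        for name in ("eps_x", "eps_y"):
            shift = np.abs(
                post.flat(name).mean(axis=0) - prior.flat(name).mean(axis=0)
            )
            if name == "eps_x":
                assert shift[part].max() < 0.15  # skew-normal variational offset
                if (~part).any():
                    assert shift[~part].max() < 0.05
            elif shift.size:
                assert shift.max() < 0.05


class TestNutsOnGaussian:
    def test_standard_normal_moments(self):
        """The sampler recovers mean and variance of a known Gaussian target."""
        from bmca_bench.bmca_inference import _nuts_chain

        class Gauss:
            dim = 8
            sigma = np.linspace(0.5, 3.0, 8)

            def logp_and_grad(self, z):
                g = -z / self.sigma**2
                return float(-0.5 * np.sum((z / self.sigma) ** 2)), g

        target = Gauss()
        draws, stats = _nuts_chain(
            target, draws=1_500, warmup=500, seed=9, target_accept=0.8,
            max_depth=10, z_init=np.zeros(8),
        )
        assert stats["divergences"] == 0
        np.testing.assert_allclose(draws.mean(axis=0), 0.0, atol=0.25)
        np.testing.assert_allclose(draws.std(axis=0), target.sigma, rtol=0.15)


class TestPosteriorSummaries:
    def test_hdi_mean_symmetric(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, size=(1, 4_000, 1))
        samples = PosteriorSamples({"p": x}, {}, "advi", 0)
        est = hdi_point_estimates(samples)["p"]
        assert abs(est[0]) < 3 / math.sqrt(4_000)

    def test_hdi_mean_constant_draws(self):
        x = np.full((1, 200, 1), 2.5)
        samples = PosteriorSamples({"p": x}, {}, "advi", 0)
        assert hdi_point_estimates(samples)["p"][0] == pytest.approx(2.5)

    def test_hdi_against_sorted_window_oracle(self):
        """Right-skewed sample: estimate below the plain mean, matches oracle."""
        rng = np.random.default_rng(1)
        x = rng.lognormal(0.0, 0.8, size=4_001)

        def oracle(vals, mass):
            xs = np.sort(vals)
            n = xs.size
            m = int(math.ceil(mass * n))
            widths = xs[m - 1:] - xs[: n - m + 1]
            i = int(np.argmin(widths))
            window = xs[i: i + m]
            return window.mean(), (xs[i], xs[i + m - 1])

        expected, (lo_o, hi_o) = oracle(x, 0.94)
        samples = PosteriorSamples({"p": x.reshape(1, -1, 1)}, {}, "advi", 0)
        est = hdi_point_estimates(samples, mass=0.94)["p"][0]
        assert est == pytest.approx(expected, abs=1e-9)
        assert est < x.mean()
        lo, hi = _hdi_interval(x, 0.94)
        assert (lo, hi) == pytest.approx((lo_o, hi_o))

    def test_too_few_draws_rejected(self):
        samples = PosteriorSamples({"p": np.zeros((1, 50, 1))}, {}, "advi", 0)
        with pytest.raises(ConfigurationError):
            hdi_point_estimates(samples)


@pytest.fixture(scope="module")
def normal_samples():
    rng = np.random.default_rng(2)
    return PosteriorSamples(
        {"p": rng.normal(0, 1, size=(1, 100_000, 1))}, {}, "advi", 0
    )


class TestLogpGroundTruth:
    def test_density_at_zero(self, normal_samples):
        lp = logp_ground_truth(normal_samples, {"p": np.array([0.0])})["p"][0]
        assert lp == pytest.approx(-0.9189, abs=0.05)

    def test_density_at_three(self, normal_samples):
        lp = logp_ground_truth(normal_samples, {"p": np.array([3.0])})["p"][0]
        assert lp == pytest.approx(-0.9189 - 4.5, abs=0.2)

    def test_far_truth_is_finite_and_negative(self, normal_samples):
        lp = logp_ground_truth(normal_samples, {"p": np.array([50.0])})["p"][0]
        assert np.isfinite(lp) and lp < -20

    def test_zero_variance_rejected(self):
        samples = PosteriorSamples({"p": np.full((1, 500, 1), 1.0)}, {}, "advi", 0)
        with pytest.raises(DegenerateDensityError):
            logp_ground_truth(samples, {"p": np.array([1.0])})
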