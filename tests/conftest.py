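import numpy as np
import pandas as pd
import pytest

from bmca_bench.model_factory import (
    KineticModel,
    NetworkSpec,
    ReactionSpec,
    SpeciesSpec,
    build_network,
)
from bmca_bench.simulation import (
    generate_perturbation_dataset,
    normalize_dataset,
    solve_steady_state,
)
from bmca_bench.ground_truth import gt_elasticities


def two_step_chain(e1: float = 1.0, e2: float = 1.0) -> KineticModel:
    """v1 = e1*(2 - x), v2 = e2*x in the mass-action limit (Km >> conc).

    v1: A(=2, clamped) <-> x with Keq = 1 gives v1 = e1*(A - x);
    v2: x -> B(~0) with huge Keq gives v2 = e2*x.
    """
    big = 1e8
    return KineticModel(
        species=(
            SpeciesSpec("A", "external", 2.0),
            SpeciesSpec("x", "internal", 1.0),
            SpeciesSpec("B", "external", 1e-9),
        ),
        reactions=(
            ReactionSpec(
                "v1", (("A", 1),), (("x", 1),),
                Vf=big * e1, Km={"A": big, "x": big}, Keq=1.0,
            ),
            ReactionSpec(
                "v2", (("x", 1),), (("B", 1),),
                Vf=big * e2, Km={"x": big, "B": big}, Keq=1e12,
            ),
        ),
        name="two_step_chain",
    )


def three_step_chain(seed: int = 0) -> KineticModel:
    """Linear A -> x1 -> x2 -> B chain with seeded moderate kinetics."""
    rng = np.random.default_rng(seed)
    species = (
        SpeciesSpec("A", "external", 2.0),
        SpeciesSpec("x1", "internal", 1.0),
        SpeciesSpec("x2", "internal", 1.0),
        SpeciesSpec("B", "external", 0.1),
    )
    edges = [("r1", "A", "x1"), ("r2", "x1", "x2"), ("r3", "x2", "B")]
    reactions = tuple(
        ReactionSpec(
            rid, ((s, 1),), ((p, 1),),
            Vf=float(rng.uniform(1.5, 2.5)),
            Km={s: float(rng.uniform(0.5, 2.0)), p: float(rng.uniform(0.5, 2.0))},
            Keq=float(rng.uniform(5.0, 20.0)),
        )
        for rid, s, p in edges
    )
    return KineticModel(species, reactions, name="three_step_chain")


@pytest.fixture(scope="session")
def linear_model():
    return build_network(NetworkSpec("linear_branched", seed=1))


@pytest.fixture(scope="session")
def branched_model():
    return build_network(NetworkSpec("branched", seed=1))


@pytest.fixture(scope="session")
def core_model():
    return build_network(NetworkSpec("core_like", seed=2))


@pytest.fixture(scope="session")
def linear_reference(linear_model):
    return solve_steady_state(linear_model)


@pytest.fixture(scope="session")
def linear_truth(linear_model, linear_reference):
    return gt_elasticities(linear_model, linear_reference)


@pytest.fixture(scope="session")
def linear_dataset_150(linear_model):
    """Normalized 150%-perturbation dataset on the linear-branched preset."""
    ds = generate_perturbation_dataset(linear_model, levels=[1.5])[0]
    return normalize_dataset(ds)


@pytest.fixture(scope="session")
def chain3():
    return three_step_chain(seed=0)


@pytest.fixture(scope="session")
def chain2():
    return two_step_chain()
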