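import numpy as np
import pytest

from mtbo.domain import CategoricalVariable, Condition, ContinuousVariable, Domain


@pytest.fixture
def ch_domain() -> Domain:
    """The flow C-H activation condition space: 3 continuous variables,
    5 solvents and 4 ligands (encoded dimension 12, 20 level combinations)."""
    return Domain(
        (
            ContinuousVariable("residence_time", 5.0, 60.0, "min"),
            ContinuousVariable("temperature", 50.0, 150.0, "degC"),
            ContinuousVariable("catalyst_loading", 1.0, 10.0, "mol%"),
            CategoricalVariable("solvent", ("toluene", "DMA", "acetonitrile", "DMSO", "NMP")),
            CategoricalVariable("ligand", ("JohnPhos", "SPhos", "XPhos", "DPEPhos")),
        ),
        objective_name="yield",
        maximize=True,
    )


@pytest.fixture
def cont_domain_1d() -> Domain:
    return Domain((ContinuousVariable("x", 0.0, 1.0),))


@pytest.fixture
def cont_domain_2d() -> Domain:
    return Domain((ContinuousVariable("x1", 0.0, 1.0), ContinuousVariable("x2", 0.0, 1.0)))


def random_condition(domain: Domain, rng: np.random.Generator) -> Condition:
    values = {}
    for v in domain.continuous:
        values[v.name] = float(rng.uniform(v.lower, v.upper))
    for v in domain.categorical:
        values[v.name] = str(rng.choice(v.levels))
    return Condition.from_mapping(values)
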