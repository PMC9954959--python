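import numpy as np
import pytest

from thyrocad.fis_core import AnfisModel, GaussianMF, SugenoRule
from thyrocad.synthetic_nodules import GeneratorConfig, build_schema, generate


@pytest.fixture(scope="session")
def schema():
    return build_schema()


@pytest.fixture(scope="session")
def default_table(schema):
    """The study-sized synthetic table: 398 nodules, 284 malignant."""
    return generate(schema, GeneratorConfig(seed=12345))


def random_model(rng, n_inputs, n_rules):
    """A random but well-conditioned ANFIS model for round-trip tests."""
    rules = tuple(
        SugenoRule(
            premises=tuple(
                GaussianMF(center=float(rng.uniform(0, 1)),
                           sigma=float(rng.uniform(0.05, 0.8)))
                for _ in range(n_inputs)
            ),
            consequent_coeffs=tuple(rng.uniform(-2, 2, size=n_inputs)),
            consequent_bias=float(rng.uniform(-2, 2)),
        )
        for _ in range(n_rules)
    )
    scaling = tuple((0.0, 1.0) for _ in range(n_inputs))
    return AnfisModel(rules=rules, input_scaling=scaling)
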