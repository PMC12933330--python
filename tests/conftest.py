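"""Shared fixtures: a toy linker corpus, ligand pair, permeability data and a
small trained policy, all generated deterministically at session start."""

import numpy as np
import pytest

from linkergen.chem import BIT_FP_2048, morgan_fingerprint
from linkergen.filters import (
    FilterConfig,
    FilterReferences,
    default_alert_patterns,
    default_specific_patterns,
)
from linkergen.fixtures import (
    FixtureRule,
    default_ligands,
    generate_linker_corpus,
    generate_permeability_dataset,
)
from linkergen.generator import EvaluationContext, augment_corpus, train_policy
from linkergen.permeability import PermeabilityRegressor


@pytest.fixture(scope="session")
def corpus():
    return generate_linker_corpus(300, seed=0)


@pytest.fixture(scope="session")
def ligands():
    return default_ligands()


@pytest.fixture(scope="session")
def permeability_data():
    """Noise-free 60-compound fixture dataset with its ground truth."""
    return generate_permeability_dataset(60, seed=1)


@pytest.fixture(scope="session")
def fitted_model(permeability_data):
    dataset, _ = permeability_data
    return PermeabilityRegressor(quantiles=()).fit_dataset(dataset)


@pytest.fixture(scope="session")
def references(corpus, ligands, fitted_model):
    poi, e3 = ligands
    return FilterReferences(
        poi=poi,
        e3=e3,
        linker_fps=[morgan_fingerprint(s, BIT_FP_2048) for s in corpus],
        protac_fps=fitted_model.train_ad_fps_,
        alert_patterns=default_alert_patterns(),
        specific_patterns=default_specific_patterns(),
    )


@pytest.fixture(scope="session")
def filter_config():
    return FilterConfig()


@pytest.fixture(scope="session")
def trained_policy(corpus):
    return train_policy(augment_corpus(corpus, 4, seed=0), epochs=20, seed=0)


@pytest.fixture(scope="session")
def evaluation_context(fitted_model, filter_config, references):
    return EvaluationContext(
        model=fitted_model,
        preset="relaxed",
        filter_config=filter_config,
        references=references,
    )
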