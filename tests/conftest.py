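"""Shared fixtures: the toy network, its omics fixtures, and sampled ensembles.

Expensive artifacts (context extraction, ACHR ensembles) are session-scoped
so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest

import fibroflux as ff
from fibroflux.pipeline import PipelineConfig, _condition_model
from fibroflux.synthetic import generate_evidence


@pytest.fixture(scope="session")
def toy():
    """(model, yield-table) pair with default construction parameters."""
    return ff.generate_toy_model()


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def yield_table(toy):
    return toy[1]


@pytest.fixture(scope="session")
def expression(toy_model):
    return ff.generate_expression_counts(toy_model, seed=3)


@pytest.fixture(scope="session")
def evidence(toy_model):
    return generate_evidence(toy_model)


@pytest.fixture(scope="session")
def extracted(toy_model, expression, evidence):
    """Context-specific toy model plus the per-gene decision table."""
    return ff.build_context_model(toy_model, expression.counts, evidence)


@pytest.fixture(scope="session")
def extracted_model(extracted):
    return extracted[0]


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig(
        model_path="", counts_path="", evidence_path="",
        n_total=10_000, thinning=20, n_kept=10_000, seed=11,
    )


@pytest.fixture(scope="session")
def sampled_ctrl(extracted_model, pipeline_config):
    model = _condition_model(extracted_model, pipeline_config, disease=False)
    return ff.achr_sample(
        model,
        n_total=pipeline_config.n_total,
        thinning=pipeline_config.thinning,
        n_kept=pipeline_config.n_kept,
        seed=pipeline_config.seed,
    )


@pytest.fixture(scope="session")
def sampled_rd(extracted_model, pipeline_config):
    model = _condition_model(extracted_model, pipeline_config, disease=True)
    return ff.achr_sample(
        model,
        n_total=pipeline_config.n_total,
        thinning=pipeline_config.thinning,
        n_kept=pipeline_config.n_kept,
        seed=pipeline_config.seed + 1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
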