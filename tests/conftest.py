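"""Shared fixtures: one seeded synthetic study reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from conet import (
    CorrelationTable,
    ExpressionMatrix,
    SynthConfig,
    correlation_table,
    generate_study,
)


@pytest.fixture(scope="session")
def study():
    """Default-sized synthetic study with a fixed seed."""
    return generate_study(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def corr_ref(study):
    return correlation_table(study.expression[study.config.reference_condition])


@pytest.fixture(scope="session")
def corr_disease(study):
    return correlation_table(study.expression[study.config.disease_condition])


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_expression(values, condition="test", genes=None, samples=None, unit="TPM"):
    """Small ExpressionMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        condition=condition,
        unit=unit,
    )


def make_corr(genes, matrix, condition="test"):
    """CorrelationTable from an explicit symmetric matrix."""
    return CorrelationTable(
        genes=list(genes), matrix=np.asarray(matrix, dtype=float), condition=condition
    )
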