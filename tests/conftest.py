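import numpy as np
import pandas as pd
import pytest

from coexscreen import screen_orchestrator as orch
from coexscreen import synthetic_data as syn
from coexscreen.io_formats import ExpressionMatrix, GenomeModel, SampleTable


@pytest.fixture(scope="session")
def default_cohort() -> syn.SyntheticCohort:
    """The default planted cohort: 2,000 genes, 5 modules, 200 samples."""
    return syn.generate_cohort(syn.CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_report(default_cohort):
    """End-to-end screen output on the default planted cohort."""
    return orch.run_screen(
        default_cohort.expression, default_cohort.betas, default_cohort.segments,
        default_cohort.samples, default_cohort.reference,
        default_cohort.reference_labels, syn.default_genome(),
        orch.ScreenParams(seed=1),
    )


@pytest.fixture
def small_genome() -> GenomeModel:
    return GenomeModel({"chr1": 100, "chr2": 200})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_expression(values: np.ndarray, genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def make_samples(n_tumor: int, n_normal: int) -> SampleTable:
    ids = [f"t{i}" for i in range(n_tumor)] + [f"n{i}" for i in range(n_normal)]
    return SampleTable(pd.DataFrame({
        "sample_id": ids,
        "condition": ["tumor"] * n_tumor + ["normal"] * n_normal,
    }))
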