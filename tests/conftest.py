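import numpy as np
import pandas as pd
import pytest

from escmeth import (
    CohortConfig,
    MethylationDataset,
    SimulationConfig,
    generate_call_cohort,
    generate_clinical_covariates,
    generate_expression_dataset,
    generate_methylation_dataset,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(n_probes=2000, seed=1)


@pytest.fixture(scope="session")
def sim_data(sim_config):
    """Seeded 2000-probe methylation dataset with ground truth."""
    return generate_methylation_dataset(sim_config)


@pytest.fixture(scope="session")
def sim_expression(sim_data, sim_config):
    _, truth = sim_data
    return generate_expression_dataset(truth, sim_config)


@pytest.fixture(scope="session")
def cohort():
    config = CohortConfig(seed=11)
    calls = generate_call_cohort(config)
    clinical = generate_clinical_covariates(calls, config)
    return config, calls, clinical


def make_dataset(values: np.ndarray, groups: list[str],
                 sample_ids: list[str] | None = None,
                 manifest: pd.DataFrame | None = None) -> MethylationDataset:
    """Small hand-built dataset for unit tests."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n_samples)]
    probe_ids = [f"cg{i:04d}" for i in range(n_probes)]
    if manifest is None:
        manifest = pd.DataFrame(
            {
                "chromosome": "chr1",
                "position": np.arange(1, n_probes + 1),
                "gene": [f"G{i}" for i in range(n_probes)],
                "gene_region": "TSS200",
                "cgi_context": "island",
            },
            index=pd.Index(probe_ids, name="probe_id"),
        )
    samples = pd.DataFrame(
        {"group": groups, "patient_id": ""},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return MethylationDataset(
        values=pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        manifest=manifest,
        samples=samples,
        scale="M",
    )
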