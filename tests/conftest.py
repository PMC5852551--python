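import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from empaikit import normalize
from empaikit.io_tables import AbundanceMatrix, PipelineConfig, ProteinRecord
from empaikit.synthetic import (
    SimulationConfig,
    default_pipeline_config,
    generate_dataset,
    generate_worked_example,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def worked_example():
    return generate_worked_example()


@pytest.fixture(scope="session")
def worked_normalized(worked_example):
    return normalize.normalize_empai(worked_example["matrix"], worked_example["config"])


@pytest.fixture(scope="session")
def synthetic_dataset():
    """One study-scale synthetic dataset with a fixed seed."""
    scfg = SimulationConfig(seed=7)
    matrix, records, truth = generate_dataset(scfg)
    cfg = default_pipeline_config(scfg, truth)
    return scfg, matrix, records, truth, cfg


@pytest.fixture(scope="session")
def synthetic_normalized(synthetic_dataset):
    _, matrix, _, _, cfg = synthetic_dataset
    return normalize.normalize_empai(matrix, cfg)


@pytest.fixture()
def toy_matrix():
    """3 proteins x 2 conditions with one undetected cell."""
    df = pd.DataFrame(
        {"base": [1.0, 1.0, 2.0], "alt": [2.0, 0.0, 2.0]},
        index=["P1", "P2", "P3"],
    )
    return AbundanceMatrix(df, baseline="base")


@pytest.fixture()
def toy_records():
    return [
        ProteinRecord("P1", "c1", 1, arcog_id="g1", category="E"),
        ProteinRecord("P2", "c1", 2, arcog_id="g1", category="E"),
        ProteinRecord("P3", "c1", 3, arcog_id=None, category="J"),
    ]


@pytest.fixture()
def default_config():
    return PipelineConfig()


def make_records(detected_flags, contig="c1", start=1):
    """Annotation records for a run of genes; flags only name the loci."""
    return [
        ProteinRecord(f"L{i:03d}", contig, start + i)
        for i in range(len(detected_flags))
    ]


def lpai_matrix(lpai: np.ndarray, conditions, loci, baseline, pseudo=1e-3):
    """NormalizedMatrix built directly from an lPAI array (detected where
    lpai > log10(pseudo))."""
    lp = pd.DataFrame(lpai, index=loci, columns=conditions)
    detected = lp > np.log10(pseudo)
    nempai = pd.DataFrame(
        np.where(detected, 10.0**lp.values, 0.0), index=loci, columns=conditions
    )
    return normalize.NormalizedMatrix(
        nempai, lp, detected, baseline, scale_count=len(loci), pseudo_abundance=pseudo
    )
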