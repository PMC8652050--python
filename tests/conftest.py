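import numpy as np
import pandas as pd
import pytest

from irsplice.descriptors import ExpressionMatrix, PsiMatrix
from irsplice.synthetic import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_config():
    """A fast planted cohort used across integration tests."""
    return SimConfig(
        n_cancer_types=19,
        samples_per_type=20,
        n_events=120,
        n_genes=120,
        n_isoforms=60,
        n_splicing_factors=30,
        reports_per_type=5000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture
def toy_psi():
    """3 genes x 4 events x 6 samples, hand-checkable PSI matrix."""
    samples = [f"S{i}" for i in range(6)]
    psi = pd.DataFrame(
        [
            [0.50, 0.60, np.nan, 0.70, 0.55, 0.65],   # gA, EX
            [0.10, np.nan, 0.15, np.nan, 0.12, 0.20], # gA, RI
            [0.85, 0.90, 0.88, np.nan, np.nan, 0.82], # gB, AS3
            [np.nan, 0.30, 0.35, 0.40, np.nan, 0.45], # gC, MEX
        ],
        index=["e1", "e2", "e3", "e4"],
        columns=samples,
    )
    events = pd.DataFrame(
        {"gene": ["gA", "gA", "gB", "gC"], "mode": ["EX", "RI", "AS3", "MEX"]},
        index=psi.index,
    )
    return PsiMatrix(psi=psi, events=events)


@pytest.fixture
def toy_sample_map():
    return pd.Series(
        {"S0": "T1", "S1": "T1", "S2": "T1", "S3": "T2", "S4": "T2", "S5": "T2"},
        name="cancer_type",
    )


def random_filtered_psi(rng, n_events=20, n_samples=15):
    """A random PSI matrix that already satisfies the event filters."""
    vals = rng.uniform(0.05, 0.95, size=(n_events, n_samples))
    mask = rng.random((n_events, n_samples)) < 0.3
    vals = np.where(mask, np.nan, vals)
    # guarantee the >10-sample detection rule
    vals[:, :11] = np.where(np.isnan(vals[:, :11]),
                            rng.uniform(0.05, 0.95, (n_events, 11)), vals[:, :11])
    genes = rng.choice([f"g{i}" for i in range(6)], size=n_events)
    modes = rng.choice(["AS3", "AS5", "EX", "MEX", "RI"], size=n_events)
    idx = [f"e{i}" for i in range(n_events)]
    return PsiMatrix(
        psi=pd.DataFrame(vals, index=idx, columns=[f"S{j}" for j in range(n_samples)]),
        events=pd.DataFrame({"gene": genes, "mode": modes}, index=idx),
    )


@pytest.fixture
def toy_expression():
    tpm = pd.DataFrame(
        {
            "S0": [50.0, 8.0, 0.0, 100.0],
            "S1": [50.0, 6.0, 0.0, 1.0],
            "S2": [50.0, 7.0, 0.0, 1.5],
            "S3": [50.0, 5.0, 12.0, 1.8],
        },
        index=["kept_high", "low_max", "low_median", "high_max_low_median"],
    )
    return ExpressionMatrix(tpm=tpm, kind="gene")
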