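import numpy as np
import pandas as pd
import pytest

from methvar import preprocess as pp
from methvar.simulate import simulate_experiment, small_config


@pytest.fixture(scope="session")
def small_experiment():
    """One small simulated experiment shared by read-only tests."""
    return simulate_experiment(small_config(seed=11))


@pytest.fixture(scope="session")
def small_matrix(small_experiment):
    """Preprocessed (filtered, log2) matrix of the small experiment."""
    probes, annotation, clinical, truth = small_experiment
    matrix, beta, qc_report, filter_report = pp.preprocess_pipeline(
        probes, sequence_class=annotation["sequence_class"]
    )
    return matrix


@pytest.fixture(scope="session")
def small_beta(small_matrix):
    return pp.beta_transform(small_matrix)


def make_matrix(values: np.ndarray, n_tumors: int, n_controls: int, prefix="S"):
    """Tiny hand-rolled MethylationMatrix for unit tests."""
    n_seq = values.shape[0]
    samples = [f"{prefix}T{i}" for i in range(n_tumors)] + [
        f"{prefix}C{i}" for i in range(n_controls)
    ]
    idx = pd.Index([f"Q{i:04d}" for i in range(n_seq)], name="sequence_id")
    return pp.MethylationMatrix(
        values=pd.DataFrame(values, index=idx, columns=samples),
        sequence_class=pd.Series("CpG", index=idx),
        sample_groups=pd.Series(
            ["tumor"] * n_tumors + ["control"] * n_controls,
            index=pd.Index(samples, name="sample_id"),
        ),
    )
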