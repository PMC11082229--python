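import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from deabench import ContrastDesign, ExpressionMatrix, SimulationConfig, ViewConfig
from deabench.simulate import simulate_spikein

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(values, scale="log2", matrix_type="LFQ", setting="generic",
                proteins=None, samples=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return ExpressionMatrix(
        protein_ids=proteins or [f"P{i}" for i in range(n)],
        sample_ids=samples or [f"S{j}" for j in range(m)],
        values=values,
        scale=scale,
        matrix_type=matrix_type,
        setting=setting,
    )


@pytest.fixture
def two_group_design():
    group_of = {f"S{j}": ("A" if j < 3 else "B") for j in range(6)}
    return ContrastDesign(group_of=group_of, contrast=("A", "B"))


@pytest.fixture(scope="session")
def spikein_dataset():
    """One small simulated spike-in dataset shared across tests."""
    cfg = SimulationConfig(
        n_proteins=500,
        views=(
            ViewConfig("dlfq", noise_sd=0.075, missing_rate=0.17),
            ViewConfig("LFQ", noise_sd=0.075, missing_rate=0.17),
            ViewConfig("top3", noise_sd=0.12, missing_rate=0.17),
        ),
    )
    return simulate_spikein(cfg, seed=11)
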