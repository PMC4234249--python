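import pysam
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from smvkit.caller import CallerConfig, call_sample
from smvkit.simulator import SimulationConfig, simulate_sample


@pytest.fixture(scope="session")
def clean_sim(tmp_path_factory):
    """Error-free simulation: 150 loci, 20% het, depth 50."""
    d = tmp_path_factory.mktemp("clean_sim")
    cfg = SimulationConfig(n_loci=150, per_base_error=0.0, het_fraction=0.2, seed=101)
    reference, catalogue, truth, bam = simulate_sample(cfg, str(d))
    return cfg, reference, catalogue, truth, bam


@pytest.fixture(scope="session")
def clean_calls(clean_sim):
    cfg, reference, catalogue, truth, bam = clean_sim
    with pysam.AlignmentFile(bam) as af:
        calls = call_sample(af, catalogue, CallerConfig(), reference=reference)
    return calls


@pytest.fixture(scope="session")
def noisy_sim(tmp_path_factory):
    """1% per-base error, 5% het, planted subclonal minors at 10% of loci."""
    d = tmp_path_factory.mktemp("noisy_sim")
    cfg = SimulationConfig(
        n_loci=200, per_base_error=0.01, het_fraction=0.05,
        minor_planting_rate=0.10, seed=202,
    )
    reference, catalogue, truth, bam = simulate_sample(cfg, str(d))
    return cfg, reference, catalogue, truth, bam


@pytest.fixture(scope="session")
def noisy_calls(noisy_sim):
    cfg, reference, catalogue, truth, bam = noisy_sim
    with pysam.AlignmentFile(bam) as af:
        calls = call_sample(af, catalogue, CallerConfig(), reference=reference)
    return calls
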