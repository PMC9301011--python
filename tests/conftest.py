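import numpy as np
import pytest

from meriplite import PipelineConfig, plant_m6a_sites, run_pipeline, simulate_fragments, simulate_genome


@pytest.fixture(scope="session")
def small_sim():
    """50-gene simulated dataset with planted up/down/unchanged sites."""
    genes, genome = simulate_genome(50, seed=7)
    truth = plant_m6a_sites(
        genes, genome, beta_range=(8.0, 8.0), fraction_up=0.25, fraction_down=0.25,
        fold=3.0, seed=7,
    )
    libs = simulate_fragments(truth, depth=20_000, seed=7)
    return genes, genome, truth, libs


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """Full study-scale pipeline run: 200 planted sites (50 up at fold 3,
    50 down at fold 1/3, 100 unchanged), beta 8, depth 1e5 per library,
    2 replicates per condition."""
    outdir = tmp_path_factory.mktemp("study")
    cfg = PipelineConfig(outdir=str(outdir), seed=11)
    summary = run_pipeline(cfg)
    return cfg, summary, outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
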