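import numpy as np
import pandas as pd
import pytest

from transchrom.core_io import CountMatrix
from transchrom.simulate import SimulationConfig, build_genome_layout, simulate

DEFAULT_SEED = 20240901


@pytest.fixture(scope="session")
def tiny_config():
    return SimulationConfig(
        n_chromosomes=1,
        chrom_length_bp=20_000_000,
        n_genes=30,
        n_peaks=80,
        n_interactions=60,
        n_trans_targets=12,
        n_cis_targets=12,
        n_trans_egenes=4,
        replicates_per_strain=2,
        library_size=20_000.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_layout(tiny_config):
    return build_genome_layout(tiny_config)


@pytest.fixture(scope="session")
def default_config():
    # the end-to-end recovery configuration: ~2,000 peaks, 300 trans-targets,
    # 84% D2-repressive, 2 log2-unit effects, phi = 0.05, d_true = -1, 3 reps
    return SimulationConfig(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_sim(default_config):
    return simulate(default_config)


@pytest.fixture(scope="session")
def default_pipeline(tmp_path_factory):
    from transchrom.pipeline import run_pipeline

    outdir = tmp_path_factory.mktemp("pipeline")
    report = run_pipeline(
        {"seed": DEFAULT_SEED, "outdir": str(outdir), "thresholds": {"n_perm": 50}}
    )
    return outdir, report


def make_counts(values, features=None, samples=None) -> CountMatrix:
    values = np.asarray(values)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return CountMatrix(pd.DataFrame(values, index=features, columns=samples))
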