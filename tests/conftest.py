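import logging
import warnings

import pytest

from agosort.pipeline import run_synthetic_pipeline
from agosort.simulate import SimulationParams, paper_like_config

logging.disable(logging.WARNING)
warnings.filterwarnings("ignore", message=".*empty collapsed FASTA.*")


@pytest.fixture(scope="session")
def small_params():
    return SimulationParams(
        n_loci=12,
        seed=11,
        arm_asymmetry_sd=2.0,
        ago1_logit_bias={"five_prime_U": 1.0, "five_prime_C": -1.0,
                         "mismatch_pos9": 0.5, "mismatch_3prime_end": -0.5,
                         "is_star": -1.0},
        mono_addition_prob={"total": 0.1, "ago1": 0.1, "ago2": 0.35},
        trim_prob=0.1,
        upregulated_cluster={"size": 2, "fold": 8.0, "onset_h": 12},
        background_fraction={"total": 0.4, "ago1": 0.1, "ago2": 0.4},
        library_depth=30_000,
    )


@pytest.fixture(scope="session")
def small_pipeline(small_params):
    return run_synthetic_pipeline(small_params)


@pytest.fixture(scope="session")
def paper_params():
    return paper_like_config(library_depth=200_000, seed=1)


@pytest.fixture(scope="session")
def paper_pipeline(paper_params):
    return run_synthetic_pipeline(paper_params)
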