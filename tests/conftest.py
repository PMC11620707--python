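import numpy as np
import pytest

from semdecode import pipeline, synth


@pytest.fixture(scope="session")
def lexicon():
    return synth.generate_lexicon(70, 5.0, seed=7)


@pytest.fixture(scope="session")
def small_lexicon():
    return synth.generate_lexicon(30, 5.0, seed=3)


@pytest.fixture(scope="session")
def default_trials(lexicon):
    return synth.build_priming_design(lexicon, 14, 28, (5.0, 7.0), seed=11)


@pytest.fixture(scope="session")
def small_config():
    """A fast two-ROI pipeline configuration for end-to-end tests."""
    return pipeline.validate_config({
        "n_subjects": 6, "grid": (12, 12, 8), "n_permutations": 200,
        "motor_repetitions": 8, "n_word_pairs": 6, "n_pseudo_pairs": 12,
        "n_per_category": 30, "cluster_p": 0.01, "cluster_extent": 5,
        "rois": [
            {"name": "a", "center": (3, 3, 4), "n_voxels": 40,
             "rho_within": 0.6, "rho_across": 0.0,
             "mean_offsets": {"ToolUnprimed": 0.5}},
            {"name": "b", "center": (8, 8, 4), "n_voxels": 30},
        ],
        "seed": 11,
    })


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
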