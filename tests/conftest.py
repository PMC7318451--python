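import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))

import copyvar as cv


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def sim_sample():
    """One simulated sample: genome pair, truth, depth tracks, evidence."""
    events = (
        cv.CNVEvent("DEL", 5000, 0, tandem=True),
        cv.CNVEvent("DUP", 4000, 3, tandem=False),
        cv.CNVEvent("DUP", 3000, 2, tandem=True),
    )
    config = cv.SimConfig(
        genome_length=300_000, cnv_events=events, mean_depth=50.0, seed=7
    )
    reference, sample, truth = cv.simulate_genome_with_cnvs(config)
    tracks, evidence = cv.simulate_depth_track(truth, config)
    return config, reference, sample, truth, tracks, evidence
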