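import numpy as np
import pytest

from sleeptriage import (
    annotate, calibrate_swr, classify_epochs, default_tree,
    extract_recording_features, generate_hypnogram, normalize_features,
    segment_epochs, smooth, synthesize_recording,
)
from sleeptriage.reliability import LEVEL1


@pytest.fixture(scope="session")
def fixture500():
    """One 500-epoch synthetic night run through the full pipeline.

    Shared across tests because feature extraction over 500 epochs is the
    expensive step; everything downstream is cheap.
    """
    truth = generate_hypnogram(500, seed=1)
    rec = synthesize_recording(truth, seed=2)
    grid = segment_epochs(rec)
    norm = normalize_features(extract_recording_features(grid))
    raw = classify_epochs(norm, default_tree())
    auto = smooth(raw)
    cal = calibrate_swr(norm, truth)  # training step on the expert labels
    ann = annotate(raw, norm, cal, LEVEL1)
    return {"truth": truth, "norm": norm, "raw": raw, "auto": auto,
            "cal": cal, "ann": ann}


@pytest.fixture(scope="session")
def random_hypnogram_suite():
    """Seeded random stage sequences (varied lengths) for oracle checks."""
    rng = np.random.default_rng(20240901)
    stages = np.array(["W", "N1", "N2", "N3", "R"])
    suite = []
    for _ in range(1000):
        n = int(rng.integers(1, 201))
        suite.append(list(stages[rng.integers(0, 5, size=n)]))
    return suite
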