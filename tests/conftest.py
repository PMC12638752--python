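import numpy as np
import pytest

import ratstates as rs

FS = 250.0


@pytest.fixture(scope="session")
def truth5():
    """Planted 5-state ground truth: 19 channels, orthogonal maps, SNR 5."""
    return rs.make_ground_truth(k=5, n_channels=19, snr=5.0, seed=1)


@pytest.fixture(scope="session")
def rec5(truth5):
    """120-s recording rendered from the planted 5-state process."""
    labels = rs.simulate_state_sequence(truth5, 120.0, FS)
    return rs.simulate_recording(truth5, labels, FS)


@pytest.fixture(scope="session")
def planted_labels(truth5):
    return rs.simulate_state_sequence(truth5, 120.0, FS)


@pytest.fixture(scope="session")
def model5(rec5):
    """AAHC model at K=5 fitted on the 120-s recording's GFP peaks."""
    return rs.fit_recording(rec5, 5)[5]


@pytest.fixture(scope="session")
def noiseless_rec():
    """Short noise-free recording with known labels (for exact checks)."""
    truth = rs.make_ground_truth(k=4, n_channels=10, snr=np.inf, seed=3)
    truth.noise_sd = 0.0
    labels = rs.simulate_state_sequence(truth, 10.0, FS)
    rec = rs.simulate_recording(truth, labels, FS)
    return truth, labels, rec


def match_maps(estimated: np.ndarray, planted: np.ndarray) -> np.ndarray:
    """Best one-to-one |spatial correlation| matching, sorted ascending."""
    from scipy.optimize import linear_sum_assignment

    corr = np.abs(
        np.array([[rs.spatial_correlation(e, p, ignore_polarity=False)
                   for p in planted] for e in estimated]))
    r, c = linear_sum_assignment(-corr)
    return np.sort(corr[r, c])
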