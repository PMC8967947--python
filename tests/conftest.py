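import math

import numpy as np
import pytest

import zpfdcnn as z

#: fixture-scale recipe: small widths and a larger learning rate so the few
#: optimisation steps available at tiny sample counts suffice to converge.
SMALL_NET = dict(conv_channels=(8, 16), fc_width=128)
SMALL_TRAIN = dict(learning_rate=1e-2, batch_size=32)


@pytest.fixture(scope="session")
def codebook8():
    """8-target BETA-like codebook: 8.0-9.4 Hz in 0.2 Hz steps."""
    return z.make_codebook(f_min=8.0, f_max=9.4, step=0.2,
                           phase_step=0.5 * math.pi)


@pytest.fixture(scope="session")
def noiseless_epochs(codebook8):
    """Noiseless two-harmonic epochs, 4 blocks, fixed latency."""
    cfg = z.SimulationConfig(noise_snr_db=math.inf, n_blocks=4, seed=7,
                             latency_sd_s=0.0)
    return z.simulate_epochs(codebook8, cfg)


@pytest.fixture(scope="session")
def noisy_epochs(codebook8):
    """Moderate-noise epochs used by training-based tests."""
    cfg = z.SimulationConfig(noise_snr_db=-8.0, n_blocks=10, seed=11)
    return z.simulate_epochs(codebook8, cfg)


@pytest.fixture(scope="session")
def noiseless_features(noiseless_epochs, codebook8):
    """Feature tensor + labels from the noiseless epochs (2 bands)."""
    segs = z.sliding_segments(noiseless_epochs, 1.0, 0.13, 0.1)
    X = np.array([z.build_feature_matrix(s, codebook8, n_bands=2).values
                  for s in segs])
    y = np.array([s.label for s in segs])
    return X, y
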