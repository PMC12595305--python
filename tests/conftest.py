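import numpy as np
import pytest

from fibrilkit import simulate


@pytest.fixture(scope="session")
def silac_noisefree():
    """Small noise-free SILAC table with its ground truth."""
    cfg = simulate.SilacSimConfig(
        n_proteins=20, intensity_cv=0.0, detection_dropout=0.0, seed=3
    )
    return simulate.gen_silac_table(cfg)


@pytest.fixture(scope="session")
def red_decay_trace():
    """Noise-free photoswitch trace with a 24 h red half-life."""
    cfg = simulate.TraceSimConfig(
        duration_h=48.0, sampling_h=0.5, noise_cv=0.0, switch_time_h=0.0
    )
    return simulate.gen_traces(cfg)


@pytest.fixture(scope="session")
def fibril_image():
    """High-SNR synthetic fibril image: 4 cells x 3 fibrils, non-crossing."""
    cfg = simulate.FibrilImageSimConfig(seed=5, min_separation_px=8)
    return simulate.gen_fibril_image(cfg)
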