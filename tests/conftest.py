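import numpy as np
import pytest

from valvephenoquant import synthetic as syn


@pytest.fixture(scope="session")
def aligned_doppler_gt():
    """Noise-free ground truth whose sample grid hits the waveform peak
    exactly: T = 0.125 s, T_ej = 0.04 s, peak at t = 0.02 s = sample 160."""
    return syn.DopplerGroundTruth(
        peak_velocity=1000.0,
        heart_rate=480.0,
        ejection_fraction_of_cycle=0.32,
        n_cycles=3,
        noise_sd=0.0,
        sampling_rate=8000.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def nuclei_field():
    """100 nuclei, 10 touching pairs, planted Runx2 positivity 0.55."""
    coverages = np.array([0.8] * 55 + [0.2] * 45)
    np.random.default_rng(42).shuffle(coverages)
    gt = syn.FluorescenceGroundTruth(
        n_nuclei=100,
        n_touching_pairs=10,
        marker_coverage_per_nucleus=tuple(coverages),
        noise_sd=100.0,
        seed=7,
    )
    return gt, syn.simulate_fluorescence(gt)
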