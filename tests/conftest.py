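import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def brute_force_runs(intensities, threshold):
    """Independent enumeration of maximal supra-threshold pixel runs."""
    runs = []
    start = None
    for i, v in enumerate(intensities):
        if v > threshold and start is None:
            start = i
        elif v <= threshold and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(intensities)))
    return runs


def brute_force_detect(scan, min_width_um, k_sd, bg_mean, bg_sd):
    """Oracle puncta caller: run enumeration + width filter, nothing shared
    with the implementation's segmentation code."""
    t = bg_mean + k_sd * bg_sd
    keep = []
    for start, stop in brute_force_runs(scan.intensities, t):
        if (stop - start) * scan.pixel_size_um >= min_width_um:
            keep.append((start, stop))
    return keep
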