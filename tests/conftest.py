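import numpy as np
import pytest

import firmap as fm


@pytest.fixture(scope="session")
def brain64():
    """The default 64x64 brain-like phantom: noiseless, direct sampling."""
    spec = fm.default_brain_spec()
    gt, times, radial, gridded = fm.simulate_dataset(spec)
    return {"spec": spec, "gt": gt, "times": times, "radial": radial, "gridded": gridded}


@pytest.fixture(scope="session")
def small_phantom():
    """A 32x32 two-coil phantom for fast reconstructor-level tests."""
    spec = fm.default_brain_spec(n=32, n_proj=200, n_coil=2)
    gt, times, radial, gridded = fm.simulate_dataset(spec)
    return {"spec": spec, "gt": gt, "times": times, "radial": radial, "gridded": gridded}


@pytest.fixture
def times999():
    """The scanner-like inversion time axis: TE 2.5 ms, TR 6 ms, 999 frames."""
    return fm.InversionTimeAxis(2.5 + 6.0 * np.arange(999))


def roi_errors(t1_map, roi_masks, truths):
    """Relative ROI-mean error (percent) per tissue label."""
    tab = fm.roi_stats(t1_map, roi_masks)
    out = {}
    for label, truth in truths.items():
        mean = tab.loc[tab.roi == label, "mean"].iloc[0]
        out[label] = 100.0 * abs(mean - truth) / truth
    return out
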