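import numpy as np
import pytest

from agdep import stimuli, synth


@pytest.fixture(scope="session")
def inventory():
    return stimuli.sample_tone_inventory(1)


@pytest.fixture(scope="session")
def geometry():
    return synth.HeadGeometry()


@pytest.fixture(scope="session")
def template(geometry):
    """Head template: crop around a front-facing head, standing in for
    the photograph-from-above template the coder uses on real video."""
    frame = synth.render_frame(0.0, (60.0, 80.0), geometry)
    ext = int(np.ceil(geometry.extent_px)) + 2
    return frame[60 - ext : 60 + ext, 80 - ext : 80 + ext]
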