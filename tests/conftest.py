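import numpy as np
import pytest

from retinasample import synth
from retinasample.events import Fixation
from retinasample.geometry import default_geometry
from retinasample.synth import GazeTrace


@pytest.fixture(scope="session")
def geometry448():
    return default_geometry(448)


@pytest.fixture(scope="session")
def geometry224():
    return default_geometry(224)


@pytest.fixture(scope="session")
def small_cohort():
    """Six identities with stimuli at 224 px plus the region mask."""
    identities, stimuli = synth.generate_identities(6, image_size=224, seed=3)
    mask = synth.build_region_mask(224)
    return identities, stimuli, mask


def make_trace(segments, rate_hz=250.0, participant_id="p0", trial_id="t0",
               spotlight_pct=100):
    """Build a noise-free trace from (x, y, n_samples, valid) segments."""
    xs, ys, vs = [], [], []
    for x, y, n, *rest in segments:
        valid = rest[0] if rest else True
        xs += [float(x)] * n
        ys += [float(y)] * n
        vs += [valid] * n
    t = np.arange(len(xs)) * 1000.0 / rate_hz
    return GazeTrace(participant_id=participant_id, trial_id=trial_id,
                     spotlight_pct=spotlight_pct, t_ms=t,
                     x_px=np.array(xs), y_px=np.array(ys),
                     valid=np.array(vs, dtype=bool), rate_hz=rate_hz)


def oracle_trace_and_events(geometry):
    """A hand-constructed trace whose fixation list is derived by hand.

    At 250 Hz (dt = 4 ms) with the 448-px default geometry (~33.3 px/deg):

    * dwell 1: 101 samples at (100, 100) -> fixation [0, 400] ms;
    * 2 saccade samples (~375 deg/s) to (200, 100);
    * 11 samples at (200, 100): the first still carries saccade speed, so the
      run is [412, 452] ms = 40 ms -> removed by the 50 ms minimum;
    * 2 saccade samples to (300, 100);
    * 50 samples at (300, 100): run [464, 660] ms;
    * 13 invalid samples (blink-like dropout);
    * 51 samples at (310, 100): the first sample's speed over the gap is
      10 px / 56 ms ~ 5.4 deg/s < 30, so the run is [716, 916] ms. Distance to
      the previous run is 10 px ~ 0.3 deg <= 0.5 deg and the gap is
      56 ms <= 75 ms -> merged into [464, 916] ms with duration-weighted
      centroid x = (300*196 + 310*200) / 396;
    * 2 saccade samples to (100, 300);
    * 100 samples at (100, 300): the first carries saccade speed, so the run
      is [928, 1324] ms.
    """
    trace = make_trace([
        (100, 100, 101),
        (150, 100, 1), (200, 100, 1),
        (200, 100, 11),
        (250, 100, 1), (300, 100, 1),
        (300, 100, 50),
        (0, 0, 13, False),
        (310, 100, 51),
        (200, 200, 1), (100, 300, 1),
        (100, 300, 100),
    ])
    expected = [
        Fixation(onset=0.0, offset=400.0, x=100.0, y=100.0),
        Fixation(onset=464.0, offset=916.0,
                 x=(300.0 * 196 + 310.0 * 200) / 396.0, y=100.0),
        Fixation(onset=928.0, offset=1324.0, x=100.0, y=300.0),
    ]
    return trace, expected
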