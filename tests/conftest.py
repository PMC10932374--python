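import numpy as np
import pytest

import relaxmap as rm

#: printed worked-example saturation-recovery data (T1 = 2250 ms)
WORKED_TR_MS = [500, 700, 1000, 1500, 2000, 3000, 5000, 10000, 15000]
WORKED_IS_T1 = [0.1993, 0.2674, 0.3588, 0.4866, 0.5889, 0.7364,
                0.8916, 0.9883, 0.9987]


@pytest.fixture(scope="session")
def tr_schedule():
    return np.array(rm.T1_TR_SCHEDULE_MS)


@pytest.fixture(scope="session")
def te_schedule():
    return np.array(rm.T2_TE_SCHEDULE_MS)


@pytest.fixture(scope="session")
def small_phantom_maps():
    """A 64x64 capillary phantom with 4 capillaries, for fast geometry tests."""
    spec = rm.PhantomSpec(fov_mm=20.0, matrix=64, tube_inner_diameter_mm=13.8,
                          capillary_count=4, seed=0)
    return rm.build_phantom(spec)


@pytest.fixture(scope="session")
def uniform_t1_series():
    """Noiseless 16x16 T1-protocol stack with uniform T1 = 800 ms."""
    maps = rm.ParameterMaps(
        pd=np.full((16, 16), 1.0),
        t1_ms=np.full((16, 16), 800.0),
        t2_ms=np.full((16, 16), 2000.0),
        labels=np.ones((16, 16), dtype=np.int32),
        pixel_spacing_mm=1.0,
    )
    return rm.simulate_series(maps, rm.t1_schedule(te_ms=0.0), noise_sigma=0.0,
                              seed=0, intensity_scale=None)


@pytest.fixture()
def synthetic_series():
    """A small integer-valued 3-frame T1 series for I/O round-trips."""
    rng = np.random.default_rng(42)
    frames = [
        rm.AcquisitionFrame(
            pixels=rng.integers(0, 4000, size=(12, 10)).astype(float),
            tr_ms=tr, te_ms=3.0, pixel_spacing_mm=(0.5, 0.5),
            slice_thickness_mm=1.0, frame_id=f"synthetic-{tr}",
        )
        for tr in (500.0, 1500.0, 5000.0)
    ]
    return rm.ImageSeries(frames=frames, mode=rm.T1_PROTOCOL,
                          fixed_parameter_ms=3.0)
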