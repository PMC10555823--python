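import dataclasses

import pytest

import tiltmontage as tm
from tiltmontage import fixtures as fx


@pytest.fixture(scope="session")
def bench_frame():
    """Benchmark-geometry camera: 5760 x 4092 px at 4.603 A/px."""
    return tm.CameraFrame(5760, 4092, 4.603)


@pytest.fixture(scope="session")
def bench_beam():
    return tm.BeamIllumination(3.15)


@pytest.fixture(scope="session")
def bench_pattern():
    """3 x 3 array at the printed piece-coordinate overlaps."""
    return tm.MontagePattern(3, 3, 1152, 576)


@pytest.fixture(scope="session")
def bench_scheme():
    return tm.TiltScheme(60.0, 3.0, group_size=3)


@pytest.fixture(scope="session")
def desk_dataset():
    """Desk-scale 3 x 3 x 21-tilt synthetic montage with 2 px jitter."""
    cfg = dataclasses.replace(fx.DESK, seed=11, jitter_px=2)
    return fx.make_montage_dataset(cfg)


@pytest.fixture(scope="session")
def bench_dose_map(bench_frame, bench_beam, bench_pattern, bench_scheme):
    """No-shift benchmark-geometry dose map at 2 e-/A^2 per tile per tilt."""
    plan = tm.build_exposure_plan(
        bench_frame, bench_beam, bench_pattern, bench_scheme, None, 2.0
    )
    return tm.simulate(plan)
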