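import pytest

from glucest.bloch import GLU_AMINE_POOL, WATER_POOL, PoolParameters
from glucest.phantom import (BRAIN, LEFT_HIPPOCAMPUS, RIGHT_HIPPOCAMPUS,
                             AcquisitionSchedule, build_phantom,
                             calibrate_contrast, forward_b1_pair,
                             forward_zspectrum_series)


@pytest.fixture(scope="session")
def schedule():
    return AcquisitionSchedule()


@pytest.fixture(scope="session")
def hippocampal_water():
    # matches the phantom's hippocampal tissue truth (T1 1900 ms, T2 50 ms)
    return PoolParameters(0.0, 0.0, 1.0, t1=1.9, t2=0.05)


@pytest.fixture(scope="session")
def calibrated_fractions(schedule, hippocampal_water):
    """Proton fractions for the contrasts used throughout the suite."""
    return {
        "hippo_5.02": calibrate_contrast(5.02, water=hippocampal_water,
                                         schedule=schedule),
        "brain_4.0": calibrate_contrast(4.0, schedule=schedule),
    }


@pytest.fixture(scope="session")
def noiseless_phantom():
    return build_phantom(shape=(48, 48), seed=1, tissue_jitter=0.0)


@pytest.fixture(scope="session")
def noiseless_acquisition(noiseless_phantom, schedule, calibrated_fractions):
    """CEST + WASSR + B1 pair forward-simulated without noise."""
    ph = noiseless_phantom
    fr = {BRAIN: calibrated_fractions["brain_4.0"],
          LEFT_HIPPOCAMPUS: calibrated_fractions["hippo_5.02"],
          RIGHT_HIPPOCAMPUS: calibrated_fractions["hippo_5.02"]}
    cest = forward_zspectrum_series(ph, schedule, fr, "cest")
    wassr = forward_zspectrum_series(ph, schedule, fr, "wassr")
    b1_pair = forward_b1_pair(ph)
    return {"phantom": ph, "fractions": fr, "cest": cest, "wassr": wassr,
            "b1_pair": b1_pair}


@pytest.fixture(scope="session")
def glu_pool():
    return GLU_AMINE_POOL


@pytest.fixture(scope="session")
def water_pool():
    return WATER_POOL
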