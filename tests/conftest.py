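import numpy as np
import pytest

from replifork import SegmentSet, StrainConfig, build_segments
from replifork.simulate import SimConfig, SpeedProfile


@pytest.fixture(scope="session")
def toy_strain() -> StrainConfig:
    """4 Mbp toy circle with round coordinates for hand-checkable arithmetic."""
    return StrainConfig(
        genome_length=4_000_000,
        oriC_pos=3_000_000,
        terA_pos=1_000_000,
        terC_pos=1_300_000,
        oriX_pos=2_150_000,
        ter_extension=50_000,
        name="toy",
    )


@pytest.fixture(scope="session")
def toy_segset(toy_strain) -> SegmentSet:
    return build_segments(toy_strain, 1000)


@pytest.fixture(scope="session")
def oriCX_strain() -> StrainConfig:
    return StrainConfig.mg1655_oriCX()


@pytest.fixture(scope="session")
def oriCX_segset(oriCX_strain) -> SegmentSet:
    return build_segments(oriCX_strain, 1000)


@pytest.fixture(scope="session")
def wt_strain() -> StrainConfig:
    return StrainConfig.mg1655()


@pytest.fixture()
def constant_speed_sim(oriCX_strain) -> SimConfig:
    """Noiseless two-origin culture at the canonical 1 kbp/s fork speed."""
    return SimConfig(
        strain=oriCX_strain,
        tau=3600.0,
        initiation_age=60.0,
        speeds=SpeedProfile.constant(1000.0),
        noise="none",
    )


@pytest.fixture()
def stepped_speed_sim(oriCX_strain) -> SimConfig:
    """Fork speed varying with the active-fork count (0.5/0.8/1.0 kbp/s)."""
    return SimConfig(
        strain=oriCX_strain,
        tau=3600.0,
        initiation_age=600.0,
        speeds=SpeedProfile.from_kbps(0.5, 0.8, 1.0),
        noise="none",
    )
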