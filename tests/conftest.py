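import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spatial2dms import (
    FragmentationPattern,
    PrecursorSpecies,
    ScanSchedule,
    TofInstrumentConfig,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tof_config() -> TofInstrumentConfig:
    return TofInstrumentConfig()


@pytest.fixture
def dual_slit(tof_config) -> FragmentationPattern:
    return FragmentationPattern(
        kind="dual_slit",
        fringe_spacing=2.0e-4,
        zone_length=tof_config.zone_length,
    )


@pytest.fixture
def small_schedule(tof_config) -> ScanSchedule:
    """A 4096-scan zone-splitting schedule (fast everywhere it suffices)."""
    return ScanSchedule.zone_splitting(tof_config, n_scans=4096)


@pytest.fixture
def single_precursor() -> list[PrecursorSpecies]:
    return [PrecursorSpecies(mz=1000.0, fragments=((500.0, 0.8),))]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230206)
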