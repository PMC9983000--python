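"""Side kick - delay - fragment - detect scan sequence (TOF variant).

Each scan line kicks the precursors laterally, waits an incrementally
stepped delay, samples the fragmentation pattern at every ion's position at
the start of the fragmentation period, and records the resulting fragment
intensities; stacking the scan lines gives one transient per fragment
channel whose modulation frequency encodes the precursor m/z.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _scanner
from .errors import ChannelLookupError, ConfigurationError, DomainError
from .kinematics import (
    IonState,
    PrecursorSpecies,
    TofInstrumentConfig,
    flight_time_from_mz,
    speed_from_potential,
)
from .patterns import FragmentationPattern, pattern_intensity

__all__ = [
    "ScanSchedule",
    "TransientCube",
    "ChannelTransient",
    "TofSpectrum",
    "run_tof_scan_sequence",
    "detect_fragments",
    "extract_channel_transient",
]


@dataclass(frozen=True)
class ScanSchedule:
    """The incremental-delay acquisition schedule.

    ``n_scans`` scan lines are acquired; scan ``k`` uses delay
    ``initial_delay + k * delay_increment``.
    """

    delay_increment: float
    n_scans: int = 32768
    initial_delay: float = 0.0

    def __post_init__(self) -> None:
        if self.n_scans < 2:
            raise ConfigurationError("n_scans must be >= 2")
        if not self.delay_increment > 0:
            raise ConfigurationError("delay increment must be positive")
        if self.initial_delay < 0:
            raise ConfigurationError("initial delay must be >= 0")

    @classmethod
    def zone_splitting(
        cls,
        config: TofInstrumentConfig,
        n_scans: int = 32768,
        mz_ref: float = 1000.0,
        charge: int = 1,
    ) -> "ScanSchedule":
        """Delay increment determined at initialization to split evenly
        across the fragmentation zone: the reference ion (default 1000 Th)
        traverses the zone exactly once over the full schedule, starting at
        the zone entry.
        """
        v = speed_from_potential(mz_ref, charge, config.v_kick)
        if v == 0:
            raise ConfigurationError("zone-splitting rule needs a nonzero kick")
        return cls(
            delay_increment=config.zone_length / (v * n_scans),
            n_scans=n_scans,
            initial_delay=config.zone_start / v,
        )

    @property
    def delays(self) -> np.ndarray:
        return self.initial_delay + np.arange(self.n_scans) * self.delay_increment


@dataclass
class TransientCube:
    """Scans x fragment-channel matrix of detected intensity.

    ``scan_axis`` holds the scanned parameter per scan line (delay in s for
    the TOF variant, pulse length in s for the sector variant) and must be
    strictly increasing and uniformly spaced; ``channel_kind`` distinguishes
    fragment channels from depleted-precursor channels.
    """

    intensity: np.ndarray
    scan_axis: np.ndarray
    channel_mz: np.ndarray
    channel_kind: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.scan_axis = np.asarray(self.scan_axis, dtype=float)
        self.channel_mz = np.asarray(self.channel_mz, dtype=float)
        self.channel_kind = np.asarray(self.channel_kind)
        if self.intensity.ndim != 2:
            raise ConfigurationError("intensity must be scans x channels")
        n_scans, n_chan = self.intensity.shape
        if self.scan_axis.shape != (n_scans,):
            raise ConfigurationError("scan axis length mismatch")
        if self.channel_mz.shape != (n_chan,) or self.channel_kind.shape != (n_chan,):
            raise ConfigurationError("channel axis length mismatch")
        if np.any(self.intensity < 0):
            raise ConfigurationError("intensities must be >= 0")
        steps = np.diff(self.scan_axis)
        if np.any(steps <= 0):
            raise ConfigurationError("scan axis must be strictly increasing")
        step = steps[0]
        # 1e-12 relative on the step, plus the float64 representation noise
        # of the axis values themselves
        tol = 1e-12 * abs(step) + 8 * np.finfo(float).eps * np.abs(self.scan_axis).max()
        if np.any(np.abs(steps - step) > tol):
            raise ConfigurationError("scan axis must be uniformly spaced")

    @property
    def n_scans(self) -> int:
        return self.intensity.shape[0]

    @property
    def scan_step(self) -> float:
        return float(self.scan_axis[1] - self.scan_axis[0])

    def fragment_channels(self) -> np.ndarray:
        """Column indices of fragment (non-precursor) channels."""
        return np.nonzero(self.channel_kind == _scanner.FRAGMENT)[0]


@dataclass(frozen=True)
class ChannelTransient:
    """One channel's intensity series with its scan-axis metadata."""

    values: np.ndarray
    scan_axis: np.ndarray
    fragment_mz: float
    matched_channels: tuple[float, ...]

    @property
    def scan_step(self) -> float:
        return float(self.scan_axis[1] - self.scan_axis[0])


def run_tof_scan_sequence(
    mixture: Sequence[PrecursorSpecies],
    config: TofInstrumentConfig,
    pattern: FragmentationPattern,
    schedule: ScanSchedule,
    mode: str = "deterministic",
    seed: Optional[int] = None,
    n_ions: int = 10000,
    collect_events: bool = True,
    event_log_path=None,
) -> tuple[TransientCube, Optional[pd.DataFrame]]:
    """Run the side kick - delay - fragment - detect sequence.

    For scan ``k`` each precursor sits at
    ``d = v_lateral * (t0 + k dt) - zone_start`` at the start of the
    fragmentation period and fragments with probability ``I(d)``.  In
    deterministic mode each fragment channel receives
    ``abundance * branching * I(d)`` exactly; in stochastic mode ``n_ions``
    ion copies per precursor fragment as independent Bernoulli(I) draws
    (reproducible for a given seed).  Unfragmented precursors are recorded
    on a depleted-precursor channel at ``abundance * (1 - I)``.

    Returns the transient cube and the per-scan event log (one row per
    precursor per scan: scan_index, ion_id, precursor_mz,
    lateral_position_m, fragmentation_intensity), also written as CSV when
    ``event_log_path`` is given.
    """
    mixture = list(mixture)
    if not mixture:
        raise ConfigurationError("mixture is empty")
    delays = schedule.delays
    positions = np.empty((len(mixture), schedule.n_scans))
    intensities = np.empty_like(positions)
    for pi, p in enumerate(mixture):
        state = IonState.after_kick(p, config)
        if state.lateral_speed == 0:
            raise ConfigurationError(
                f"precursor {p.mz} Th has zero lateral speed (kick off?)"
            )
        d = state.lateral_speed * delays - config.zone_start
        positions[pi] = d
        intensities[pi] = pattern_intensity(pattern, d)

    cube_arr, channel_mz, channel_kind, overlaps, events = _scanner.accumulate(
        mixture, positions, intensities, mode, seed, n_ions, collect_events
    )
    metadata = {
        "variant": "tof",
        "mode": mode,
        "seed": seed,
        "n_ions": n_ions if mode == "stochastic" else None,
        "config": asdict(config),
        "schedule": {
            "n_scans": schedule.n_scans,
            "delay_increment": schedule.delay_increment,
            "initial_delay": schedule.initial_delay,
        },
        "pattern": {
            "kind": pattern.kind,
            "fringe_spacing": pattern.fringe_spacing,
            "zone_length": pattern.zone_length,
            "phase_offset": pattern.phase_offset,
            "envelope": pattern.envelope,
        },
        "overlapping_channels": overlaps,
    }
    cube = TransientCube(cube_arr, delays, channel_mz, channel_kind, metadata)
    if events is not None and event_log_path is not None:
        events.to_csv(event_log_path, index=False)
    return cube, events


@dataclass(frozen=True)
class TofSpectrum:
    """One scan line mapped onto the detector flight-time axis."""

    time_bins: np.ndarray  # bin centers, s
    intensity: np.ndarray
    loss: float  # total intensity outside the detector window


def detect_fragments(
    channel_mz: np.ndarray,
    intensities: np.ndarray,
    config: TofInstrumentConfig,
    charge: int = 1,
    window: Optional[tuple[float, float]] = None,
    n_bins: int = 4096,
) -> TofSpectrum:
    """Map one scan's channel intensities onto the TOF detector axis.

    Each channel's flight time comes from the standard TOF relation; the
    intensities are binned onto a uniform time axis.  Total intensity is
    conserved except for channels whose flight time falls outside the
    detector window, which are dropped and tallied in ``loss``.
    """
    channel_mz = np.asarray(channel_mz, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if np.any(channel_mz <= 0):
        raise DomainError("fragment m/z values must be positive")
    if channel_mz.size == 0:
        return TofSpectrum(np.empty(0), np.empty(0), 0.0)
    times = np.array([flight_time_from_mz(m, config, charge) for m in channel_mz])
    if window is None:
        window = (0.0, 1.2 * times.max())
    inside = (times >= window[0]) & (times <= window[1])
    loss = float(intensities[~inside].sum())
    hist, edges = np.histogram(
        times[inside], bins=n_bins, range=window, weights=intensities[inside]
    )
    centers = 0.5 * (edges[:-1] + edges[1:])
    return TofSpectrum(centers, hist, loss)


def extract_channel_transient(
    cube: TransientCube, fragment_mz: float, tolerance: float = 0.0
) -> ChannelTransient:
    """Intensity series of the channel(s) within ``tolerance`` Th of
    ``fragment_mz`` (summed when several match), with scan-axis metadata.

    Raises
    ------
    ChannelLookupError
        If no channel matches; the message names the nearest channel.
    """
    diffs = np.abs(cube.channel_mz - fragment_mz)
    hit = diffs <= tolerance
    if not hit.any():
        nearest = cube.channel_mz[np.argmin(diffs)]
        raise ChannelLookupError(
            f"no channel within {tolerance} Th of {fragment_mz} Th "
            f"(nearest: {nearest} Th)"
        )
    values = cube.intensity[:, hit].sum(axis=1)
    return ChannelTransient(
        values=values,
        scan_axis=cube.scan_axis,
        fragment_mz=fragment_mz,
        matched_channels=tuple(float(m) for m in cube.channel_mz[hit]),
    )
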