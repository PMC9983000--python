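"""Pinned end-to-end reproduction experiments.

These functions assemble the reference configurations of the two
instrument variants, run the full simulate -> transform -> peak-pick chain,
and report the FWHM resolving power of a chosen precursor in the m/z
domain.  They are what the ``reproduce`` CLI subcommand and the acceptance
script execute.

Reference conditions
--------------------
TOF variant
    7 V side kick, 1000 V repeller, dual-slit cos^2 pattern with 0.2 mm
    fringe spacing over a 36 mm zone (181 maxima), 2^15 = 32768 scan lines
    with the delay increment set so the 1000 Th reference ion traverses the
    zone exactly once over the schedule.  The 1000 Th precursor then sweeps
    180 fringes, giving a precursor-dimension resolving power of about
    180 / (2 * 1.2067) ~ 75.

Sector variant
    3 V deflection across a 10 mm gap (300 V/m), entry from the 1000 V
    acceleration potential at zero entry angle, pulses stepped by 1 us for
    2^13 = 8192 runs.  The drift distance is solved so the 1000 Th ion
    sweeps exactly 2171 fringes (2172 maxima) over the schedule — below the
    Nyquist limit at 0.265 cycles/run — giving RP ~ 900 at 1000 Th, ~ 636
    at 2000 Th, and a ~12x resolving-power gain over the TOF variant with
    4x fewer scans.
"""

from __future__ import annotations

import math
from .constants import ATOMIC_MASS, ELEMENTARY_CHARGE
from .errors import ConfigurationError
from .ftproc import fft_magnitude, pick_peaks
from .kinematics import PrecursorSpecies, TofInstrumentConfig, speed_from_potential
from .patterns import FragmentationPattern
from .sector_engine import SectorConfig, run_sector_scan_sequence
from .tof_engine import (
    ScanSchedule,
    extract_channel_transient,
    run_tof_scan_sequence,
)

__all__ = [
    "tof_reference_setup",
    "sector_reference_setup",
    "reproduce_tof_rp",
    "reproduce_sector_rp",
    "reproduce",
    "EXPERIMENTS",
]

#: Fringes swept by the 1000 Th reference ion in the sector schedule
#: (2172 maxima, counting both ends of the sweep).
SECTOR_REFERENCE_FRINGES = 2171


def tof_reference_setup(
    mz: float = 1000.0,
    n_scans: int = 32768,
    fragment_mz: float = 500.0,
    branching: float = 0.8,
):
    """Reference TOF configuration plus a single-precursor mixture."""
    config = TofInstrumentConfig()
    pattern = FragmentationPattern(
        kind="dual_slit", fringe_spacing=2.0e-4, zone_length=config.zone_length
    )
    schedule = ScanSchedule.zone_splitting(config, n_scans=n_scans)
    mixture = [
        PrecursorSpecies(mz=mz, fragments=((fragment_mz, branching),))
    ]
    return mixture, config, pattern, schedule


def sector_reference_setup(
    mz: float = 1000.0,
    n_runs: int = 8192,
    fragment_mz: float = 500.0,
    branching: float = 0.8,
    mz_min_covered: float = 500.0,
):
    """Reference sector configuration plus a single-precursor mixture.

    The drift distance is solved so the 1000 Th ion crosses fringes at the
    reference rate of ``SECTOR_REFERENCE_FRINGES / 8191`` (~0.265) fringes
    per run — i.e. it sweeps exactly 2171 fringes over the full 8192-run
    schedule, and proportionally fewer over a shortened one, so the per-run
    modulation frequency is independent of ``n_runs``.  The pattern extent
    covers the larger deflection of ions down to ``mz_min_covered`` Th so
    that a 500-3000 Th survey stays on the pattern.
    """
    fringe_spacing = 2.0e-4
    base = SectorConfig(n_runs=n_runs)
    v_ref = speed_from_potential(1000.0, 1, base.entry_potential)
    # tan(theta_F) grows at k = eE/(m v_forward) per second of pulse
    k = ELEMENTARY_CHARGE * base.field / (1000.0 * ATOMIC_MASS * v_ref)
    fringes_per_run = SECTOR_REFERENCE_FRINGES / 8191.0
    drift = fringes_per_run * fringe_spacing / (k * base.pulse_step)
    config = SectorConfig(n_runs=n_runs, drift_distance=drift)
    extent = (
        fringes_per_run
        * (n_runs - 1)
        * fringe_spacing
        * math.sqrt(1000.0 / mz_min_covered)
        * 1.01
    )
    pattern = FragmentationPattern(
        kind="dual_slit", fringe_spacing=fringe_spacing, zone_length=extent
    )
    mixture = [
        PrecursorSpecies(mz=mz, fragments=((fragment_mz, branching),))
    ]
    return mixture, config, pattern


def _measure_rp(cube, fragment_mz: float) -> dict:
    transient = extract_channel_transient(cube, fragment_mz, tolerance=0.5)
    spectrum = fft_magnitude(transient, window="none", zero_fill=4)
    peaks = pick_peaks(spectrum, min_relative_height=0.2)
    if not peaks:
        raise ConfigurationError("no modulation peak found in the reference channel")
    peak = peaks[0]
    return {
        "rp_mz": float(peak.resolving_power_mz),
        "rp_f": float(peak.resolving_power_f),
        "frequency_cycles_per_scan": float(peak.frequency),
        "fwhm_cycles_per_scan": float(peak.fwhm),
        "n_scans": int(cube.n_scans),
    }


def reproduce_tof_rp(mz: float = 1000.0, n_scans: int = 32768) -> dict:
    """Run the reference TOF experiment and measure the precursor-dimension
    FWHM resolving power (m/z domain) at ``mz``."""
    mixture, config, pattern, schedule = tof_reference_setup(mz=mz, n_scans=n_scans)
    cube, _ = run_tof_scan_sequence(
        mixture, config, pattern, schedule, mode="deterministic", collect_events=False
    )
    out = _measure_rp(cube, mixture[0].fragments[0][0])
    out.update({"variant": "tof", "precursor_mz": mz})
    return out


def reproduce_sector_rp(mz: float = 1000.0, n_runs: int = 8192) -> dict:
    """Run the reference sector experiment and measure the
    precursor-dimension FWHM resolving power (m/z domain) at ``mz``."""
    mixture, config, pattern = sector_reference_setup(mz=mz, n_runs=n_runs)
    cube, _ = run_sector_scan_sequence(
        mixture, config, pattern, mode="deterministic", collect_events=False
    )
    out = _measure_rp(cube, mixture[0].fragments[0][0])
    out.update({"variant": "sector", "precursor_mz": mz})
    return out


def _rp_ratio() -> dict:
    tof = reproduce_tof_rp(1000.0)
    sector = reproduce_sector_rp(1000.0)
    return {
        "rp_tof_1000": tof["rp_mz"],
        "rp_sector_1000": sector["rp_mz"],
        "ratio": sector["rp_mz"] / tof["rp_mz"],
        "scan_ratio": tof["n_scans"] / sector["n_scans"],
    }


EXPERIMENTS = {
    "rp-tof-1000": lambda: reproduce_tof_rp(1000.0),
    "rp-tof-2300": lambda: reproduce_tof_rp(2300.0),
    "rp-sector-1000": lambda: reproduce_sector_rp(1000.0),
    "rp-sector-2000": lambda: reproduce_sector_rp(2000.0),
    "rp-ratio": _rp_ratio,
}


def reproduce(name: str) -> dict:
    """Run a named reference experiment end-to-end and return its summary."""
    try:
        runner = EXPERIMENTS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown experiment {name!r} (available: {sorted(EXPERIMENTS)})"
        ) from None
    return runner()
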