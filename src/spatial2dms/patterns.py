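"""Spatially periodic fragmentation-intensity patterns.

The fragmentation zone is illuminated with a banded light pattern (the
two-slit interference fringe system is the reference case).  An ion at
lateral position ``d`` captures a photon — and subsequently fragments — with
probability proportional to the local relative intensity ``I(d) in [0, 1]``.

For the ideal two-slit (equal-spacing, small-angle) fringe system

    I(d) = cos^2(pi (d - phase_offset) / Lambda)

with fringe spacing ``Lambda``; an optional far-field single-slit ``sinc^2``
visibility envelope can be applied but is off by default (slit widths are a
hardware detail, and the pure cos^2 law has maximal modulation depth and is
exactly analyzable).  An idealized sinusoidal grating produces the same
intensity law, so ``kind="grating"`` is an alias; arbitrary measured patterns
can be supplied as a tabulated position/intensity curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .constants import ATOMIC_MASS, ELEMENTARY_CHARGE
from .errors import ConfigurationError, DomainError, ParseError
from .kinematics import speed_from_potential

__all__ = [
    "FragmentationPattern",
    "pattern_intensity",
    "maxima_count",
    "modulation_frequency_tof",
    "calibration_constant_tof",
]

_KINDS = ("dual_slit", "grating", "custom_tabulated")


@dataclass(frozen=True)
class FragmentationPattern:
    """A spatially periodic relative light-intensity pattern over the zone.

    Parameters
    ----------
    kind :
        ``"dual_slit"`` (cos^2 fringes), ``"grating"`` (idealized sinusoidal
        grating — same law), or ``"custom_tabulated"``.
    fringe_spacing :
        Fringe spacing Lambda in m (distance between adjacent maxima).
    zone_length :
        Extent of the illuminated zone in m; ``I(d) = 0`` outside
        ``[0, zone_length]``.
    phase_offset :
        Position of the first intensity maximum relative to the zone start,
        in m; must lie in ``[0, Lambda)``.
    envelope :
        ``None`` or ``"sinc2"`` — a visibility envelope centered on the zone.
    table :
        For ``custom_tabulated``: ``(positions_m, relative_intensities)``
        arrays, intensities in ``[0, 1]``; evaluated by linear interpolation.
    """

    kind: str = "dual_slit"
    fringe_spacing: float = 2.0e-4
    zone_length: float = 0.036
    phase_offset: float = 0.0
    envelope: Optional[str] = None
    table: Optional[Tuple[np.ndarray, np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(f"unknown pattern kind {self.kind!r}")
        if not self.fringe_spacing > 0:
            raise ConfigurationError("fringe spacing must be positive")
        if not self.zone_length > 0:
            raise ConfigurationError("zone length must be positive")
        if not 0 <= self.phase_offset < self.fringe_spacing:
            raise ConfigurationError(
                "phase offset must lie in [0, fringe_spacing)"
            )
        if self.envelope not in (None, "sinc2"):
            raise ConfigurationError(f"unknown envelope {self.envelope!r}")
        if self.kind == "custom_tabulated":
            if self.table is None:
                raise ConfigurationError("custom_tabulated pattern needs a table")
            pos = np.asarray(self.table[0], dtype=float)
            val = np.asarray(self.table[1], dtype=float)
            if pos.ndim != 1 or pos.shape != val.shape or pos.size < 2:
                raise ConfigurationError("table must be two equal 1-D columns, n >= 2")
            if np.any(np.diff(pos) <= 0):
                raise ConfigurationError("table positions must be strictly increasing")
            if np.any(val < 0) or np.any(val > 1):
                raise ConfigurationError("table intensities must lie in [0, 1]")
            object.__setattr__(self, "table", (pos, val))

    @classmethod
    def from_csv(cls, path, zone_length: Optional[float] = None) -> "FragmentationPattern":
        """Load a ``custom_tabulated`` pattern from a two-column CSV
        (``position_m, relative_intensity``, with a header line)."""
        try:
            data = np.genfromtxt(path, delimiter=",", names=True)
        except Exception as exc:  # pragma: no cover - numpy error text varies
            raise ParseError(f"could not parse pattern CSV {path}: {exc}") from exc
        names = data.dtype.names
        if names is None or len(names) != 2:
            raise ParseError(f"{path}: expected two columns position_m,relative_intensity")
        pos = np.atleast_1d(data[names[0]]).astype(float)
        val = np.atleast_1d(data[names[1]]).astype(float)
        if zone_length is None:
            zone_length = float(pos[-1])
        spacing = _estimate_fringe_spacing(pos, val)
        return cls(
            kind="custom_tabulated",
            fringe_spacing=spacing,
            zone_length=zone_length,
            table=(pos, val),
        )


def _estimate_fringe_spacing(pos: np.ndarray, val: np.ndarray) -> float:
    """Median spacing between interior local maxima of a tabulated pattern,
    falling back to the table span when it is not periodic."""
    interior = np.nonzero((val[1:-1] >= val[:-2]) & (val[1:-1] > val[2:]))[0] + 1
    if interior.size >= 2:
        return float(np.median(np.diff(pos[interior])))
    return float(pos[-1] - pos[0])


def pattern_intensity(pattern: FragmentationPattern, d) -> np.ndarray | float:
    """Relative intensity ``I(d) in [0, 1]`` at lateral position(s) ``d``.

    Positions outside ``[0, zone_length]`` return 0.  Accepts scalars or
    arrays; vectorized.
    """
    d_arr = np.asarray(d, dtype=float)
    inside = (d_arr >= 0.0) & (d_arr <= pattern.zone_length)
    if pattern.kind == "custom_tabulated":
        pos, val = pattern.table  # type: ignore[misc]
        out = np.interp(d_arr, pos, val, left=0.0, right=0.0)
    else:
        phase = np.pi * (d_arr - pattern.phase_offset) / pattern.fringe_spacing
        out = np.cos(phase) ** 2
        if pattern.envelope == "sinc2":
            center = 0.5 * pattern.zone_length
            out = out * np.sinc((d_arr - center) / pattern.zone_length) ** 2
    out = np.where(inside, out, 0.0)
    if np.isscalar(d) or d_arr.ndim == 0:
        return float(out)
    return out


def maxima_count(pattern: FragmentationPattern, zone_length: Optional[float] = None) -> int:
    """Integer number of intensity maxima ``n`` inside ``[0, zone_length]``.

    For a periodic pattern with first maximum at ``phase_offset`` this is
    ``n = 1 + floor((zone_length - phase_offset) / Lambda)``.
    """
    L = pattern.zone_length if zone_length is None else zone_length
    if not L > 0:
        raise DomainError("zone length must be positive")
    if pattern.kind == "custom_tabulated":
        pos, val = pattern.table  # type: ignore[misc]
        m = (pos >= 0) & (pos <= L)
        v = np.where(m, val, -1.0)
        interior = (v[1:-1] >= v[:-2]) & (v[1:-1] > v[2:]) & m[1:-1]
        ends = 0
        if m[0] and val[0] > val[1]:
            ends += 1
        if m[-1] and val[-1] >= val[-2]:
            ends += 1
        return int(np.count_nonzero(interior)) + ends
    if pattern.phase_offset > L:
        return 0
    # guard against floating junk at exact multiples of the fringe spacing
    return 1 + int(math.floor((L - pattern.phase_offset) / pattern.fringe_spacing + 1e-9))


def modulation_frequency_tof(
    pattern: FragmentationPattern,
    mz: float,
    charge: int = 1,
    v_kick: float = 7.0,
) -> float:
    """Fragmentation-modulation frequency (Hz w.r.t. delay time) of a
    precursor drifting across the fringes: ``f = v_lateral / Lambda``.

    Since ``v_lateral = sqrt(2 e z v_kick / (m u))``, the frequency obeys the
    inverse-square-root law ``f = D / sqrt(m/z)`` with ``D`` given by
    :func:`calibration_constant_tof` — the same constant for all masses.
    """
    v_lat = speed_from_potential(mz, charge, v_kick)
    return v_lat / pattern.fringe_spacing


def calibration_constant_tof(
    pattern: FragmentationPattern, v_kick: float = 7.0, charge: int = 1
) -> float:
    """Calibration constant ``D = sqrt(2 e z v_kick / u) / Lambda`` in
    Hz * sqrt(Th), such that ``f = D / sqrt(m/z)``."""
    if v_kick < 0:
        raise DomainError("kick potential must be >= 0")
    return (
        math.sqrt(2.0 * ELEMENTARY_CHARGE * charge * v_kick / ATOMIC_MASS)
        / pattern.fringe_spacing
        / math.sqrt(charge)
    )
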