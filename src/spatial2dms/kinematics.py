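"""Closed-form ion kinematics in idealized uniform fields.

An ion of mass-to-charge ratio ``m/z`` (Th) accelerated through a potential
difference ``V`` acquires kinetic energy ``K_E = z e V`` and therefore speed

    v = sqrt(2 e V / ((m/z) u))

independent of the charge state, because both the energy gained and the mass
scale with ``z``.  The time-of-flight relation over a field-free flight tube
of length ``L`` follows as ``m/z = 2 e V t^2 / (u L^2)``.

The lateral "side kick" that disperses ions across the fragmentation zone is
modeled as an impulsive uniform-field acceleration through the kick potential
followed by field-free drift at constant lateral speed; axial (detection) and
lateral (kick/fragmentation) motions are treated as independent.  Fringe
fields and lens-stack aberrations are deliberately idealized away.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import ATOMIC_MASS, ELEMENTARY_CHARGE
from .errors import ConfigurationError, DomainError

__all__ = [
    "PrecursorSpecies",
    "TofInstrumentConfig",
    "IonState",
    "speed_from_potential",
    "lateral_position_at_delay",
    "is_in_zone",
    "flight_time_from_mz",
    "mz_from_flight_time",
]


@dataclass(frozen=True)
class PrecursorSpecies:
    """A precursor ion and its fragment channels.

    Parameters
    ----------
    mz :
        Mass-to-charge ratio in Th (Da per elementary charge).
    charge :
        Positive charge state in units of e.
    abundance :
        Relative abundance, dimensionless and non-negative.
    fragments :
        Sequence of ``(fragment_mz, branching_ratio)`` pairs.  Fragments are
        singly charged by convention, so every ``fragment_mz`` must be below
        the precursor ``mz``; branching ratios are non-negative and sum to at
        most 1 (the remainder is unmonitored product).
    """

    mz: float
    charge: int = 1
    abundance: float = 1.0
    fragments: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise DomainError(f"precursor m/z must be positive, got {self.mz}")
        if int(self.charge) != self.charge or self.charge < 1:
            raise DomainError(f"charge must be a positive integer, got {self.charge}")
        if self.abundance < 0:
            raise DomainError(f"abundance must be >= 0, got {self.abundance}")
        object.__setattr__(
            self, "fragments", tuple((float(m), float(b)) for m, b in self.fragments)
        )
        total = 0.0
        for fmz, br in self.fragments:
            if not 0 < fmz < self.mz:
                raise DomainError(
                    f"fragment m/z {fmz} must lie in (0, {self.mz}) "
                    "(singly charged fragment convention)"
                )
            if br < 0:
                raise DomainError(f"branching ratio must be >= 0, got {br}")
            total += br
        if total > 1 + 1e-12:
            raise DomainError(f"branching ratios sum to {total} > 1")

    @property
    def mass_kg(self) -> float:
        """Ion mass in kg: (m/z) * z * u."""
        return self.mz * self.charge * ATOMIC_MASS


@dataclass(frozen=True)
class TofInstrumentConfig:
    """Geometry and potentials of the TOF side-kick instrument.

    Defaults follow the reference side-kick setup: a 7 V kick (deliberately
    low relative to the 1000 V repeller, so the kicked trajectory stays
    nearly parallel to the detector), extractor 905 V, lens 914 V.  Zone
    geometry (the kick-exit-to-zone gap and the zone length) and the flight
    length are exposed here because they are instrument design choices.
    """

    v_kick: float = 7.0
    v_repeller: float = 1000.0
    v_extractor: float = 905.0
    v_lens: float = 914.0
    flight_length: float = 1.0
    zone_start: float = 0.005
    zone_length: float = 0.036

    def __post_init__(self) -> None:
        for name in ("flight_length", "zone_start", "zone_length"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.v_kick < 0 or self.v_repeller <= 0:
            raise ConfigurationError("potentials must be non-negative (repeller > 0)")
        if not self.v_kick < self.v_repeller:
            raise ConfigurationError(
                "the side-kick potential must be small relative to the repeller "
                f"(v_kick={self.v_kick} V >= v_repeller={self.v_repeller} V)"
            )


def speed_from_potential(mz: float, charge: int = 1, potential: float = 0.0) -> float:
    """Speed acquired by an ion accelerated through ``potential``.

    Implements ``v = sqrt(2 z e V / ((m/z) z u))``: every ion of the same
    charge gains the same kinetic energy ``z e V``, so the speed depends only
    on m/z and the potential.

    Raises
    ------
    DomainError
        If ``mz <= 0`` or ``potential < 0``.
    """
    if not mz > 0:
        raise DomainError(f"m/z must be positive, got {mz}")
    if potential < 0:
        raise DomainError(f"potential must be >= 0, got {potential}")
    if not charge >= 1:
        raise DomainError(f"charge must be >= 1, got {charge}")
    return math.sqrt(
        2.0 * charge * ELEMENTARY_CHARGE * potential / (mz * charge * ATOMIC_MASS)
    )


@dataclass(frozen=True)
class IonState:
    """Kinematic state of one ion after the kick and axial acceleration.

    ``kinetic_energy`` must equal ``1/2 m (lateral^2 + axial^2)`` for the
    stored speeds (checked to 1e-9 relative on construction).
    """

    species: PrecursorSpecies
    lateral_speed: float
    axial_speed: float
    kinetic_energy: float
    lateral_position: float = 0.0

    def __post_init__(self) -> None:
        if self.lateral_speed < 0 or self.axial_speed < 0:
            raise DomainError("speeds must be >= 0")
        expected = 0.5 * self.species.mass_kg * (
            self.lateral_speed**2 + self.axial_speed**2
        )
        if expected > 0 and abs(self.kinetic_energy - expected) > 1e-9 * expected:
            raise DomainError(
                f"kinetic energy {self.kinetic_energy} J inconsistent with speeds "
                f"(expected {expected} J)"
            )

    @classmethod
    def after_kick(
        cls, species: PrecursorSpecies, config: TofInstrumentConfig
    ) -> "IonState":
        """State after the impulsive side kick and repeller acceleration."""
        v_lat = speed_from_potential(species.mz, species.charge, config.v_kick)
        v_ax = speed_from_potential(species.mz, species.charge, config.v_repeller)
        ke = 0.5 * species.mass_kg * (v_lat**2 + v_ax**2)
        return cls(
            species=species,
            lateral_speed=v_lat,
            axial_speed=v_ax,
            kinetic_energy=ke,
        )


def lateral_position_at_delay(state: IonState, delay: float, zone_start: float) -> float:
    """Lateral position ``d`` across the fragmentation zone after ``delay``.

    Field-free drift after the kick: ``d = lateral_speed * delay - zone_start``,
    measured from the first point of the zone; negative values mean the ion
    has not yet entered.
    """
    if delay < 0:
        raise DomainError(f"delay must be >= 0, got {delay}")
    return state.lateral_speed * delay - zone_start


def is_in_zone(d: float, zone_length: float) -> bool:
    """Whether a lateral position lies inside ``[0, zone_length]``."""
    return 0.0 <= d <= zone_length


def flight_time_from_mz(
    mz: float, config: TofInstrumentConfig, charge: int = 1
) -> float:
    """Flight time over the field-free tube: ``t = L / v(V_repeller)``.

    Strictly increasing in m/z (larger m/z arrives later).
    """
    v = speed_from_potential(mz, charge, config.v_repeller)
    return config.flight_length / v


def mz_from_flight_time(
    t: float, config: TofInstrumentConfig, charge: int = 1
) -> float:
    """Invert the TOF relation: ``m/z = 2 e V t^2 / (u L^2)`` per charge.

    Exact inverse of :func:`flight_time_from_mz` (round trip to 1e-9
    relative).
    """
    if not t > 0:
        raise DomainError(f"flight time must be positive, got {t}")
    return (
        2.0
        * ELEMENTARY_CHARGE
        * config.v_repeller
        * t**2
        / (config.flight_length**2 * ATOMIC_MASS)
    )
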