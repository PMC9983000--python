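"""Frequency -> precursor m/z calibration and 2D map assembly.

Every precursor modulates the intensity of its fragments at a frequency
``f = D / sqrt(m/z)``, where the calibration constant ``D`` is the same for
all masses in a given acquisition (it depends only on the kick or deflection
geometry and the fringe spacing).  Fitting ``f`` against ``(m/z)^(-1/2)``
through the origin therefore calibrates the precursor axis; inverting the
law assigns each picked modulation frequency a precursor m/z, and collecting
``(precursor m/z, fragment m/z, intensity)`` triplets over all fragment
channels yields the 2D mass spectrum.

A phase constant ``C`` (the offset between the ions' start point and the
first fringe maximum) is carried on the model but plays no role in
magnitude-mode processing; it would matter only for absorption-mode
phasing, which is not implemented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, DomainError
from .ftproc import fft_magnitude, pick_peaks
from .tof_engine import TransientCube

__all__ = [
    "CalibrationModel",
    "Spectrum2D",
    "fit_inverse_sqrt_calibration",
    "frequency_to_precursor_mz",
    "precursor_mz_to_frequency",
    "assemble_2d",
    "precursor_slice",
]


@dataclass(frozen=True)
class CalibrationModel:
    """The fitted ``f = D / sqrt(m/z)`` mapping.

    ``frequency_unit`` records the scale of ``D`` (``"cycles_per_scan"`` or
    ``"hz"``); mixing units between fit and application is an error the
    caller must avoid, so the unit is carried explicitly.
    """

    D: float
    C: float = 0.0  # phase constant; unused in magnitude mode
    variant: str = "tof"
    frequency_unit: str = "cycles_per_scan"
    residual_rms: float = 0.0
    n_points: int = 0

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise CalibrationError(f"calibration constant D must be positive, got {self.D}")
        if self.frequency_unit not in ("cycles_per_scan", "hz"):
            raise CalibrationError(f"unknown frequency unit {self.frequency_unit!r}")


def fit_inverse_sqrt_calibration(
    points: Sequence[tuple[float, float]],
    variant: str = "tof",
    frequency_unit: str = "cycles_per_scan",
    C: float = 0.0,
) -> CalibrationModel:
    """Least-squares fit of frequency against ``(m/z)^(-1/2)`` through the
    origin over ``(frequency, known m/z)`` points.

    Exact (zero residual) for noiseless law-consistent input; with a single
    point it reduces to ``D = f sqrt(m/z)``.
    """
    pts = [(float(f), float(mz)) for f, mz in points]
    if not pts:
        raise CalibrationError("need at least one calibration point")
    if any(f <= 0 or mz <= 0 for f, mz in pts):
        raise CalibrationError("frequencies and m/z values must be positive")
    f = np.array([p[0] for p in pts])
    x = np.array([p[1] for p in pts]) ** -0.5
    D = float(np.dot(f, x) / np.dot(x, x))
    resid = f - D * x
    return CalibrationModel(
        D=D,
        C=C,
        variant=variant,
        frequency_unit=frequency_unit,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points=len(pts),
    )


def frequency_to_precursor_mz(frequency: float, model: CalibrationModel) -> float:
    """Invert the calibration: ``m/z = (D / f)^2``; strictly decreasing in f."""
    if not frequency > 0:
        raise DomainError(f"frequency must be positive, got {frequency}")
    return (model.D / frequency) ** 2


def precursor_mz_to_frequency(mz: float, model: CalibrationModel) -> float:
    """Forward calibration ``f = D / sqrt(m/z)`` (round-trip identity with
    :func:`frequency_to_precursor_mz`)."""
    if not mz > 0:
        raise DomainError(f"m/z must be positive, got {mz}")
    return model.D / math.sqrt(mz)


@dataclass
class Spectrum2D:
    """Sparse 2D precursor x fragment intensity map.

    Stored as parallel triplet arrays; under the singly-charged fragment
    convention every stored triplet satisfies
    ``precursor_mz > fragment_mz``.
    """

    precursor_mz: np.ndarray
    fragment_mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.precursor_mz = np.asarray(self.precursor_mz, dtype=float)
        self.fragment_mz = np.asarray(self.fragment_mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        n = self.precursor_mz.size
        if self.fragment_mz.size != n or self.intensity.size != n:
            raise CalibrationError("triplet arrays must have equal length")
        if np.any(self.intensity < 0):
            raise CalibrationError("intensities must be >= 0")
        if np.any(self.precursor_mz <= self.fragment_mz):
            raise CalibrationError(
                "every triplet must satisfy precursor_mz > fragment_mz"
            )

    def __len__(self) -> int:
        return int(self.precursor_mz.size)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "precursor_mz": self.precursor_mz,
                "fragment_mz": self.fragment_mz,
                "intensity": self.intensity,
            }
        )

    def slice(self, precursor_mz: float, tolerance: float) -> pd.DataFrame:
        """Horizontal fragment scan: all triplets with
        ``|precursor - requested| <= tolerance``, as a fragment spectrum
        sorted by fragment m/z (may be empty)."""
        hit = np.abs(self.precursor_mz - precursor_mz) <= tolerance
        df = pd.DataFrame(
            {
                "fragment_mz": self.fragment_mz[hit],
                "intensity": self.intensity[hit],
            }
        )
        return df.sort_values("fragment_mz", ignore_index=True)


def precursor_slice(
    spectrum: Spectrum2D, precursor_mz: float, tolerance: float
) -> pd.DataFrame:
    """Module-level alias for :meth:`Spectrum2D.slice`."""
    return spectrum.slice(precursor_mz, tolerance)


def assemble_2d(
    cube: TransientCube,
    model: CalibrationModel,
    min_relative_height: float = 0.2,
    window: str = "none",
    zero_fill: int = 4,
) -> Spectrum2D:
    """Transform every fragment channel, pick peaks, and map each picked
    modulation frequency to a precursor m/z.

    Only fragment channels are mapped (depleted-precursor channels carry the
    same modulation but describe the precursor itself, not a correlation).
    Peaks whose calibrated precursor m/z does not exceed the channel's
    fragment m/z violate the singly-charged convention and are discarded
    (counted in ``metadata["discarded_triplets"]``).
    """
    variant = cube.metadata.get("variant")
    if variant is not None and variant != model.variant:
        raise CalibrationError(
            f"cube variant {variant!r} does not match model variant {model.variant!r}"
        )
    prec: list[float] = []
    frag: list[float] = []
    inten: list[float] = []
    discarded = 0
    for col in cube.fragment_channels():
        fmz = float(cube.channel_mz[col])
        spectrum = fft_magnitude(
            cube.intensity[:, col],
            window=window,
            zero_fill=zero_fill,
            scan_step=cube.scan_step,
        )
        for peak in pick_peaks(spectrum, min_relative_height=min_relative_height):
            f = peak.frequency
            if model.frequency_unit == "hz":
                f = f / cube.scan_step
            pmz = frequency_to_precursor_mz(f, model)
            if pmz > fmz:
                prec.append(pmz)
                frag.append(fmz)
                inten.append(peak.height)
            else:
                discarded += 1
    return Spectrum2D(
        precursor_mz=np.array(prec),
        fragment_mz=np.array(frag),
        intensity=np.array(inten),
        metadata={
            "variant": model.variant,
            "calibration_D": model.D,
            "frequency_unit": model.frequency_unit,
            "discarded_triplets": discarded,
            "cube_metadata": cube.metadata,
        },
    )
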