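"""Transient -> frequency spectrum, peak picking, resolving power.

The per-channel transients are demodulated with a magnitude-mode FFT.  A
cos^2 fringe pattern carries a constant 1/2 offset, so the mean is
subtracted before transforming (otherwise bin 0 dominates every spectrum);
the remaining oscillation appears at the fringe-crossing frequency.

Resolving power is reported as the FWHM quantity ``RP_f = f / FWHM`` in the
frequency domain.  Because ``m/z = (D/f)^2``, a relative frequency width
maps to twice the relative m/z width, so the m/z-domain resolving power is
exactly ``RP_f / 2``.

Frequencies are handled in cycles/scan (the natural unit of a scan-indexed
series); the scan-axis step converts to Hz when known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DegeneratePeakError, DomainError

__all__ = [
    "FrequencySpectrum",
    "Peak",
    "NyquistReport",
    "fft_magnitude",
    "pick_peaks",
    "resolving_power",
    "check_nyquist",
]


@dataclass
class FrequencySpectrum:
    """One-sided magnitude spectrum of a channel transient.

    ``frequency`` spans ``[0, 0.5]`` cycles/scan; ``scan_step`` (s) converts
    to Hz when available.  ``n_scans`` is the unpadded transient length, so
    one "bin" in the resolution sense is ``1/n_scans`` cycles/scan.
    """

    frequency: np.ndarray
    magnitude: np.ndarray
    n_scans: int
    scan_step: Optional[float] = None
    window: str = "none"
    zero_fill: int = 4
    mode: str = "magnitude"

    @property
    def frequency_hz(self) -> np.ndarray:
        if self.scan_step is None:
            raise DomainError("scan step unknown; cannot convert to Hz")
        return self.frequency / self.scan_step

    @property
    def bin_width(self) -> float:
        """Natural resolution element, 1/n_scans cycles/scan."""
        return 1.0 / self.n_scans


def fft_magnitude(
    transient,
    window: str = "none",
    zero_fill: int = 4,
    scan_step: Optional[float] = None,
    subtract_mean: bool = True,
) -> FrequencySpectrum:
    """Magnitude spectrum of a transient.

    Parameters
    ----------
    transient :
        1-D array of per-scan intensities, or any object with ``values`` and
        ``scan_step`` attributes (e.g. a channel transient).
    window :
        ``"none"`` (rectangular) or ``"hann"``.
    zero_fill :
        Pad the (windowed) transient to ``zero_fill * n_scans`` samples
        before transforming; interpolates the line shape for centroid/FWHM
        measurement without changing the underlying resolution.
    """
    if hasattr(transient, "values") and hasattr(transient, "scan_step"):
        if scan_step is None:
            scan_step = transient.scan_step
        transient = transient.values
    x = np.asarray(transient, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DomainError("transient must be 1-D with length >= 2")
    if zero_fill < 1:
        raise DomainError("zero_fill must be >= 1")
    n = x.size
    if subtract_mean:
        x = x - x.mean()
    if window == "hann":
        x = x * np.hanning(n)
    elif window != "none":
        raise DomainError(f"unknown window {window!r}")
    m = zero_fill * n
    spec = np.abs(np.fft.rfft(x, n=m))
    freq = np.arange(spec.size) / m
    return FrequencySpectrum(
        frequency=freq,
        magnitude=spec,
        n_scans=n,
        scan_step=scan_step,
        window=window,
        zero_fill=zero_fill,
    )


@dataclass(frozen=True)
class Peak:
    """A picked spectral line with FWHM-based resolving powers.

    ``resolving_power_mz`` is exactly half ``resolving_power_f`` because
    m/z scales as the inverse square of frequency.
    """

    frequency: float  # interpolated centroid, cycles/scan
    height: float
    fwhm: float  # cycles/scan
    resolving_power_f: float
    resolving_power_mz: float
    index: int  # sample index of the maximum in the padded spectrum


def _parabolic_vertex(y0: float, y1: float, y2: float) -> tuple[float, float]:
    """Offset (in samples, in [-0.5, 0.5]) and height of the vertex of the
    parabola through three equally spaced samples."""
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return 0.0, y1
    delta = 0.5 * (y0 - y2) / denom
    height = y1 - 0.25 * (y0 - y2) * delta
    return delta, height


def _half_crossing(mag: np.ndarray, i: int, half: float, step: int) -> Optional[float]:
    """Sample position where the magnitude crosses ``half`` walking from
    ``i`` in direction ``step``; linear interpolation between samples."""
    j = i
    while 0 < j < mag.size - 1 and mag[j + step] < mag[j] and mag[j + step] > half:
        j += step
    nxt = j + step
    if not 0 <= nxt < mag.size or mag[nxt] > half:
        return None
    return j + step * (mag[j] - half) / (mag[j] - mag[nxt])


def pick_peaks(
    spectrum: FrequencySpectrum,
    min_relative_height: float = 0.1,
    min_separation_bins: float = 3.0,
    min_frequency_bins: float = 4.0,
) -> list[Peak]:
    """Pick local maxima above ``min_relative_height`` of the tallest bin.

    The first ``min_frequency_bins`` natural bins are excluded (and the
    height reference is taken above that guard band): transients gated by
    zone entry/exit leave a baseline step after mean subtraction whose
    magnitude piles up against DC and does not represent a modulation.

    Centroid and height come from three-point parabolic interpolation on the
    magnitude; FWHM from linear interpolation of the half-height crossings.
    Maxima whose half-height crossings cannot be resolved (blended lines at
    the spectrum edge) are skipped, and maxima closer than
    ``min_separation_bins`` natural bins (``1/n_scans`` cycles/scan) to a
    taller accepted peak are treated as sidelobes of that peak and dropped —
    the first sidelobes of an unapodized line reach ~22% of its height, and
    beyond three bins they fall under 10%.  Peaks are returned tallest
    first.
    """
    mag = spectrum.magnitude
    if mag.size < 3:
        return []
    guard = min_frequency_bins * spectrum.bin_width
    allowed = spectrum.frequency >= guard
    if not allowed.any():
        return []
    top = mag[allowed].max()
    if top <= 0:
        return []
    threshold = min_relative_height * top
    is_max = (
        (mag[1:-1] > mag[:-2])
        & (mag[1:-1] >= mag[2:])
        & (mag[1:-1] >= threshold)
        & allowed[1:-1]
    )
    peaks: list[Peak] = []
    for i in np.nonzero(is_max)[0] + 1:
        delta, height = _parabolic_vertex(mag[i - 1], mag[i], mag[i + 1])
        half = height / 2.0
        left = _half_crossing(mag, i, half, -1)
        right = _half_crossing(mag, i, half, +1)
        if left is None or right is None or right <= left:
            continue
        padded = spectrum.zero_fill * spectrum.n_scans
        centroid = (i + delta) / padded
        fwhm = (right - left) / padded
        rp_f = centroid / fwhm
        peaks.append(
            Peak(
                frequency=centroid,
                height=height,
                fwhm=fwhm,
                resolving_power_f=rp_f,
                resolving_power_mz=rp_f / 2.0,
                index=int(i),
            )
        )
    peaks.sort(key=lambda p: p.height, reverse=True)
    min_sep = min_separation_bins * spectrum.bin_width
    accepted: list[Peak] = []
    for p in peaks:
        if all(abs(p.frequency - q.frequency) >= min_sep for q in accepted):
            accepted.append(p)
    return accepted


def resolving_power(peak: Peak) -> tuple[float, float]:
    """``(RP_f, RP_mz)`` of a peak: centroid/FWHM and exactly half of it."""
    if not peak.fwhm > 0:
        raise DegeneratePeakError("peak has zero width")
    rp_f = peak.frequency / peak.fwhm
    return rp_f, rp_f / 2.0


@dataclass(frozen=True)
class NyquistReport:
    ok: bool
    frequency: float
    apparent_frequency: float
    message: str


def check_nyquist(frequency: float) -> NyquistReport:
    """Check a per-scan frequency against the sampling criterion.

    A modulation above 0.5 cycles/scan folds back to an apparent frequency
    ``min(f mod 1, 1 - f mod 1)`` and cannot be assigned unambiguously; a
    warning is emitted and the aliased apparent frequency reported.
    """
    f = abs(frequency)
    folded = f % 1.0
    apparent = min(folded, 1.0 - folded)
    if f <= 0.5:
        return NyquistReport(True, frequency, apparent, "below Nyquist")
    msg = (
        f"frequency {frequency} cycles/scan exceeds the Nyquist limit "
        f"(0.5); aliases to {apparent} cycles/scan"
    )
    warnings.warn(msg, stacklevel=2)
    return NyquistReport(False, frequency, apparent, msg)
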