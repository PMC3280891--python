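"""Analytic wavelet transform of sound through the extremal filterbank.

Conventions (fixed once, validated by the pure-tone closed form):

* Fourier synthesis ``f(t) = (1/2pi) int fhat(omega) e^{i omega t} domega``.
* Hilbert transform multiplier ``-i sgn(omega)`` so that ``H cos = sin``;
  the analytic row ``Z = u + iHu`` then has spectrum ``2 fhat ghat_a`` on
  positive frequencies only.
* Filter row at scale ``a``: ``ghat_a(omega) = sqrt(a) h_c(a omega)``.

With these choices the response to ``f = A cos(nu t + theta)`` is exactly

    Z f(a, t) = A sqrt(a) h_c(a nu) e^{i(nu t + theta)}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import hilbert as _scipy_hilbert

from .filters import FilterParameters, extremal_h_neg_extension
from .tonotopy import ScaleGrid, TonotopicMap, position_to_frequency

__all__ = [
    "SampledSignal",
    "assemble_cochleogram",
    "Cochleogram",
    "ImpulseResponse",
    "hilbert_transform",
    "wavelet_transform",
    "analytic_transform",
    "impulse_response",
    "nyquist_safe_mask",
]

#: relative amplitude floor below which phase is marked invalid
DEFAULT_AMP_FLOOR = 1e-6
#: localizations above this fraction of the Nyquist circular frequency
#: are considered alias-endangered
NYQUIST_SAFETY = 0.4


@dataclass(frozen=True)
class SampledSignal:
    """Uniformly sampled real signal."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return self.n / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.rate

    def energy(self) -> float:
        return float(np.sum(self.samples**2) / self.rate)


@dataclass
class Cochleogram:
    """Complex response field over a (scale, time) grid.

    ``Z[j]`` is the analytic row at scale ``grid.scales[j]``; ``logr``
    and ``phase`` are its polar decomposition with the phase unwrapped
    along time first, then along scale anchored at mid-signal.  ``mask``
    marks samples whose modulus exceeds the amplitude floor (phase is
    meaningless elsewhere).  ``row_valid`` marks Nyquist-safe rows.
    """

    grid: ScaleGrid
    times: np.ndarray
    Z: np.ndarray
    params: FilterParameters
    logr: Optional[np.ndarray] = None
    phase: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None
    row_valid: Optional[np.ndarray] = None
    amp_floor: float = DEFAULT_AMP_FLOOR
    meta: dict = field(default_factory=dict)

    @property
    def real(self) -> np.ndarray:
        return self.Z.real

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def energy(self) -> float:
        return float(np.sum(np.abs(self.Z) ** 2) * self.dt * self.grid.log_step)


def hilbert_transform(f: SampledSignal) -> SampledSignal:
    """Hilbert transform with the ``H cos = sin`` convention.

    Implemented as the frequency multiplier ``-i sgn(omega)``; on
    mean-free band-limited signals ``H(H f) = -f`` and the energy is
    preserved.
    """
    return SampledSignal(samples=np.imag(_scipy_hilbert(f.samples)), rate=f.rate)


def nyquist_safe_mask(grid: ScaleGrid, rate: float,
                      safety: float = NYQUIST_SAFETY) -> np.ndarray:
    """Rows whose localization ``1/a`` stays below ``safety`` times the
    Nyquist circular frequency ``pi * rate``."""
    return grid.center_frequencies < safety * np.pi * rate


def _padded_length(n: int) -> int:
    return 1 << int(np.ceil(np.log2(max(n, 2))))


def _taper_window(n: int, taper: float) -> np.ndarray:
    if taper <= 0:
        return np.ones(n)
    m = max(1, int(round(taper * n / 2)))
    w = np.ones(n)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(m) / m))
    w[:m] = ramp
    w[-m:] = ramp[::-1]
    return w


def _analytic_rows(f: SampledSignal, grid: ScaleGrid, p: FilterParameters,
                   pad: bool, taper: float):
    n = f.n
    x = f.samples * _taper_window(n, taper) if taper > 0 else f.samples
    m = _padded_length(n) if pad else n
    spec = np.fft.fft(x, n=m)
    omega = 2 * np.pi * np.fft.fftfreq(m, d=1.0 / f.rate)
    pos = omega > 0

    valid = nyquist_safe_mask(grid, f.rate)
    if not np.all(valid):
        warnings.warn(
            f"{np.count_nonzero(~valid)} scale rows exceed the Nyquist-safe "
            "band and are masked",
            RuntimeWarning,
            stacklevel=3,
        )

    Z = np.zeros((len(grid), n), dtype=complex)
    buf = np.zeros(m, dtype=complex)
    for j, a in enumerate(grid.scales):
        if not valid[j]:
            continue
        buf[:] = 0.0
        buf[pos] = 2.0 * spec[pos] * np.sqrt(a) * extremal_h_neg_extension(
            a * omega[pos], p
        )
        Z[j] = np.fft.ifft(buf)[:n]
    return Z, valid


def wavelet_transform(
    f: SampledSignal,
    grid: ScaleGrid,
    p: FilterParameters,
    pad: bool = True,
    taper: float = 0.0,
) -> Cochleogram:
    """Real wavelet transform of ``f`` (real part of the analytic rows).

    The returned cochleogram has only ``Z.real`` populated (imaginary
    part zero); use :func:`analytic_transform` for the polar fields.
    Scales are in seconds/radian, so ``a * omega`` with ``omega`` in
    rad/s is the dimensionless filter argument.
    """
    Z, valid = _analytic_rows(f, grid, p, pad, taper)
    return Cochleogram(grid=grid, times=f.times, Z=Z.real + 0j, params=p,
                       row_valid=valid,
                       meta={"rate": f.rate, "analytic": False})


def _unwrap_phase(Z: np.ndarray, mask: np.ndarray) -> np.ndarray:
    phase = np.unwrap(np.angle(Z), axis=1)
    mid = Z.shape[1] // 2
    anchor = np.unwrap(phase[:, mid])
    phase += (anchor - phase[:, mid])[:, None]
    return phase


def assemble_cochleogram(
    Z: np.ndarray,
    grid: ScaleGrid,
    times: np.ndarray,
    p: FilterParameters,
    row_valid: Optional[np.ndarray] = None,
    amp_floor: float = DEFAULT_AMP_FLOOR,
    meta: Optional[dict] = None,
) -> Cochleogram:
    """Build an analytic :class:`Cochleogram` (polar fields, masks) from
    precomputed complex rows."""
    absZ = np.abs(Z)
    zmax = absZ.max() if absZ.size else 0.0
    mask = absZ > amp_floor * zmax
    with np.errstate(divide="ignore"):
        logr = np.where(mask, np.log(np.where(mask, absZ, 1.0)), -np.inf)
    phase = _unwrap_phase(np.where(mask, Z, 1.0), mask)
    phase[~mask] = np.nan
    if row_valid is None:
        row_valid = np.ones(len(grid), dtype=bool)
    return Cochleogram(grid=grid, times=np.asarray(times, dtype=float), Z=Z,
                       params=p, logr=logr, phase=phase,
                       mask=mask & row_valid[:, None], row_valid=row_valid,
                       amp_floor=amp_floor, meta=dict(meta or {}))


def analytic_transform(
    f: SampledSignal,
    grid: ScaleGrid,
    p: FilterParameters,
    pad: bool = True,
    taper: float = 0.0,
    amp_floor: float = DEFAULT_AMP_FLOOR,
) -> Cochleogram:
    """Analytic wavelet transform ``Z = u + i H u`` with polar fields."""
    Z, valid = _analytic_rows(f, grid, p, pad, taper)
    return assemble_cochleogram(Z, grid, f.times, p, row_valid=valid,
                                amp_floor=amp_floor,
                                meta={"rate": f.rate, "analytic": True})


@dataclass(frozen=True)
class ImpulseResponse:
    """Impulse (click) response at one place, on a time grid symmetric
    about zero so that acausal leakage is measurable."""

    times: np.ndarray
    u: np.ndarray
    z: np.ndarray
    scale: float
    acausal_energy_fraction: float

    @property
    def rate(self) -> float:
        return float(1.0 / (self.times[1] - self.times[0]))


def impulse_response(
    x: float,
    p: FilterParameters,
    tmap: TonotopicMap,
    duration: float,
    rate: float,
) -> ImpulseResponse:
    """Inverse Fourier transform of the transfer function at place ``x``.

    ``tmap`` must be in rad/s units (use ``TonotopicMap.in_units``).
    ``duration`` must cover at least 20 cycles of the characteristic
    frequency; the time grid is symmetric about 0.
    """
    if tmap.units != "rad/s":
        raise ValueError("impulse_response needs a map in rad/s units")
    xi = position_to_frequency(x, tmap)  # rad/s
    if duration * xi / (2 * np.pi) < 20:
        raise ValueError("duration must cover at least 20 CF cycles")
    a = 1.0 / xi
    n = int(round(duration * rate))
    n += n % 2
    omega = 2 * np.pi * np.fft.fftfreq(n, d=1.0 / rate)
    g = np.sqrt(a) * extremal_h_neg_extension(a * omega, p)
    alt = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)  # shift to t in [-T/2, T/2)
    u = rate * np.real(np.fft.ifft(g * alt))
    gz = np.where(omega > 0, 2.0 * g, 0.0)
    z = rate * np.fft.ifft(gz * alt)
    t = (np.arange(n) - n // 2) / rate
    e = u**2
    total = float(np.sum(e))
    acausal = float(np.sum(e[t < 0]) / total) if total > 0 else 0.0
    return ImpulseResponse(times=t, u=u, z=z, scale=float(a),
                           acausal_energy_fraction=acausal)
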