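"""Position-frequency maps and scale grids.

The cochlear place ``x`` (measured in mm from the stapes) is mapped to a
characteristic frequency by a strictly decreasing map.  Two dialects are
supported:

* ``exponential``:  ``xi(x) = K * exp(-x / l)``
* ``shifted``:      ``xi(x) = K * exp(-x / l) - S``

Internally ``x`` is stored in physical mm and divided by the length
constant ``l`` where the normalized place variable is required.  The
bridge between place and wavelet scale is ``x/l = log K + log a``, i.e.
``a * xi(x) = 1`` for the exponential map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TonotopicMap",
    "ScaleGrid",
    "position_to_frequency",
    "frequency_to_position",
    "scaling_variable",
    "scale_grid_for_band",
]

#: default cochlear length over which the maps are considered valid (mm)
DEFAULT_LENGTH_MM = 35.0


@dataclass(frozen=True)
class TonotopicMap:
    """An invertible position->frequency map.

    Parameters
    ----------
    kind:
        ``"exponential"`` or ``"shifted"``.
    K:
        Frequency scale constant, in the units declared by ``units``.
        For the shifted map ``K = xi(0) + S``.
    l:
        Length constant in mm.
    S:
        Shift in frequency units (0 for the exponential kind).
    units:
        ``"hz"`` or ``"rad/s"``; purely declarative, all formulas are
        homogeneous in the frequency unit.
    length_mm:
        Declared cochlear length; positions outside [0, length_mm] are
        rejected.
    """

    kind: str = "exponential"
    K: float = 20000.0
    l: float = 6.6
    S: float = 0.0
    units: str = "hz"
    length_mm: float = DEFAULT_LENGTH_MM

    def __post_init__(self) -> None:
        if self.kind not in ("exponential", "shifted"):
            raise ValueError(f"unknown map kind {self.kind!r}")
        if self.K <= 0:
            raise ValueError("K must be positive")
        if self.l <= 0:
            raise ValueError("l must be positive")
        if self.S < 0:
            raise ValueError("S must be non-negative")
        if self.kind == "exponential" and self.S != 0.0:
            raise ValueError("exponential map requires S = 0")

    @property
    def apical_cutoff_mm(self) -> float:
        """Place beyond which the shifted map turns non-positive."""
        if self.S == 0.0:
            return np.inf
        return self.l * np.log(self.K / self.S)

    def __call__(self, x):
        return position_to_frequency(x, self)

    def inverse(self, f):
        return frequency_to_position(f, self)

    def with_shift(self, S: float) -> "TonotopicMap":
        kind = "shifted" if S > 0 else "exponential"
        return replace(self, kind=kind, S=S)

    def in_units(self, units: str) -> "TonotopicMap":
        """Convert the frequency constants between ``hz`` and ``rad/s``."""
        if units not in ("hz", "rad/s"):
            raise ValueError("units must be 'hz' or 'rad/s'")
        if units == self.units:
            return self
        factor = 2.0 * np.pi if units == "rad/s" else 1.0 / (2.0 * np.pi)
        return replace(self, K=self.K * factor, S=self.S * factor, units=units)


def position_to_frequency(x, tmap: TonotopicMap):
    """Characteristic frequency at place ``x`` (mm from the stapes)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0.0) or np.any(x > tmap.length_mm):
        raise ValueError(
            f"place out of range: expected 0 <= x <= {tmap.length_mm} mm"
        )
    cutoff = tmap.apical_cutoff_mm
    if np.any(x >= cutoff):
        raise ValueError(
            "shifted map is non-positive at the requested place; "
            f"apical cutoff is at {cutoff:.6g} mm"
        )
    f = tmap.K * np.exp(-x / tmap.l) - tmap.S
    return f if f.ndim else float(f)


def frequency_to_position(f, tmap: TonotopicMap):
    """Exact analytic inverse of :func:`position_to_frequency`."""
    f = np.asarray(f, dtype=float)
    upper = tmap.K - tmap.S
    if np.any(f <= 0.0) or np.any(f >= upper):
        raise ValueError(
            f"frequency out of range: expected 0 < f < K - S = {upper:.6g}"
        )
    x = tmap.l * np.log(tmap.K / (f + tmap.S))
    return x if x.ndim else float(x)


def scaling_variable(x, omega, tmap: TonotopicMap):
    """Dimensionless scaling variable of the filter shape at place ``x``.

    For the exponential map this is ``omega / xi(x)`` (equal to
    ``a * omega`` with ``a = 1/xi(x)``).  For the shifted map it is the
    generalized variable ``(omega + S) / (xi(x) + S)``, which reduces to
    the exponential one as ``S -> 0``.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0.0):
        raise ValueError("omega must be positive")
    xi = position_to_frequency(x, tmap)
    out = (omega + tmap.S) / (np.asarray(xi) + tmap.S)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ScaleGrid:
    """Log-spaced analysis scales and the places they correspond to.

    ``scales`` carries units of 1/frequency so that ``a * omega`` is
    dimensionless.  ``positions`` is the normalized place variable
    ``x/l`` satisfying ``positions = k_const + log(scales)`` exactly,
    with ``k_const = log K``.
    """

    scales: np.ndarray
    k_const: float
    positions: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        scales = np.asarray(self.scales, dtype=float)
        if scales.ndim != 1 or scales.size == 0:
            raise ValueError("scales must be a non-empty 1-D array")
        if np.any(scales <= 0) or np.any(np.diff(scales) <= 0):
            raise ValueError("scales must be positive and strictly increasing")
        object.__setattr__(self, "scales", scales)
        object.__setattr__(self, "positions", self.k_const + np.log(scales))

    def __len__(self) -> int:
        return len(self.scales)

    @property
    def log_step(self) -> float:
        steps = np.diff(np.log(self.scales))
        return float(steps[0]) if steps.size else 0.0

    @property
    def center_frequencies(self) -> np.ndarray:
        """Frequency localization 1/a of each row (exponential dialect)."""
        return 1.0 / self.scales


def scale_grid_for_band(
    f_lo: float,
    f_hi: float,
    scales_per_decade: int = 128,
    K: float = 20000.0,
) -> ScaleGrid:
    """Build a log-spaced :class:`ScaleGrid` covering localizations
    ``[f_lo, f_hi]`` (a = 1/f, highest frequency first scale)."""
    if not (0 < f_lo < f_hi):
        raise ValueError("need 0 < f_lo < f_hi")
    n = max(2, int(np.ceil(np.log10(f_hi / f_lo) * scales_per_decade)) + 1)
    scales = np.geomspace(1.0 / f_hi, 1.0 / f_lo, n)
    return ScaleGrid(scales=scales, k_const=np.log(K))
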