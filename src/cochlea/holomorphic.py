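"""Holomorphic solution theory for the structure equations.

At level ``c`` the complex structure equation

    a d/da log Z = (A + iB) + (C - iD) d/dt log Z

has solutions ``Z = e^{P(a)} G(z)`` with a time-independent particular
part ``P`` and ``G`` holomorphic in ``z = t - a*beta + i*a*gamma``
(upper half-plane, since ``a, gamma > 0``).  For the dilation symmetry
``P(a) = (gamma - i*alpha) * log a``; equality with the computed field
holds exactly at ``c = 1``.

The ``G`` of elementary inputs:

* pure tone ``A cos(nu t + theta)``:
  ``G(z) = d(nu) e^{i nu z}`` with
  ``d(nu) = A k e^{i(eps+theta)} nu^{gamma - 1/2 - i alpha}
  e^{gamma (1 - 1/c^2)}`` (the last factor is 1 at ``c = 1``),
* superpositions: sums of the above (exact additivity),
* unit impulse (``c = 1``, exact):
  ``G(z) = (k e^{i eps}/pi) Gamma(gamma + 1/2 - i alpha)
  (-i z)^{-(gamma + 1/2 - i alpha)}``.

The impulse response in the scale-invariant variable ``sinv = t/a``
obeys ``g' + i f' = -(gamma + 1/2 - i alpha) / (sinv - beta + i gamma)``
for the phase ``f(sinv)`` and log-amplitude ``g(sinv)``; the envelope
peak sits at ``g' = 0`` and ``f'`` is the normalized instantaneous
frequency (the click-response frequency glide).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import integrate
from scipy.special import loggamma

from .filters import FilterParameters
from .structure import coefficients, log_derivative
from .transform import Cochleogram

__all__ = [
    "zmap",
    "ParticularSolution",
    "particular_solution",
    "GSum",
    "G_pure_tone",
    "tone_g_coefficient",
    "tone_g_log_coefficient",
    "HarmonicSpectrum",
    "G_harmonic_complex",
    "HarmonicLocalExpansion",
    "AmplitudeModulationModel",
    "am_local_model",
    "DominanceError",
    "ImpulseModel",
    "impulse_model",
    "dbar_residual",
    "reconstruction_error",
]


def zmap(a, t, p: FilterParameters):
    """Upper-half-plane variable ``z = t - a*beta + i*a*gamma``."""
    a = np.asarray(a, dtype=float)
    t = np.asarray(t, dtype=float)
    return t - a * p.beta + 1j * a * p.gamma


# ---------------------------------------------------------------------------
# particular solution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParticularSolution:
    """Time-independent particular part ``P`` on a scale grid.

    ``derivative`` is ``a dP/da = A + iB``, exact by construction, so
    plugging ``(P, G == 1)`` into the complex structure equation leaves
    zero residual.
    """

    a: np.ndarray
    values: np.ndarray
    derivative: np.ndarray

    def __call__(self, a):
        """Interpolate ``P`` (linear in log a; exact for the dilation
        closed form)."""
        la = np.log(np.asarray(a, dtype=float))
        lg = np.log(self.a)
        re = np.interp(la, lg, self.values.real)
        im = np.interp(la, lg, self.values.imag)
        return re + 1j * im


def particular_solution(a_grid, p: FilterParameters, gm=None) -> ParticularSolution:
    a_grid = np.asarray(a_grid, dtype=float)
    sc = coefficients(a_grid, p, gm)
    const_c, _ = sc.as_complex()
    if gm is None:
        values = (p.gamma - 1j * p.alpha) * np.log(a_grid)
    else:
        la = np.log(a_grid)
        values = integrate.cumulative_trapezoid(const_c, la, initial=0.0)
        values = values + const_c[0] * la[0]
    return ParticularSolution(a=a_grid, values=values, derivative=const_c)


# ---------------------------------------------------------------------------
# holomorphic G of elementary signals
# ---------------------------------------------------------------------------

def tone_g_log_coefficient(amplitude: float, nu: float, theta: float,
                           p: FilterParameters) -> complex:
    """``log d(nu)``; kept in log form because sharp filters (large
    gamma) overflow the plain coefficient."""
    if nu <= 0:
        raise ValueError("nu must be positive")
    g, c = p.gamma, p.c
    return complex(np.log(amplitude * p.amplitude)
                   + (g - 0.5 - 1j * p.alpha) * np.log(nu)
                   + g * (1.0 - 1.0 / c**2)
                   + 1j * (p.epsilon + theta))


def tone_g_coefficient(amplitude: float, nu: float, theta: float,
                       p: FilterParameters) -> complex:
    """Coefficient ``d(nu)`` such that a pure tone has ``G = d e^{i nu z}``."""
    return complex(np.exp(tone_g_log_coefficient(amplitude, nu, theta, p)))


@dataclass
class GSum:
    """Finite exponential sum ``G(z) = sum_m d_m e^{i nu_m z}``.

    Closed under addition (exact superposition of input signals).
    """

    coefficients: np.ndarray
    frequencies: np.ndarray
    constant: complex = 0.0 + 0.0j  # free additive constant of log-matching

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_1d(np.asarray(self.coefficients,
                                                     dtype=complex))
        self.frequencies = np.atleast_1d(np.asarray(self.frequencies,
                                                    dtype=float))
        if self.coefficients.shape != self.frequencies.shape:
            raise ValueError("coefficient/frequency length mismatch")

    def __call__(self, z):
        z = np.asarray(z, dtype=complex)
        out = np.zeros(z.shape, dtype=complex)
        for d, nu in zip(self.coefficients, self.frequencies):
            out = out + d * np.exp(1j * nu * z)
        return out + self.constant if z.ndim else complex(
            out + self.constant)

    def __add__(self, other: "GSum") -> "GSum":
        return GSum(
            coefficients=np.concatenate([self.coefficients,
                                         other.coefficients]),
            frequencies=np.concatenate([self.frequencies, other.frequencies]),
            constant=self.constant + other.constant,
        )


def G_pure_tone(amplitude: float, nu: float, theta: float,
                p: FilterParameters) -> GSum:
    """Holomorphic function of the input ``A cos(nu t + theta)``."""
    return GSum(coefficients=[tone_g_coefficient(amplitude, nu, theta, p)],
                frequencies=[nu])


# ---------------------------------------------------------------------------
# harmonic complexes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HarmonicSpectrum:
    """Fundamental ``nu`` plus complex harmonic coefficients ``c_m``
    (m = 1..M); the input signal is ``sum_m |c_m| cos(m nu t + arg c_m)``."""

    nu: float
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        coeffs = np.atleast_1d(np.asarray(self.coefficients, dtype=complex))
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        if coeffs.size < 1:
            raise ValueError("need at least one harmonic")
        if not np.all(np.isfinite(coeffs)):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "coefficients", coeffs)

    @property
    def M(self) -> int:
        return len(self.coefficients)


@dataclass
class HarmonicLocalExpansion:
    """Local form of ``F = log G`` near the n-th harmonic:
    carrier term ``i n nu z + log d_n`` plus a remainder periodic in t
    with period ``2 pi / nu``."""

    n: int
    nu: float
    carrier_log_coefficient: complex
    neighbor_ratios: np.ndarray  # d_{n+k}/d_n keyed by offsets
    offsets: np.ndarray

    def carrier(self, z):
        return 1j * self.n * self.nu * np.asarray(z, dtype=complex) \
            + self.carrier_log_coefficient

    def remainder(self, z, two_neighbor: bool = False):
        """log(1+x) ~ x remainder; ``two_neighbor`` keeps only the
        offsets +-1 in the s/d decomposition."""
        z = np.asarray(z, dtype=complex)
        out = np.zeros(z.shape, dtype=complex)
        for off, r in zip(self.offsets, self.neighbor_ratios):
            if two_neighbor and abs(off) != 1:
                continue
            out = out + r * np.exp(1j * off * self.nu * z)
        return out

    def remainder_sd(self, z):
        """Two-neighbor remainder in the (s, d) form
        ``s cos(nu z) + i d sin(nu z)`` with ``s = c_+ + c_-``,
        ``d = c_+ - c_-``."""
        z = np.asarray(z, dtype=complex)
        cp = self.neighbor_ratios[self.offsets == 1]
        cm = self.neighbor_ratios[self.offsets == -1]
        cp = cp[0] if cp.size else 0.0
        cm = cm[0] if cm.size else 0.0
        s, d = cp + cm, cp - cm
        return s * np.cos(self.nu * z) + 1j * d * np.sin(self.nu * z)


class HarmonicComplexG(GSum):
    """G of a harmonic complex with per-place dominance helpers.

    Coefficient magnitudes are also kept in log form so that very sharp
    filters (large gamma) do not overflow the dominance bookkeeping.
    """

    def __init__(self, spec: HarmonicSpectrum, p: FilterParameters):
        logds = np.array([
            tone_g_log_coefficient(abs(c), m * spec.nu, float(np.angle(c)), p)
            for m, c in enumerate(spec.coefficients, start=1)
        ])
        with np.errstate(over="ignore"):
            ds = np.exp(logds)
        super().__init__(coefficients=ds,
                         frequencies=spec.nu * np.arange(1, spec.M + 1))
        self.log_coefficients = logds
        self.spec = spec
        self.params = p

    def log_row_weights(self, a: float) -> np.ndarray:
        """``log(|d_m| e^{-m nu a gamma})`` per harmonic at scale ``a``
        (common factor ``e^P`` dropped)."""
        g = self.params.gamma
        return self.log_coefficients.real - self.frequencies * a * g

    def row_weights(self, a: float) -> np.ndarray:
        lw = self.log_row_weights(a)
        return np.exp(lw - lw.max())

    def dominant_harmonic(self, a: float) -> int:
        """1-based index of the dominant coefficient at scale ``a``."""
        return int(np.argmax(self.log_row_weights(a))) + 1

    def local_expansion(self, n: int) -> HarmonicLocalExpansion:
        if self.spec.M < 3:
            raise ValueError("local expansion needs M >= 3 harmonics")
        if not (1 <= n <= self.spec.M):
            raise ValueError("harmonic index out of range")
        offsets = np.array([m - n for m in range(1, self.spec.M + 1)
                            if m != n])
        ratios = np.exp(self.log_coefficients[n - 1 + offsets]
                        - self.log_coefficients[n - 1])
        return HarmonicLocalExpansion(
            n=n, nu=self.spec.nu,
            carrier_log_coefficient=self.log_coefficients[n - 1],
            neighbor_ratios=ratios, offsets=offsets,
        )


def G_harmonic_complex(spec: HarmonicSpectrum,
                       p: FilterParameters) -> HarmonicComplexG:
    return HarmonicComplexG(spec, p)


# ---------------------------------------------------------------------------
# amplitude modulation
# ---------------------------------------------------------------------------

class DominanceError(ValueError):
    """Raised when the carrier does not dominate the sidebands."""


@dataclass
class AmplitudeModulationModel:
    """Local model of ``(1 + A cos mu t) cos nu t``.

    ``F(z) = i nu z + log d(nu) + rho_+ e^{i mu z} + rho_- e^{-i mu z}``
    using ``log(1 + x) ~ x``; ``F'`` carries the constant ``i nu``
    carrier term plus an oscillation of angular frequency ``mu``.
    """

    A: float
    mu: float
    nu: float
    params: FilterParameters
    threshold: float = 0.5
    d_carrier: complex = field(init=False)
    rho_plus: complex = field(init=False)
    rho_minus: complex = field(init=False)

    def __post_init__(self) -> None:
        if not (0 < self.mu < self.nu):
            raise ValueError("need 0 < mu < nu (slow modulation)")
        p = self.params
        self.d_carrier = tone_g_coefficient(1.0, self.nu, 0.0, p)
        if self.A == 0:
            self.rho_plus = self.rho_minus = 0.0 + 0.0j
        else:
            self.rho_plus = tone_g_coefficient(self.A / 2, self.nu + self.mu,
                                               0.0, p) / self.d_carrier
            self.rho_minus = tone_g_coefficient(self.A / 2, self.nu - self.mu,
                                                0.0, p) / self.d_carrier

    def sideband_magnitude(self, a) -> np.ndarray:
        """|x| bound entering the dominance condition at scale ``a``."""
        a = np.asarray(a, dtype=float)
        g = self.params.gamma
        return (np.abs(self.rho_plus) * np.exp(-self.mu * a * g)
                + np.abs(self.rho_minus) * np.exp(self.mu * a * g))

    def dominance_interval(self) -> tuple:
        """Scale interval on which the carrier dominates
        (``sideband_magnitude <= threshold``)."""
        rp, rm = np.abs(self.rho_plus), np.abs(self.rho_minus)
        if rp == 0 and rm == 0:
            return (0.0, np.inf)
        gmu = self.mu * self.params.gamma
        # quadratic in y = e^{mu gamma a}: rm y^2 - thr y + rp <= 0
        disc = self.threshold**2 - 4 * rm * rp
        if disc < 0:
            raise DominanceError("carrier never dominates for these "
                                 "amplitudes")
        if rm == 0:
            y_lo, y_hi = rp / self.threshold, np.inf
            a_lo = max(0.0, np.log(y_lo) / gmu) if y_lo > 1 else 0.0
            return (a_lo, np.inf)
        y_lo = (self.threshold - np.sqrt(disc)) / (2 * rm)
        y_hi = (self.threshold + np.sqrt(disc)) / (2 * rm)
        a_lo = np.log(y_lo) / gmu if y_lo > 1 else 0.0
        a_hi = np.log(y_hi) / gmu
        if a_hi <= a_lo:
            raise DominanceError("empty dominance interval")
        return (a_lo, a_hi)

    def check(self, a) -> None:
        if np.any(self.sideband_magnitude(a) > self.threshold):
            raise DominanceError(
                f"dominance condition violated at scale a={a}; valid "
                f"interval is {self.dominance_interval()}"
            )

    def F(self, z):
        z = np.asarray(z, dtype=complex)
        return (1j * self.nu * z + np.log(self.d_carrier)
                + self.rho_plus * np.exp(1j * self.mu * z)
                + self.rho_minus * np.exp(-1j * self.mu * z))

    def Fprime(self, z):
        z = np.asarray(z, dtype=complex)
        return 1j * self.nu + 1j * self.mu * (
            self.rho_plus * np.exp(1j * self.mu * z)
            - self.rho_minus * np.exp(-1j * self.mu * z)
        )


def am_local_model(A: float, mu: float, nu: float, p: FilterParameters,
                   threshold: float = 0.5) -> AmplitudeModulationModel:
    return AmplitudeModulationModel(A=A, mu=mu, nu=nu, params=p,
                                    threshold=threshold)


# ---------------------------------------------------------------------------
# impulse response model and frequency glides
# ---------------------------------------------------------------------------

@dataclass
class ImpulseModel:
    """Closed-form model of the click response.

    In the scale-invariant variable ``sinv = t/a`` the phase is
    ``f(sinv)`` and the log-amplitude ``g(sinv)`` with

        g' + i f' = -(gamma + 1/2 - i alpha) / (sinv - beta + i gamma).

    ``fprime`` is the normalized instantaneous frequency; the envelope
    peak solves ``gprime = 0``.
    """

    params: FilterParameters
    constant: complex = 0.0 + 0.0j

    @property
    def _coef(self) -> complex:
        p = self.params
        return p.gamma + 0.5 - 1j * p.alpha

    def _w(self, s):
        p = self.params
        s = np.asarray(s, dtype=complex)
        w = s - p.beta + 1j * p.gamma
        if np.any(w.imag <= 0):
            raise ValueError(
                f"evaluation requires Im(sinv) > -gamma = {-p.gamma}"
            )
        return w

    def fg_prime(self, s):
        """Complex ``g' + i f'`` at real ``sinv``."""
        return -self._coef / self._w(s)

    def fprime(self, s):
        out = self.fg_prime(s).imag
        return out if np.ndim(s) else float(out)

    def gprime(self, s):
        out = self.fg_prime(s).real
        return out if np.ndim(s) else float(out)

    def peak_s(self) -> float:
        """Solution of ``g'(sinv) = 0`` (travel locus of the click peak)."""
        p = self.params
        return float(p.beta + p.alpha * p.gamma / (p.gamma + 0.5))

    def glide_profile(self, s) -> np.ndarray:
        """Normalized instantaneous frequency ``f'(sinv)``."""
        return self.fprime(s)

    def integrate_fg(self, s_grid, f0: float = 0.0, g0: float = 0.0):
        """Integrate the (f', g') system along ``s_grid`` with solve_ivp."""
        s_grid = np.asarray(s_grid, dtype=float)

        def rhs(s, y):
            w = self.fg_prime(s)
            return [w.imag, w.real]

        sol = integrate.solve_ivp(
            rhs, (s_grid[0], s_grid[-1]), [f0, g0], t_eval=s_grid,
            rtol=1e-10, atol=1e-12, dense_output=False,
        )
        if not sol.success:
            raise ArithmeticError(f"glide integration failed: {sol.message}")
        return sol.y[0], sol.y[1]

    def F(self, z):
        """Holomorphic ``F(z) = const - (gamma + 1/2 - i alpha) Log(-i z)``
        on the upper half-plane; the branch has ``arg(z)`` in (0, pi)."""
        z = np.asarray(z, dtype=complex)
        if np.any(z.imag <= 0):
            raise ValueError("F is defined on the upper half-plane")
        return self.constant - self._coef * np.log(-1j * z)

    def exact_c1_G(self):
        """Exact ``G`` of the unit impulse for ``c = 1`` (includes the
        Gamma-function constant; no calibration needed)."""
        p = self.params
        if p.c != 1.0:
            raise ValueError("exact impulse G is only available at c = 1")
        logk = (np.log(p.amplitude / np.pi) + 1j * p.epsilon
                + loggamma(self._coef))

        def G(z):
            z = np.asarray(z, dtype=complex)
            return np.exp(logk - self._coef * np.log(-1j * z))

        return G

    def calibrate(self, z_point: complex, value: complex) -> "ImpulseModel":
        """Fix the free constant by matching ``e^{F}``-type value at one
        point (documented as a calibration, not a model claim)."""
        current = self.F(np.asarray([z_point]))[0] - self.constant
        return ImpulseModel(params=self.params,
                            constant=np.log(value) - current)


def impulse_model(p: FilterParameters) -> ImpulseModel:
    if p.gamma <= 0:
        raise ValueError("gamma must be positive")
    return ImpulseModel(params=p)


# ---------------------------------------------------------------------------
# field-level diagnostics
# ---------------------------------------------------------------------------

def dbar_residual(coch: Cochleogram, p: Optional[FilterParameters] = None,
                  order: int = 2) -> dict:
    """Discrete d-bar residual of ``W = log Z - P`` in the z-variable.

    ``W`` should be holomorphic as a function of
    ``z = t - a beta + i a gamma`` (exact at ``c = 1``).  Derivatives of
    ``log Z`` are formed as ``FD(Z)/Z`` (no phase unwrapping); the
    particular part is differentiated analytically.  Reports interior
    RMS of ``dW/dzbar`` relative to the RMS of ``dW/dz``, both plain and
    ``|Z|``-energy-weighted.
    """
    p = p or coch.params
    if coch.logr is None:
        raise ValueError("need an analytic cochleogram")
    a = coch.grid.scales[:, None]
    dla = coch.grid.log_step
    dt = coch.dt
    Z = coch.Z
    safe = np.where(Z == 0, 1.0, Z)
    # a dW/da = a d(log Z)/da - (gamma - i alpha);  dW/dt = d(log Z)/dt
    dW_dla = log_derivative(Z, dla, axis=0, order=order) / safe \
        - (p.gamma - 1j * p.alpha)
    dW_da = dW_dla / a
    dW_dt = log_derivative(Z, dt, axis=1, order=order) / safe
    za = -p.beta + 1j * p.gamma
    dW_dzbar = (dW_da - za * dW_dt) / (-2j * p.gamma)
    dW_dz = (dW_da - np.conj(za) * dW_dt) / (2j * p.gamma)

    from .structure import _interior_mask

    interior = _interior_mask(coch, order, None)
    num = float(np.sqrt(np.mean(np.abs(dW_dzbar[interior]) ** 2)))
    den = float(np.sqrt(np.mean(np.abs(dW_dz[interior]) ** 2)))
    w2 = np.abs(Z[interior]) ** 2
    w2s = float(np.sum(w2))
    if w2s > 0:
        numw = float(np.sqrt(np.sum(np.abs(dW_dzbar[interior]) ** 2 * w2) / w2s))
        denw = float(np.sqrt(np.sum(np.abs(dW_dz[interior]) ** 2 * w2) / w2s))
    else:
        numw = denw = np.nan
    return {"dbar_rms": num, "dz_rms": den,
            "relative": num / den if den > 0 else np.inf,
            "relative_weighted": numw / denw if denw and denw > 0 else np.inf}


def reconstruction_error(coch: Cochleogram, G, P: ParticularSolution,
                         calibrate: bool = True) -> dict:
    """Relative error of the model field ``e^{P} G(z)`` against the
    computed ``Z`` on the valid interior.

    The free multiplicative constant of ``G`` is fixed by matching at
    the grid point of maximal ``|Z|``.
    """
    p = coch.params
    a = coch.grid.scales[:, None]
    z = zmap(a, coch.times[None, :], p)
    model = np.exp(P.values)[:, None] * G(z)
    Z = coch.Z
    mask = coch.mask if coch.mask is not None else np.abs(Z) > 0
    if calibrate:
        idx = np.unravel_index(np.argmax(np.abs(Z)), Z.shape)
        factor = Z[idx] / model[idx]
        model = model * factor
    err = np.abs(model - Z)[mask]
    ref = np.abs(Z)[mask]
    rel = float(np.sqrt(np.sum(err**2) / np.sum(ref**2)))
    return {"relative_rms": rel, "n_valid": int(mask.sum())}
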