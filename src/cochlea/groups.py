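"""Generalized one-parameter invariance groups.

A model is built from a vector field ``v`` on the positive frequency
axis (extended oddly).  Its flow ``lambda_a = tau_{log a}`` solves
``d tau/dt = v(tau)``.  On any interval between consecutive zeros of
``v`` a conjugation map ``s`` with

    s'(omega) / s(omega) = -1 / v(omega)

turns the flow into pure dilations: ``s(lambda_a omega) = s(omega)/a``.
The analysis wavelet at group parameter ``a`` is the translate

    Ghat_a(omega) = sqrt(a * s'(omega)) * h_c(a * s(omega)),

which reduces to ``sqrt(a) h_c(a omega)`` for the dilation group
(``v = -omega``, ``s = identity``).  Frequency localizations, the
uncertainty functionals and the Plancherel/reconstruction constants are
all expressed through ``s``.

Built-in models:

* ``dilation``           -- ``v = -omega``
* ``model_example_1(R)`` -- ``v = -omega log(R/omega)/log(R/K)``; zeros
  at 0 and R, banded: the model is indifferent to content above ``R``
* ``model_example_2``    -- shift map ``s = omega + S`` (modified near 0
  so it maps the positive axis onto itself), ``v = -(omega + S)``;
  matches the shifted tonotopic map
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import integrate, interpolate, optimize

from .filters import (FilterParameters, extremal_h, grid_localization,
                      optimal_phase_parameters, squared_norm_positive,
                      uncertainty_gap)
from .tonotopy import ScaleGrid, TonotopicMap, position_to_frequency
from .transform import SampledSignal, Cochleogram, assemble_cochleogram

__all__ = [
    "GroupModel",
    "UncertaintyFunctionals",
    "flow",
    "conjugation_map",
    "build_group_model",
    "dilation_group",
    "model_example_1",
    "model_example_2",
    "general_extremal",
    "group_wavelet_transform",
    "reconstruct",
    "plancherel_check",
    "uncertainty_functionals",
    "sigma_localization",
]


@dataclass
class GroupModel:
    """One-parameter transformation group on the frequency half-axis."""

    kind: str
    v: Callable[[np.ndarray], np.ndarray]
    zeros: tuple
    interval: tuple  # open interval of action (x_{i-1}, x_i)
    smap: Callable[[np.ndarray], np.ndarray]
    smap_inverse: Callable[[np.ndarray], np.ndarray]
    band: Optional[float] = None  # absolute frequency bound R, if any
    anchor: Optional[float] = None  # frequency with s(anchor) = 1, if fixed
    flow_closed: Optional[Callable[[float, np.ndarray], np.ndarray]] = None
    meta: dict = field(default_factory=dict)

    def smap_derivative(self, omega):
        """``s' = -s / v`` (exact identity, no numerical differentiation)."""
        omega = np.asarray(omega, dtype=float)
        return -self.smap(omega) / self.v(omega)

    def localization_frequency(self, a):
        """Frequency localization ``s^{-1}(1/a)`` of the scale-``a``
        filter (the generalized characteristic frequency)."""
        scalar = np.ndim(a) == 0
        out = np.atleast_1d(np.asarray(
            self.smap_inverse(1.0 / np.asarray(a, dtype=float)), dtype=float))
        return float(out[0]) if scalar else out

    def scale_for_place(self, x: float, tmap: TonotopicMap) -> float:
        """Group parameter whose filter is localized at ``xi(x)``."""
        return float(1.0 / self.smap(position_to_frequency(x, tmap)))

    def scaling_variable(self, a, omega):
        """Generalized scaling variable ``a * s(omega)`` (equals
        ``a * omega`` for the dilation group)."""
        return np.asarray(a, dtype=float) * self.smap(omega)

    def cocycle(self, a, omega):
        """Amplitude factor ``sqrt(a s'(omega))`` of the translated
        wavelet."""
        return np.sqrt(np.asarray(a, dtype=float)
                       * self.smap_derivative(omega))


def flow(gm: GroupModel, a: float, omega, rtol: float = 1e-10,
         atol: float = 1e-12):
    """Transformed frequency ``lambda_a(omega)`` by high-accuracy ODE
    integration of ``d tau/dt = v(tau)`` up to ``t = log a``.

    Zeros of the vector field are returned as exact fixed points.
    """
    if a <= 0:
        raise ValueError("group parameter a must be positive")
    omega_arr = np.atleast_1d(np.asarray(omega, dtype=float))
    lo, hi = gm.interval
    if np.any((omega_arr < lo) | (omega_arr > hi)):
        raise ValueError(f"omega outside the interval of action {gm.interval}")
    out = np.empty_like(omega_arr)
    t_end = float(np.log(a))
    for i, w in enumerate(omega_arr):
        if any(np.isclose(w, z, rtol=0, atol=1e-300) for z in gm.zeros):
            out[i] = w
            continue
        if t_end == 0.0:
            out[i] = w
            continue
        sol = integrate.solve_ivp(
            lambda t, y: [gm.v(y[0])], (0.0, t_end), [w],
            rtol=rtol, atol=atol, method="RK45",
        )
        if not sol.success:
            raise ArithmeticError(f"flow integration failed: {sol.message}")
        out[i] = sol.y[0, -1]
    return out if np.ndim(omega) else float(out[0])


def conjugation_map(gm_or_v, interval=None, anchor=None, n_nodes: int = 800):
    """Conjugation map by quadrature of ``-1/v`` from an anchor point.

    Accepts a :class:`GroupModel` (its ``v`` and interval are used) or a
    bare vector field with an explicit interval.  Returns
    ``(smap, smap_inverse)`` built from cumulative adaptive quadrature
    of ``log s`` on a graded grid, interpolated monotonically.
    """
    if isinstance(gm_or_v, GroupModel):
        v = gm_or_v.v
        interval = interval or gm_or_v.interval
        anchor = anchor or gm_or_v.anchor
    else:
        v = gm_or_v
        if interval is None:
            raise ValueError("interval required for a bare vector field")
    lo, hi = interval
    if anchor is None:
        anchor = np.sqrt(lo * hi) if (lo > 0 and np.isfinite(hi)) else (
            1.0 if lo < 1.0 < hi else 0.5 * (lo + min(hi, lo * 10)))
    if not (lo < anchor < hi):
        raise ValueError("anchor must lie inside the interval")

    # graded nodes accumulating towards the (possibly singular) endpoints
    hi_eff = hi if np.isfinite(hi) else anchor * 1e6
    lo_eff = max(lo, anchor * 1e-6) if lo == 0 else lo
    tiny = (hi_eff - lo_eff) * 1e-9
    u = np.linspace(0.0, 1.0, n_nodes)
    nodes = np.unique(np.concatenate([
        (anchor - (anchor - lo_eff - tiny) * u**2)[::-1],
        anchor + (hi_eff - tiny - anchor) * u**2,
    ]))

    vals = v(nodes)
    if np.any(vals == 0):
        raise ArithmeticError("vector field vanishes inside the interval; "
                              "conjugation map is singular there")

    integrand = lambda w: -1.0 / v(w)

    def _quad(a_, b_):
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", integrate.IntegrationWarning)
            val, _ = integrate.quad(integrand, a_, b_, epsabs=1e-13,
                                    epsrel=1e-12, limit=200)
        return val

    segments = np.array([_quad(nodes[k], nodes[k + 1])
                         for k in range(len(nodes) - 1)])
    if not np.all(np.isfinite(segments)):
        raise ArithmeticError("non-integrable singularity of 1/v inside "
                              "the interval")
    logs = np.concatenate([[0.0], np.cumsum(segments)])
    k0 = int(np.argmin(np.abs(nodes - anchor)))
    logs -= logs[k0]

    if not (np.all(np.diff(logs) > 0) or np.all(np.diff(logs) < 0)):
        raise ArithmeticError("conjugation map is not monotone")
    sign = 1.0 if logs[-1] > logs[0] else -1.0
    fwd = interpolate.PchipInterpolator(nodes, sign * logs)
    inv = interpolate.PchipInterpolator(sign * logs, nodes)

    # exact per-point evaluation (adaptive quadrature from the anchor) is
    # used for small requests such as localization look-ups; large arrays
    # (transform frequency grids) go through the interpolant
    _EXACT_LIMIT = 64

    def _log_s_exact(w: float) -> float:
        return _quad(anchor, w)

    def smap(omega):
        omega = np.asarray(omega, dtype=float)
        if omega.size <= _EXACT_LIMIT:
            out = np.exp([_log_s_exact(w) for w in np.atleast_1d(omega)])
            out = out.reshape(omega.shape)
        else:
            out = np.exp(sign * fwd(omega))
        return out if out.ndim else float(out)

    def smap_inverse(tau):
        tau = np.asarray(tau, dtype=float)
        if tau.size <= _EXACT_LIMIT:
            flat = np.atleast_1d(tau)
            out = np.empty(flat.shape)
            for i, tv in enumerate(flat):
                target = float(np.log(tv))
                guess = float(inv(sign * target))
                lo_b = max(guess / 1.5, nodes[0])
                hi_b = min(guess * 1.5, nodes[-1])
                fn = lambda w: _log_s_exact(w) - target
                if fn(lo_b) * fn(hi_b) > 0:
                    lo_b, hi_b = nodes[0], nodes[-1]
                out[i] = optimize.brentq(fn, lo_b, hi_b, xtol=1e-300,
                                         rtol=8.9e-16)
            out = out.reshape(tau.shape)
        else:
            out = inv(sign * np.log(tau))
        return out if out.ndim else float(out)

    return smap, smap_inverse


def build_group_model(v, interval, anchor=None, kind: str = "custom",
                      zeros=(), band=None) -> GroupModel:
    """Custom model from a vector field; ``s`` by quadrature."""
    smap, smap_inverse = conjugation_map(v, interval=interval, anchor=anchor)
    return GroupModel(kind=kind, v=v, zeros=tuple(zeros), interval=interval,
                      smap=smap, smap_inverse=smap_inverse, band=band,
                      anchor=anchor)


def dilation_group() -> GroupModel:
    """``v = -omega``; the conjugation map is the identity."""
    ident = lambda w: (np.asarray(w, dtype=float)
                       if np.ndim(w) else float(w))
    return GroupModel(
        kind="dilation",
        v=lambda w: -np.asarray(w, dtype=float),
        zeros=(0.0,),
        interval=(0.0, np.inf),
        smap=ident,
        smap_inverse=ident,
        anchor=1.0,
        flow_closed=lambda a, w: np.asarray(w, dtype=float) / a,
    )


def model_example_1(R: float, K: float = 1.0) -> GroupModel:
    """Banded model with vector field
    ``v(omega) = -omega * log(R/omega) / log(R/K)`` on (0, R).

    Zeros at 0 and R; ``R`` is an absolute upper frequency bound.  The
    conjugation map ``s(omega) = (log(R/omega)/log(R/K))^{-log(R/K)}``
    maps (0, R) onto the positive axis; as ``R -> inf`` the model tends
    to the dilation group on compact sets.
    """
    if not (0 < K < R):
        raise ValueError("need 0 < K < R")
    m = float(np.log(R / K))

    def v(w):
        w = np.asarray(w, dtype=float)
        out = np.where(w > 0, -w * np.log(np.maximum(R / np.maximum(w, 1e-300),
                                                     1e-300)) / m, 0.0)
        return out if out.ndim else float(out)

    def smap(w):
        w = np.asarray(w, dtype=float)
        out = (np.log(R / w) / m) ** (-m)
        return out if out.ndim else float(out)

    def smap_inverse(tau):
        tau = np.asarray(tau, dtype=float)
        out = R * np.exp(-m * tau ** (-1.0 / m))
        return out if out.ndim else float(out)

    def flow_closed(a, w):
        w = np.asarray(w, dtype=float)
        return R * np.exp(-np.log(R / w) * a ** (1.0 / m))

    return GroupModel(kind="example1", v=v, zeros=(0.0, R),
                      interval=(0.0, R), smap=smap,
                      smap_inverse=smap_inverse, band=R, anchor=K,
                      flow_closed=flow_closed, meta={"R": R, "K": K})


def model_example_2(S: float, eps_blend: float = 1.0) -> GroupModel:
    """Shift-map model ``s(omega) = omega + S`` conjugating the group to
    dilations; the physiological (shifted) tonotopic axis goes with it.

    Since ``omega + S`` does not map the positive axis onto itself, the
    map is modified on ``(0, eps_blend)`` to the monotone C^1 power-law
    blend ``(eps+S) (omega/eps)^{eps/(eps+S)}``; the vector field is
    ``-s/s'`` throughout, equal to ``-(omega + S)`` for
    ``omega >= eps_blend``.  ``S = 0`` gives the dilation group exactly.
    """
    if S < 0:
        raise ValueError("S must be non-negative")
    if S == 0:
        return dilation_group()
    eps = float(eps_blend)
    r = eps / (eps + S)

    def smap(w):
        w = np.asarray(w, dtype=float)
        out = np.where(w >= eps, w + S, (eps + S) * (np.maximum(w, 0.0) / eps) ** r)
        return out if out.ndim else float(out)

    def smap_inverse(tau):
        scalar = np.ndim(tau) == 0
        tau = np.atleast_1d(np.asarray(tau, dtype=float))
        out = tau - S
        low = tau < eps + S
        if np.any(low):
            out[low] = eps * (np.maximum(tau[low], 0.0)
                              / (eps + S)) ** (1.0 / r)
        return float(out[0]) if scalar else out

    def v(w):
        w = np.asarray(w, dtype=float)
        out = np.where(w >= eps, -(w + S), -w / r)
        return out if out.ndim else float(out)

    def flow_closed(a, w):
        return smap_inverse(smap(w) / a)

    return GroupModel(kind="example2", v=v, zeros=(0.0,),
                      interval=(0.0, np.inf), smap=smap,
                      smap_inverse=smap_inverse, anchor=None,
                      flow_closed=flow_closed,
                      meta={"S": S, "eps_blend": eps})


# ---------------------------------------------------------------------------
# extremal functions and wavelet transform for a group
# ---------------------------------------------------------------------------

def general_extremal(gm: GroupModel, omega, p: FilterParameters):
    """Extremal function of the group as a function of ``s(omega)``:
    the isometric pull-back ``sqrt(s'(omega)) h_c(s(omega))``."""
    omega = np.asarray(omega, dtype=float)
    out = np.zeros(omega.shape, dtype=complex)
    lo, hi = gm.interval
    inside = (omega > lo) & (omega < hi)
    if np.any(inside):
        w = omega[inside]
        out[inside] = np.sqrt(gm.smap_derivative(w)) * extremal_h(gm.smap(w), p)
    return out if out.ndim else complex(out)


def group_filter(gm: GroupModel, a: float, omega, p: FilterParameters):
    """Translated wavelet ``Ghat_a = sqrt(a s') h_c(a s)`` on
    ``omega > 0`` (zero outside the band)."""
    omega = np.asarray(omega, dtype=float)
    out = np.zeros(omega.shape, dtype=complex)
    lo, hi = gm.interval
    inside = (omega > lo) & (omega < hi)
    if np.any(inside):
        w = omega[inside]
        out[inside] = gm.cocycle(a, w) * extremal_h(a * gm.smap(w), p)
    return out


def group_wavelet_transform(
    f: SampledSignal,
    gm: GroupModel,
    p: FilterParameters,
    grid: ScaleGrid,
    pad: bool = True,
    out_of_band_tol: float = 0.01,
) -> Cochleogram:
    """Analytic wavelet transform with the group's translated wavelets.

    Reduces exactly to the standard (dilation) transform when
    ``gm.kind == "dilation"``.  For banded models a warning is issued if
    more than ``out_of_band_tol`` of the signal energy lies beyond the
    band edge.
    """
    n = f.n
    m = 1 << int(np.ceil(np.log2(max(n, 2)))) if pad else n
    spec = np.fft.fft(f.samples, n=m)
    omega = 2 * np.pi * np.fft.fftfreq(m, d=1.0 / f.rate)
    pos = omega > 0

    if gm.band is not None:
        e_total = float(np.sum(np.abs(spec[pos]) ** 2))
        oob = (omega > 0) & (omega >= gm.band)
        e_oob = float(np.sum(np.abs(spec[oob]) ** 2))
        if e_total > 0 and e_oob / e_total > out_of_band_tol:
            warnings.warn(
                f"{100 * e_oob / e_total:.1f}% of signal energy beyond the "
                f"band edge R = {gm.band:.6g} is invisible to this model",
                RuntimeWarning, stacklevel=2,
            )

    Z = np.zeros((len(grid), n), dtype=complex)
    buf = np.zeros(m, dtype=complex)
    for j, a in enumerate(grid.scales):
        buf[:] = 0.0
        buf[pos] = 2.0 * spec[pos] * group_filter(gm, a, omega[pos], p)
        Z[j] = np.fft.ifft(buf)[:n]
    return assemble_cochleogram(Z, grid, f.times, p,
                                meta={"rate": f.rate, "analytic": True,
                                      "group": gm.kind})


# ---------------------------------------------------------------------------
# Plancherel identity and reconstruction
# ---------------------------------------------------------------------------

def admissibility_constant(gm: GroupModel, omega, p: FilterParameters):
    """Frequency-wise admissibility weight
    ``C(omega) = ||h_c||^2 * s'(omega)/s(omega)`` entering the
    Plancherel identity and the reconstruction formula."""
    return squared_norm_positive(p) * gm.smap_derivative(omega) / gm.smap(omega)


def plancherel_check(coch: Cochleogram, f: SampledSignal, gm: GroupModel,
                     p: FilterParameters) -> dict:
    """Both sides of the Plancherel-type identity

    ``int |Z f|^2 db da/a = (4/2pi) int_0^inf |fhat|^2 C(omega) domega``
    computed with the cochleogram's discrete measures."""
    dla = coch.grid.log_step
    dt = coch.dt
    lhs = float(np.sum(np.abs(coch.Z) ** 2) * dt * dla)
    m = f.n
    spec = np.fft.fft(f.samples)
    omega = 2 * np.pi * np.fft.fftfreq(m, d=1.0 / f.rate)
    posm = omega > 0
    lo, hi = gm.interval
    inband = posm & (omega > lo) & (omega < hi)
    C = np.zeros(m)
    C[inband] = admissibility_constant(gm, omega[inband], p)
    domega = 2 * np.pi * f.rate / m
    # |fhat_cont|^2 = |DFT/rate|^2; 4 from the analytic doubling
    rhs = float(np.sum(np.abs(spec[posm] / f.rate) ** 2 * C[posm])
                * domega * 4.0 / (2 * np.pi))
    return {"lhs": lhs, "rhs": rhs,
            "relative_difference": abs(lhs - rhs) / max(abs(rhs), 1e-300)}


def reconstruct(coch: Cochleogram, gm: GroupModel, p: FilterParameters,
                rate: Optional[float] = None) -> SampledSignal:
    """Weak L2-duality reconstruction of the band-limited projection of
    the input from its group wavelet transform.

    In the frequency domain, with trapezoidal weights over log-scale:

        fhat(omega) = sum_j w_j FFT_b{Z}(a_j, omega) conj(Ghat_{a_j})
                      / (2 C(omega))

    Raises if the admissibility constant degenerates on the covered band.
    """
    rate = rate or coch.meta.get("rate")
    if rate is None:
        raise ValueError("sampling rate unknown")
    n = coch.Z.shape[1]
    omega = 2 * np.pi * np.fft.fftfreq(n, d=1.0 / rate)
    pos = omega > 0
    wpos = omega[pos]

    weights = np.full(len(coch.grid), coch.grid.log_step)
    weights[0] *= 0.5
    weights[-1] *= 0.5

    acc = np.zeros(wpos.shape, dtype=complex)
    for j, a in enumerate(coch.grid.scales):
        zspec = np.fft.fft(coch.Z[j])[pos]
        acc += weights[j] * zspec * np.conj(group_filter(gm, a, wpos, p))

    lo, hi = gm.interval
    inband = (wpos > lo) & (wpos < hi)
    C = np.zeros(wpos.shape)
    C[inband] = admissibility_constant(gm, wpos[inband], p)
    if np.all(np.abs(C[inband]) < 1e-12):
        raise ArithmeticError("admissibility constant vanishes; "
                              "the transform is not invertible")
    out_spec = np.zeros(n, dtype=complex)
    good = inband & (np.abs(C) > 1e-300)
    idx = np.where(pos)[0][good]
    out_spec[idx] = acc[good] / (2.0 * C[good])
    # conjugate symmetry for a real signal
    out_spec[-idx % n] = np.conj(out_spec[idx])
    samples = np.real(np.fft.ifft(out_spec))
    return SampledSignal(samples=samples, rate=rate)


# ---------------------------------------------------------------------------
# uncertainty functionals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UncertaintyFunctionals:
    """Localization, optimal phase parameters and inequality gap of a
    sampled function."""

    nu: float
    alpha: float
    beta: float
    gap: float


def sigma_localization(omega, h, c: float, gm: GroupModel) -> float:
    """Group frequency localization ``s^{-1}`` of the c-mean of
    ``s(omega)`` under ``|h|^2``."""
    omega = np.asarray(omega, dtype=float)
    s = gm.smap(omega)
    w2 = np.abs(h) ** 2
    mean = np.trapezoid(s**c * w2, omega) / np.trapezoid(w2, omega)
    return float(gm.smap_inverse(mean ** (1.0 / c)))


def uncertainty_functionals(omega, h, c: float,
                            gm: Optional[GroupModel] = None,
                            nu: Optional[float] = None) -> UncertaintyFunctionals:
    """Evaluate the functionals on samples ``h`` over a positive grid.

    For a general group the function is pulled back isometrically to the
    conjugated (pure-dilation) picture through ``tau = s(omega)`` before
    the dilation-case operators are applied.
    """
    omega = np.asarray(omega, dtype=float)
    h = np.asarray(h, dtype=complex)
    if gm is not None and gm.kind != "dilation":
        tau = gm.smap(omega)
        sp = gm.smap_derivative(omega)
        H = h / np.sqrt(sp)
        grid = tau
    else:
        H, grid = h, omega
    Hp = np.gradient(H, grid)
    nu_val = grid_localization(grid, H, c) if nu is None else nu
    alpha, beta = optimal_phase_parameters(grid, H, Hp)
    gap = uncertainty_gap(grid, H, Hp, c, alpha, beta, nu_val)
    return UncertaintyFunctionals(nu=float(nu_val), alpha=alpha, beta=beta,
                                  gap=float(gap))
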