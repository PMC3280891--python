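"""Structure equations as residual diagnostics on a cochleogram.

With ``gamma = c * kappa`` the computed analytic field ``Z`` satisfies
(exactly for ``c = 1``, to first order in the level linearization
otherwise) the linear system

    a d/da log r  =  A + C * d/dt log r + D * d/dt phi
    a d/da phi    =  B + C * d/dt phi   - D * d/dt log r

which combines into the complex equation

    a d/da log Z  =  (A + iB) + (C - iD) * d/dt log Z.

For the plain dilation symmetry the coefficients are the constants /
linear functions ``A = gamma``, ``B = -alpha``, ``C = -a*beta``,
``D = -a*gamma``.  For a general one-parameter group with vector field
``v`` they involve the frequency ``omega_a`` at which the scale-``a``
filter is localized:

    q_a = -1 / v(omega_a)          (equals ``a`` for ``v = -omega``)
    A = gamma * q_a * omega_a
    B = -alpha - beta * (1 - q_a * omega_a)
    C = -beta * q_a
    D = -gamma * q_a

Sign note: ``B`` carries the negative of the filter's log-phase
coefficient ``alpha``; with the convention ``alpha < 0`` used throughout,
``B > 0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .filters import FilterParameters
from .transform import Cochleogram

__all__ = [
    "StructureCoefficients",
    "ResidualField",
    "coefficients",
    "residuals",
    "exchange_phase_amplitude",
    "exchange_amplitude_phase",
    "log_derivative",
]


@dataclass(frozen=True)
class StructureCoefficients:
    """Coefficient functions evaluated on a scale grid (arrays over a)."""

    a: np.ndarray
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray

    def as_complex(self):
        """Constant term ``A + iB`` and slope ``C - iD`` of the complex
        equation."""
        return self.A + 1j * self.B, self.C - 1j * self.D


def coefficients(
    a,
    p: FilterParameters,
    gm=None,
) -> StructureCoefficients:
    """Structure-equation coefficients at scales ``a``.

    ``gm=None`` selects the dilation group; otherwise ``gm`` must offer
    ``localization_frequency(a)`` and a vector field ``gm.v``.  The
    general path with the dilation group reproduces the special-case
    constants identically.
    """
    a = np.atleast_1d(np.asarray(a, dtype=float))
    g = p.gamma
    if gm is None:
        A = np.full_like(a, g)
        B = np.full_like(a, -p.alpha)
        C = -a * p.beta
        D = -a * g
    else:
        omega_a = np.asarray(gm.localization_frequency(a), dtype=float)
        v = np.asarray(gm.v(omega_a), dtype=float)
        if np.any(np.abs(v) < 1e-300):
            raise ZeroDivisionError(
                "vector field vanishes at a requested localization; "
                "coefficients are singular there"
            )
        q = -1.0 / v
        A = g * q * omega_a
        B = -p.alpha - p.beta * (1.0 - q * omega_a)
        C = -p.beta * q
        D = -g * q
    return StructureCoefficients(a=a, A=A, B=B, C=C, D=D)


def log_derivative(field: np.ndarray, step: float, axis: int,
                   order: int = 2) -> np.ndarray:
    """Finite-difference derivative on a uniform grid.

    Centered stencils of the requested order on the interior, one-sided
    second-order at the edges (edge values are excluded from reported
    norms downstream).
    """
    f = np.asarray(field)
    d = np.empty_like(f, dtype=f.dtype)
    f = np.moveaxis(f, axis, 0)
    d = np.moveaxis(d, axis, 0)
    n = f.shape[0]
    if order == 2:
        if n < 3:
            raise ValueError("need at least 3 points for order-2 stencil")
        d[1:-1] = (f[2:] - f[:-2]) / (2 * step)
    elif order == 4:
        if n < 5:
            raise ValueError("need at least 5 points for order-4 stencil")
        d[2:-2] = (-f[4:] + 8 * f[3:-1] - 8 * f[1:-3] + f[:-4]) / (12 * step)
        d[1] = (f[2] - f[0]) / (2 * step)
        d[-2] = (f[-1] - f[-3]) / (2 * step)
    else:
        raise ValueError("order must be 2 or 4")
    d[0] = (-3 * f[0] + 4 * f[1] - f[2]) / (2 * step)
    d[-1] = (3 * f[-1] - 4 * f[-2] + f[-3]) / (2 * step)
    return np.moveaxis(d, 0, axis)


@dataclass
class ResidualField:
    """Pointwise residuals of the two real equations and the complex one,
    plus interior RMS norms.

    ``*_rms`` are plain RMS over the interior; the ``weighted`` variants
    weight each sample by ``|Z|`` (equivalent to testing the equation
    multiplied through by ``Z``), which keeps points near zeros of the
    field from dominating.  ``*_relative`` divide by the RMS magnitude
    of the equation's own terms."""

    residual1: np.ndarray
    residual2: np.ndarray
    residual_complex: np.ndarray
    interior: np.ndarray
    eq1_rms: float
    eq2_rms: float
    complex_rms: float
    complex_rms_relative: float
    complex_rms_weighted: float = np.nan
    complex_rms_weighted_relative: float = np.nan


def _interior_mask(coch: Cochleogram, order: int,
                   edge_margin: Optional[int]) -> np.ndarray:
    n_a, n_t = coch.Z.shape
    m = np.ones((n_a, n_t), dtype=bool)
    k = max(order // 2, 1) if edge_margin is None else edge_margin
    m[:k, :] = False
    m[-k:, :] = False
    m[:, :k] = False
    m[:, -k:] = False
    if coch.mask is not None:
        # every point of the FD stencil must be valid
        ok = coch.mask.copy()
        for shift in range(1, k + 1):
            ok[shift:, :] &= coch.mask[:-shift, :]
            ok[:-shift, :] &= coch.mask[shift:, :]
            ok[:, shift:] &= coch.mask[:, :-shift]
            ok[:, :-shift] &= coch.mask[:, shift:]
        m &= ok
    if coch.row_valid is not None:
        m &= coch.row_valid[:, None]
    return m


def residuals(
    coch: Cochleogram,
    p: Optional[FilterParameters] = None,
    gm=None,
    order: int = 2,
    edge_margin: Optional[int] = None,
    method: str = "direct",
) -> ResidualField:
    """Evaluate the structure equations on a computed cochleogram.

    Derivatives with respect to ``log a`` and ``t`` use centered
    differences (``order`` 2 or 4); edge rows/columns and samples below
    the amplitude floor are excluded from the reported norms.

    ``method="direct"`` differentiates ``Z`` itself and divides by ``Z``
    (robust near zeros of the field, no phase unwrapping involved);
    ``method="polar"`` differentiates the unwrapped ``logr``/``phase``
    fields (exact in time for linear-phase inputs such as pure tones).
    """
    if coch.logr is None or coch.phase is None:
        raise ValueError("residuals need an analytic cochleogram "
                         "(use analytic_transform)")
    if len(coch.grid) < 5:
        raise ValueError("need at least 5 scale rows")
    p = p or coch.params

    dla = coch.grid.log_step
    dt = coch.dt
    if method == "polar":
        logz = np.where(np.isfinite(coch.logr), coch.logr,
                        0.0) + 1j * np.nan_to_num(coch.phase)
        dz_dla = log_derivative(logz, dla, axis=0, order=order)
        dz_dt = log_derivative(logz, dt, axis=1, order=order)
    elif method == "direct":
        Z = coch.Z
        safe = np.where(Z == 0, 1.0, Z)
        dz_dla = log_derivative(Z, dla, axis=0, order=order) / safe
        dz_dt = log_derivative(Z, dt, axis=1, order=order) / safe
    else:
        raise ValueError("method must be 'direct' or 'polar'")

    sc = coefficients(coch.grid.scales, p, gm)
    const_c, slope_c = sc.as_complex()
    const_c = const_c[:, None]
    slope_c = slope_c[:, None]

    res_c = dz_dla - const_c - slope_c * dz_dt
    res1 = res_c.real
    res2 = res_c.imag

    interior = _interior_mask(coch, order, edge_margin)
    if not np.any(interior):
        raise ValueError("no interior samples available for residual norms")

    def rms(v):
        return float(np.sqrt(np.mean(np.abs(v[interior]) ** 2)))

    terms2 = (np.abs(dz_dla) ** 2
              + np.abs(np.broadcast_to(const_c, res_c.shape)) ** 2
              + np.abs(slope_c * dz_dt) ** 2)
    term_scale = np.sqrt(np.mean(terms2[interior]))
    c_rms = rms(res_c)

    w2 = np.abs(coch.Z) ** 2
    w2sum = np.sum(w2[interior])
    if w2sum > 0:
        cw = float(np.sqrt(np.sum((np.abs(res_c) ** 2 * w2)[interior]) / w2sum))
        tw = float(np.sqrt(np.sum((terms2 * w2)[interior]) / w2sum))
    else:
        cw = tw = np.nan
    out = ResidualField(
        residual1=res1,
        residual2=res2,
        residual_complex=res_c,
        interior=interior,
        eq1_rms=rms(res1),
        eq2_rms=rms(res2),
        complex_rms=c_rms,
        complex_rms_relative=float(c_rms / term_scale) if term_scale > 0 else np.nan,
        complex_rms_weighted=cw,
        complex_rms_weighted_relative=cw / tw if tw and tw > 0 else np.nan,
    )
    n_edge = np.count_nonzero(~interior)
    if n_edge > 0.9 * interior.size:
        import warnings

        warnings.warn("residual norms dominated by excluded edge samples",
                      RuntimeWarning, stacklevel=2)
    return out


def _check_D(sc: StructureCoefficients):
    if np.any(np.abs(sc.D) < 1e-12):
        raise ZeroDivisionError("coefficient D vanishes; exchange is singular")


def exchange_phase_amplitude(dphi_dt, a_dphi_da, sc: StructureCoefficients):
    """Solve the system for the amplitude derivatives given the phase
    derivatives (arrays broadcast over (scale, time))."""
    _check_D(sc)
    B = sc.B[:, None]
    C = sc.C[:, None]
    D = sc.D[:, None]
    A = sc.A[:, None]
    dlogr_dt = (B + C * dphi_dt - a_dphi_da) / D
    a_dlogr_da = A + C * dlogr_dt + D * dphi_dt
    return dlogr_dt, a_dlogr_da


def exchange_amplitude_phase(dlogr_dt, a_dlogr_da, sc: StructureCoefficients):
    """Converse of :func:`exchange_phase_amplitude`."""
    _check_D(sc)
    B = sc.B[:, None]
    C = sc.C[:, None]
    D = sc.D[:, None]
    A = sc.A[:, None]
    dphi_dt = (a_dlogr_da - A - C * dlogr_dt) / D
    a_dphi_da = B + C * dphi_dt - D * dlogr_dt
    return dphi_dt, a_dphi_da
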