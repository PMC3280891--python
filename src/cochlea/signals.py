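"""Synthetic signal generators, audio/tabular I/O and the pipeline.

All generators are deterministic given their spec (noise and harmonic
ripple through an explicit seed).  Frequencies at this boundary are in
Hz; they are converted once to circular frequency internally.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.io import wavfile

from .filters import PRESETS, FilterParameters
from .holomorphic import HarmonicSpectrum, dbar_residual
from .tonotopy import TonotopicMap, scale_grid_for_band
from .transform import (Cochleogram, SampledSignal, analytic_transform)
from .structure import residuals as structure_residuals

__all__ = [
    "GeneratorSpec",
    "generate",
    "harmonic_spectrum",
    "read_wav",
    "write_wav",
    "save_cochleogram_binary",
    "load_cochleogram_binary",
    "save_cochleogram_tsv",
    "filter_parameters_from_config",
    "tonotopic_map_from_config",
    "parse_vector_field",
    "run_pipeline",
]

NYQUIST_GUARD = 0.45  # max generated frequency as a fraction of rate


@dataclass(frozen=True)
class GeneratorSpec:
    """Specification of a synthetic test signal.

    kinds: ``tone`` (A cos(2 pi f t + phase)), ``am``
    ((1 + A_mod cos(2 pi f_mod t)) cos(2 pi f t)), ``harmonic``
    (complex with a dB-per-harmonic amplitude slope and seeded ripple),
    ``click`` (unit impulse), ``noise`` (seeded band-limited noise).
    """

    kind: str = "tone"
    rate: float = 44100.0
    duration: float = 1.0
    amplitude: float = 1.0
    freq_hz: float = 440.0
    phase: float = 0.0
    mod_freq_hz: float = 8.0
    mod_depth: float = 0.5
    n_harmonics: int = 20
    db_slope: float = 2.0
    ripple_db: float = 3.0
    band_hz: tuple = (50.0, 2000.0)
    click_time: float = 0.5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("tone", "am", "harmonic", "click", "noise"):
            raise ValueError(f"unknown generator kind {self.kind!r}")
        limit = NYQUIST_GUARD * self.rate
        offenders = []
        if self.kind in ("tone", "am") and self.freq_hz >= limit:
            offenders.append(f"freq_hz={self.freq_hz}")
        if self.kind == "am" and self.freq_hz + self.mod_freq_hz >= limit:
            offenders.append(f"freq_hz+mod_freq_hz={self.freq_hz + self.mod_freq_hz}")
        if self.kind == "harmonic" and self.n_harmonics * self.freq_hz >= limit:
            offenders.append(
                f"n_harmonics*freq_hz={self.n_harmonics * self.freq_hz}")
        if self.kind == "noise" and self.band_hz[1] >= limit:
            offenders.append(f"band_hz[1]={self.band_hz[1]}")
        if offenders:
            raise ValueError(
                "Nyquist-unsafe components (need < "
                f"{limit:.0f} Hz at rate {self.rate}): " + ", ".join(offenders)
            )


def harmonic_spectrum(spec: GeneratorSpec) -> HarmonicSpectrum:
    """Harmonic coefficients with a linear dB decrease of ``db_slope``
    per harmonic index and seeded +-``ripple_db`` oscillation."""
    rng = np.random.default_rng(spec.seed)
    m = np.arange(1, spec.n_harmonics + 1)
    level_db = -spec.db_slope * (m - 1)
    if spec.ripple_db > 0:
        level_db = level_db + rng.uniform(-spec.ripple_db, spec.ripple_db,
                                          size=len(m))
        level_db[0] = 0.0  # reference harmonic stays put
    amp = spec.amplitude * 10.0 ** (level_db / 20.0)
    theta = rng.uniform(0, 2 * np.pi, size=len(m))
    coeffs = amp * np.exp(1j * theta)
    return HarmonicSpectrum(nu=2 * np.pi * spec.freq_hz, coefficients=coeffs)


def generate(spec: GeneratorSpec) -> SampledSignal:
    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate
    w = 2 * np.pi * spec.freq_hz
    if spec.kind == "tone":
        x = spec.amplitude * np.cos(w * t + spec.phase)
    elif spec.kind == "am":
        if not (0 < spec.mod_freq_hz < spec.freq_hz):
            raise ValueError("am requires 0 < mod_freq_hz < freq_hz")
        mu = 2 * np.pi * spec.mod_freq_hz
        x = (1 + spec.mod_depth * np.cos(mu * t)) * np.cos(w * t + spec.phase)
        x *= spec.amplitude
    elif spec.kind == "harmonic":
        hs = harmonic_spectrum(spec)
        x = np.zeros(n)
        for m, c in enumerate(hs.coefficients, start=1):
            x += np.abs(c) * np.cos(m * w * t + np.angle(c))
    elif spec.kind == "click":
        x = np.zeros(n)
        idx = int(round(spec.click_time * spec.rate))
        if not (0 <= idx < n):
            raise ValueError("click_time outside the signal duration")
        x[idx] = spec.amplitude
    elif spec.kind == "noise":
        if spec.seed is None:
            raise ValueError("noise generator requires a seed")
        rng = np.random.default_rng(spec.seed)
        white = rng.standard_normal(n)
        spec_f = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, d=1.0 / spec.rate)
        lo, hi = spec.band_hz
        spec_f[(freqs < lo) | (freqs > hi)] = 0.0
        x = np.fft.irfft(spec_f, n=n)
        peak = np.max(np.abs(x))
        if peak > 0:
            x *= spec.amplitude / peak
    else:  # pragma: no cover - guarded in __post_init__
        raise AssertionError
    return SampledSignal(samples=x, rate=spec.rate)


# ---------------------------------------------------------------------------
# audio and cochleogram I/O
# ---------------------------------------------------------------------------

def read_wav(path) -> SampledSignal:
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if data.dtype == np.int16:
        data = data.astype(float) / 32768.0
    elif data.dtype == np.int32:
        data = data.astype(float) / 2147483648.0
    else:
        data = data.astype(float)
    return SampledSignal(samples=data, rate=float(rate))


def write_wav(path, sig: SampledSignal, dtype: str = "float32") -> None:
    if dtype == "float32":
        wavfile.write(path, int(round(sig.rate)),
                      sig.samples.astype(np.float32))
    elif dtype == "pcm16":
        clipped = np.clip(sig.samples, -1.0, 1.0)
        wavfile.write(path, int(round(sig.rate)),
                      (clipped * 32767).astype(np.int16))
    else:
        raise ValueError("dtype must be 'float32' or 'pcm16'")


_COCH_MAGIC = b"COCH"

# Flat binary layout (little endian):
#   magic 'COCH' | int32 n_scales | int32 n_times | float64 dt
#   | float64 k_const | float64 a[n_scales]
#   | float64 interleaved Re/Im, row-major over (scale, time)


def save_cochleogram_binary(path, coch: Cochleogram) -> None:
    with open(path, "wb") as fh:
        fh.write(_COCH_MAGIC)
        n_a, n_t = coch.Z.shape
        fh.write(struct.pack("<iidd", n_a, n_t, coch.dt, coch.grid.k_const))
        coch.grid.scales.astype("<f8").tofile(fh)
        inter = np.empty((n_a, 2 * n_t))
        inter[:, 0::2] = coch.Z.real
        inter[:, 1::2] = coch.Z.imag
        inter.astype("<f8").tofile(fh)


def load_cochleogram_binary(path, p: Optional[FilterParameters] = None) -> Cochleogram:
    from .tonotopy import ScaleGrid
    from .transform import assemble_cochleogram

    with open(path, "rb") as fh:
        if fh.read(4) != _COCH_MAGIC:
            raise ValueError("not a cochleogram file")
        n_a, n_t, dt, k_const = struct.unpack("<iidd", fh.read(24))
        scales = np.fromfile(fh, dtype="<f8", count=n_a)
        body = np.fromfile(fh, dtype="<f8", count=2 * n_a * n_t)
    body = body.reshape(n_a, 2 * n_t)
    Z = body[:, 0::2] + 1j * body[:, 1::2]
    grid = ScaleGrid(scales=scales, k_const=k_const)
    times = np.arange(n_t) * dt
    return assemble_cochleogram(Z, grid, times,
                                p or FilterParameters(),
                                meta={"rate": 1.0 / dt})


def save_cochleogram_tsv(path, coch: Cochleogram) -> None:
    """Delimited-text export: commented header, then one line per
    (scale, time) sample with Re/Im columns."""
    with open(path, "w") as fh:
        fh.write("# cochleogram\n")
        fh.write(f"# n_scales={coch.Z.shape[0]} n_times={coch.Z.shape[1]} "
                 f"dt={coch.dt!r} k_const={coch.grid.k_const!r}\n")
        fh.write("# scale\ttime\tre\tim\n")
        for j, a in enumerate(coch.grid.scales):
            for k, t in enumerate(coch.times):
                z = coch.Z[j, k]
                fh.write(f"{a!r}\t{t!r}\t{z.real!r}\t{z.imag!r}\n")


# ---------------------------------------------------------------------------
# configuration helpers
# ---------------------------------------------------------------------------

def filter_parameters_from_config(cfg: dict) -> FilterParameters:
    """Build filter parameters from a config mapping; a ``preset`` key
    selects a named preset, other keys override its fields."""
    import dataclasses

    cfg = dict(cfg or {})
    preset = cfg.pop("preset", None)
    base = PRESETS[preset] if preset else FilterParameters()
    known = {f.name for f in dataclasses.fields(FilterParameters)}
    unknown = set(cfg) - known
    if unknown:
        raise KeyError(f"unknown filter config keys: {sorted(unknown)}")
    return dataclasses.replace(base, **cfg)


def tonotopic_map_from_config(cfg: dict) -> TonotopicMap:
    cfg = dict(cfg or {})
    kind = cfg.pop("kind", "exponential")
    K = cfg.pop("K_hz", 20000.0)
    l = cfg.pop("l_mm", 6.6)
    S = cfg.pop("S_hz", 200.0 if kind == "shifted" else 0.0)
    if cfg:
        raise KeyError(f"unknown tonotopy config keys: {sorted(cfg)}")
    return TonotopicMap(kind=kind, K=K, l=l, S=S, units="hz")


def parse_vector_field(expr: str):
    """Parse a symbolic vector-field expression in ``omega`` into a
    vectorized callable (e.g. ``"-omega*log(20000/omega)"``)."""
    import sympy

    omega = sympy.Symbol("omega", positive=True)
    tree = sympy.sympify(expr, locals={"omega": omega})
    fn = sympy.lambdify(omega, tree, modules="numpy")

    def v(w):
        out = np.asarray(fn(np.asarray(w, dtype=float)), dtype=float)
        return out if out.ndim else float(out)

    return v


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

_REQUIRED_PIPELINE_KEYS = ("signal", "grid")


def run_pipeline(config: dict, out_dir=None) -> dict:
    """generate/load -> analytic transform -> structure residuals ->
    holomorphy diagnostic -> report.

    Returns the report dict; with ``out_dir`` also writes
    ``report.json`` plus a per-row residual table
    (``residuals.jsonl``).  Fully deterministic for a given config.
    """
    for key in _REQUIRED_PIPELINE_KEYS:
        if key not in config:
            raise KeyError(f"missing required config key: {key!r}")

    sig_cfg = dict(config["signal"])
    wav = sig_cfg.pop("wav", None)
    if wav is not None:
        if sig_cfg:
            raise KeyError("signal config mixes 'wav' with generator keys")
        signal = read_wav(wav)
        spec_info = {"wav": str(wav)}
    else:
        spec = GeneratorSpec(**sig_cfg)
        signal = generate(spec)
        spec_info = asdict(spec)

    p = filter_parameters_from_config(config.get("filter"))
    gcfg = dict(config["grid"])
    grid = scale_grid_for_band(
        2 * np.pi * float(gcfg["f_lo_hz"]),
        2 * np.pi * float(gcfg["f_hi_hz"]),
        scales_per_decade=int(gcfg.get("scales_per_decade", 128)),
    )

    coch = analytic_transform(signal, grid, p,
                              taper=float(config.get("taper", 0.0)))
    res = structure_residuals(coch, p, order=int(config.get("fd_order", 2)))
    holo = dbar_residual(coch, p)

    interior = res.interior
    rows = []
    for j in range(len(grid)):
        sel = interior[j]
        if not np.any(sel):
            continue
        rows.append({
            "row": j,
            "scale": float(grid.scales[j]),
            "eq1_rms": float(np.sqrt(np.mean(res.residual1[j, sel] ** 2))),
            "eq2_rms": float(np.sqrt(np.mean(res.residual2[j, sel] ** 2))),
            "complex_rms": float(np.sqrt(np.mean(
                np.abs(res.residual_complex[j, sel]) ** 2))),
        })

    import dataclasses as _dc

    report = {
        "signal": spec_info,
        "filter": _dc.asdict(p),
        "grid": {"n_scales": len(grid), "log_step": grid.log_step},
        "residuals": {
            "eq1_rms": res.eq1_rms,
            "eq2_rms": res.eq2_rms,
            "complex_rms": res.complex_rms,
            "complex_rms_relative": res.complex_rms_relative,
            "complex_rms_weighted": res.complex_rms_weighted,
            "complex_rms_weighted_relative": res.complex_rms_weighted_relative,
        },
        "holomorphy": holo,
        "versions": _versions(),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        with open(out_dir / "residuals.jsonl", "w") as fh:
            for row in rows:
                fh.write(json.dumps(row, sort_keys=True) + "\n")
    report["rows"] = rows
    return report


def _versions() -> dict:
    import scipy

    from . import __version__

    return {"cochlea": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__}
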