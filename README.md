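# cochlea

A level-dependent extremal-function cochlear filterbank with the analytic
wavelet transforms, structure-equation diagnostics, holomorphic solution
theory and generalized one-parameter invariance groups built on top of it.

The model: the basilar-membrane transfer function is taken to be an
extremal (coherent-state) function of the uncertainty inequality for the
affine-times-circle symmetry group, with a scalar level parameter `c`
indexing the linearization of the compressive cochlea (`c ~ 1` high sound
level, `c >> 1` low level). The analytic response `Z f(a, t)` of a sound
then satisfies a linear system — the structure equations — relating the
scale- and time-derivatives of its log-amplitude and phase, exactly at
`c = 1`. In the variable `z = t - a*beta + i*a*gamma` the solutions
factor as `e^{P(a)} G(z)` with `G` holomorphic and determined by the
input signal.

## Layout

| module                 | contents |
|------------------------|----------|
| `cochlea.tonotopy`     | position-frequency maps (exponential / shifted), scaling variables, scale grids |
| `cochlea.filters`      | extremal filter family `h_c`, localization / normalization, transfer function, modulus peak, uncertainty functionals |
| `cochlea.transform`    | Hilbert transform, (analytic) wavelet transform, cochleograms, impulse responses with acausality diagnostics |
| `cochlea.structure`    | structure-equation coefficients, residual fields, phase/amplitude exchange |
| `cochlea.holomorphic`  | particular solution `P`, holomorphic `G` of tones / AM / harmonic complexes / clicks, d-bar residuals, frequency glides |
| `cochlea.groups`       | one-parameter groups from vector fields: flows, conjugation maps, group wavelet transforms, reconstruction, two worked example models |
| `cochlea.signals` / `cochlea.cli` | synthetic signal generators, WAV and cochleogram I/O, config, pipeline, CLI |

## CLI

```sh
cochlea tonotopy --freq 500            # place <-> characteristic frequency
cochlea filterbank --preset fig1 --place-mm 15 --out table.tsv
cochlea generate --kind tone --freq-hz 200 --rate 8192 --duration 0.5 --out tone.wav
cochlea transform tone.wav --preset fig1 --f-lo-hz 120 --f-hi-hz 320 --out coch.bin
cochlea residuals coch.bin --preset fig1 --c 1   # JSON-lines per scale row
cochlea holo coch.bin --preset fig1 --c 1        # holomorphy report
cochlea impulse --preset fig5 --cf-hz 200        # click response + acausal fraction
cochlea glide --preset fig6                      # frequency-glide profile table
cochlea pipeline --config cfg.yaml --out-dir out/
```

Frequencies at the CLI are in Hz; internally everything is circular
frequency (rad/s). Filter presets `fig1`, `fig2`, `fig5`, `fig6` carry
the worked parameter sets; any field can be overridden per flag or
config key.

## Conventions

Fourier synthesis `f(t) = (1/2pi) \int fhat e^{i omega t} domega`;
Hilbert transform with `H cos = sin`; filter row at scale `a` is
`sqrt(a) h_c(a omega)`, so the response of `A cos(nu t)` is exactly
`A sqrt(a) h_c(a nu) e^{i nu t}`. Residual norms are reported plain and
`|Z|`-energy-weighted; the weighted form is robust near zeros of the
field. With the phase convention used here (`arg h = eps - alpha log w -
beta w`, `alpha < 0`), the constant in the phase structure equation is
`-alpha`.
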