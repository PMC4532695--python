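# lileychaos

Lyapunov spectra, attractor classification and four-dimensional-chaos
mapping for the macrocolumnar Liley mean-field model of the
electroencephalogram (EEG).

## The problem

Mean-field (mesoscopic) models describe the averaged activity of cortical
neural populations rather than individual neurons.  The macrocolumnar Liley
model couples the mean soma membrane potentials `h_e, h_i` of an excitatory
and an inhibitory population through critically damped second-order synaptic
kinetics (alpha-function postsynaptic potentials), giving ten first-order
nonlinear ODEs; `h_e` is the model's EEG correlate.  The external
(thalamo-cortical) input pulse densities `p_ee` and `p_ei` (ms⁻¹) are the
physiologically most variable parameters and span the plane over which the
dynamics are mapped.

A chaotic attractor of an `n`-dimensional flow with ordered Lyapunov
exponents `λ₁ ≥ λ₂ ≥ … ≥ λ_n` (s⁻¹, base e) has

* **topological dimension** `D` — the largest integer with
  `λ₁ + … + λ_D ≥ 0`; the attractor needs at least `D + 1` integer
  dimensions to exist in;
* **Kaplan–Yorke dimension** `D_KY = D + (λ₁ + … + λ_D)/|λ_{D+1}|`.

**Four-dimensional chaos (FDC)** is chaos with a *single* positive exponent
(`λ₂ = 0`, distinguishing it from hyperchaos) whose attractor nevertheless
requires at least four dimensions.  The dimensional shortcut implemented
here: if `λ₁ ≥ 1 s⁻¹`, `λ₂ = 0` (within tolerance) and `λ₁ > |λ₃|`, then
`λ₁+λ₂+λ₃ > 0`, so `D ≥ 3` and `D_KY > 3` — decidable from the **three**
leading exponents alone.  Computing only the top `k` exponents via a
tangent system with built-in continuous Gram–Schmidt orthonormalization
needs `n + k·n + k` equations: 43 instead of the 120 the full spectrum
would require at `n = 10`.

## What the package provides

| module | contents |
|---|---|
| `lileychaos.params` | `LileyParameters` (validated physiological schema), TOML I/O, shipped fixtures |
| `lileychaos.model` | right-hand side, analytic Jacobian, equilibria, adaptive simulation |
| `lileychaos.tangent` | `compute_spectrum` (continuous Gram–Schmidt) and `benettin_spectrum` (discrete QR oracle) |
| `lileychaos.classify` | `topological_dimension`, `kaplan_yorke`, `classify` (point / periodic / chaotic / chaotic_4d) |
| `lileychaos.sweep` | seeded random sweeps of the `(p_ee, p_ei)` rectangle, checkpoint/resume, Wilson binomial intervals |
| `lileychaos.benchmarks` | systems with known Lyapunov structure (diagonal linear, Hopf normal form, Lorenz-63) |
| `lileychaos.plotting`, `lileychaos.cli` | blue–green–red LLE maps with FDC overlay; `lileychaos` command-line tool |

Install and test:

```sh
pip install --no-build-isolation -e .
python -m pytest -q tests/
```

Two test outcomes are expected to fail and are left failing deliberately:
the shipped `standard` parameter fixture could not be verified against the
exact published table of the four-dimensional-chaos studies (see the fixture
header and `docs/methods.md`), so the two checks conditioned on that
correspondence report the discrepancy honestly.

## Worked example

Classify the published reference spectrum (9.6, 0, −6.4, −11.5) s⁻¹:

```
$ lileychaos classify --lambdas 9.6,0,-6.4,-11.5
label = chaotic_4d
D = 3
D_KY = 3.27826
hyperchaos = False
thresholds: chaos>=1.0 s^-1, zero_tol=0.5 s^-1
```

`D = 3` because `9.6 + 0 − 6.4 = 3.2 ≥ 0` while the four-term sum is
`−8.3 < 0`; the attractor therefore needs at least four dimensions, and
`D_KY = 3 + 3.2/11.5 ≈ 3.278 > 3`: four-dimensional chaos with a single
positive exponent.

Spectrum of a benchmark system (units: the package works in ms and reports
exponents per second, base e):

```
$ lileychaos lyap --system lorenz63 --k 3 --t-transient 50 --t-run 2000 --seed 1
lambda_1 = +907.0203 s^-1
lambda_2 = -0.1251 s^-1
lambda_3 = -14573.5618 s^-1
```

A positive, a zero (flow direction) and a strongly negative exponent — the
classic chaotic signature; `λ₁+λ₂+λ₃` matches the constant Jacobian trace
`−(σ+1+β) = −13666.7 s⁻¹` to better than 1%.

Sweep a rectangle of the thalamic-input plane and render the map:

```sh
lileychaos sweep --n 500 --seed 42 --out results.csv --summary summary.json \
                 --checkpoint ckpt.csv
lileychaos plot --results results.csv --out map.png
```

The summary JSON reports, with Wilson 95% intervals, the fraction of
clearly chaotic points (largest exponent ≥ 1 s⁻¹) and the fraction of those
exhibiting four-dimensional chaos.

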