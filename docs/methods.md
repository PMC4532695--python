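# Methods

## Model

The macrocolumnar (spatially homogeneous) Liley model describes two coupled
mean neural populations, excitatory `e` and inhibitory `i`.  State vector
(fixed ordering, used identically by the tangent dynamics):

    (h_e, h_i, I_ee, J_ee, I_ei, J_ei, I_ie, J_ie, I_ii, J_ii)

`h` are mean soma membrane potentials (mV), `I_jk` the postsynaptic
activation of synapse type `j → k` (mV) and `J_jk = dI_jk/dt`.  Equations
(time in ms):

    tau_e dh_e/dt = (h_e_rest - h_e) + psi_ee(h_e) I_ee + psi_ie(h_e) I_ie
    tau_i dh_i/dt = (h_i_rest - h_i) + psi_ei(h_i) I_ei + psi_ii(h_i) I_ii
    (d/dt + gamma_jk)^2 I_jk = e Gamma_jk gamma_jk (N_jk S_j(h_j) + p_jk)

with reversal-potential weights `psi_jk(h) = (h_j_eq - h)/|h_j_eq - h_k_rest|`
(normalized to ±1 at rest, zero at the reversal potential) and logistic
firing rates `S_q(h) = S_q_max / (1 + exp(-sqrt(2)(h - mu_q)/sigma_q))`.
The `e·Gamma·gamma` factor normalizes the critically damped (double pole at
`-gamma_jk`) synaptic impulse response to peak at exactly `Gamma_jk` at time
`1/gamma_jk`; this is verified in the tests by fine integration.  The
external pulse densities `p_jk` follow the source-first index convention:
`p_ee`/`p_ei` are excitatory-type external inputs to the `e`/`i`
populations, the inhibitory-type `p_ie`/`p_ii` default to zero.

The Jacobian is analytic; only two columns (through `dS_e/dh_e` and
`dS_i/dh_i`) are state-dependent in the eight synaptic rows.  It is tested
against central finite differences at 100 random states.

## Parameter fixtures and their provenance

`fixtures/standard.toml` carries the standard physiological
parameterization of this model family (resting potentials −70 mV, reversal
potentials +45/−90 mV, membrane constants 94/42 ms, PSP amplitudes 0.71 mV
with rate constants 0.3/0.065 ms⁻¹, 3034/536 intracortical connections,
sigmoid ceiling 0.5 ms⁻¹ at threshold −50 mV with 5 mV spread), plus the
reference thalamic inputs `p_ee = 24.2453`, `p_ei = 2.299` ms⁻¹.

**Transcription status.**  The published four-dimensional-chaos analyses of
this model report, at those reference inputs, the leading exponents
(9.6, 0, −6.4, −11.5) s⁻¹.  The exact parameter table behind that result is
not reproduced in this repository's sources, and with the standard values
above the model instead settles onto a stable large-amplitude relaxation
oscillation (exponents ≈ (0, −64, −65) s⁻¹).  This was probed extensively:
350+ random points over the input rectangle and beyond, both index
conventions for the swept inputs, many random initial conditions
(the reference point has a single, unstable equilibrium — no coexisting
chaotic attractor was found), and single-parameter variants.  The
correspondence between the shipped fixture and the published table is
therefore **unverified**, the two test-suite checks conditioned on it fail
by design, and quantitative comparisons with the published chaos fractions
(21.8% of chaotic points, ~8% of all points) should not be made with this
fixture.  Everything else in the package — model mechanics, both Lyapunov
backends, the classification calculus, sweep statistics — is validated
independently of it.  `fixtures/demo.toml` is a synthetic, clearly labeled
plausible set for examples.

## Lyapunov spectra

Two backends share one compiled (numba) RK4 core and one contract:

* **continuous** — Gram–Schmidt orthonormalization built into the tangent
  ODEs.  With `u_i = J e_i`:

      de_i/dt  = u_i - (e_i·u_i) e_i - sum_{j<i} [(e_j·u_i) + (e_i·u_j)] e_j
      dnu_i/dt = e_i·u_i

  integrated together with the base flow as one augmented system of
  `n + k·n + k` equations (43 at `n=10, k=3`; 120 for the full spectrum).
  `lambda_i = nu_i(T)/T`.
* **discrete** — Benettin's method: variational equations for a tangent
  frame, re-orthonormalized by modified Gram–Schmidt (positive-diagonal QR)
  at fixed intervals, exponents from the time-averaged log of the R
  diagonal.  It also accumulates the time-averaged Jacobian trace, giving
  the `sum(lambda) = <tr J>` identity test for full spectra.

The two backends are mutually validating: they agree on every benchmark and
their shared analytic truths (diagonal linear flow: exact rates; Hopf
normal form: (0, −2μ); Lorenz-63: cross-method agreement within 2% and the
constant-trace identity within 1%).

Numerical choices:

* Fixed-step classical RK4 for base, variational and augmented flows
  (deterministic step count, bitwise-reproducible runs); step 0.05 ms for
  the cortical model (fastest synaptic pole 0.3 ms⁻¹, so ≥ 60 steps per
  e-folding), 0.01 ms for the stiffer benchmarks, 0.002 for Lorenz.  The
  user-facing `simulate` uses adaptive stiffness-capable scipy solvers
  (LSODA default, rtol 1e-8 / atol 1e-10) instead.
* Hard re-orthonormalization every 10 ms as numerical insurance for both
  backends (the continuous stabilization is not trusted over long runs);
  the log-norms removed are folded into the accumulators so the estimates
  stay exact.  Frame-norm errors self-amplify at roughly `2|lambda|` on
  contracting directions, so the continuous core additionally checks drift
  every 5 steps and renormalizes early beyond a 1e-9 defect.  Orthonormality
  at checkpoints is asserted to 1e-6.
* Tangent frames initialize as the QR of a seeded Gaussian matrix; the
  cortical initial state is the numerically found equilibrium plus a seeded
  0.1 mV perturbation of the membrane potentials, making every run a pure
  function of (parameters, times, seed, method).
* Exponents accumulate per ms and are reported per second (×1000), base e,
  sorted descending; no exponent is ever forced to zero — zero-tolerances
  are applied downstream by the classifier.
* Default accumulation times: 10 s transient, 100 s run.  A `converged`
  diagnostic (running estimates moving less than max(2%, 0.5 s⁻¹) over the
  final 20% of the run) is reported rather than auto-extending the run,
  keeping per-point cost bounded and seeds meaningful; callers rerun with a
  longer `t_run` when it is false.  The test suite and the sweeps it runs
  use shorter windows (1.5–30 s) chosen per test: bookkeeping tests need no
  converged exponents, benchmark-recovery tests use windows where the
  finite-time alignment transient (which decays as 1/T) sits well below the
  asserted tolerance.

## Classification

From ordered exponents (s⁻¹): topological dimension `D` = largest prefix
with non-negative sum (0 for an all-negative spectrum); Kaplan–Yorke
dimension `D + (sum_{i<=D} lambda_i)/|lambda_{D+1}|`, undefined (flagged,
not 0) when fewer than `D+1` exponents are supplied or the total sum is
non-negative.  Labels: `point` (`lambda_1 < -zero_tol`), `periodic`
(anything below the chaos threshold, including the slow-convergence band),
`chaotic` (`lambda_1 >= 1 s⁻¹`), `chaotic_4d` (additionally
`|lambda_2| <= zero_tol` and `lambda_1 > |lambda_3|`).  Two or more
positive exponents set a hyperchaos flag but keep the label `chaotic` —
four-dimensional chaos specifically requires a single positive exponent.

The chaos threshold of 1 s⁻¹ guards against exponents converging slowly to
zero on periodic orbits.  `zero_tol` defaults to 0.5 s⁻¹; no published
value exists for it, it is configurable, and it is recorded in every
output, so the sensitivity of FDC counts to it can be reported rather than
assumed.  The dimensional shortcut itself — premise: one positive exponent
exceeding the accumulated contraction through `lambda_3`, dissipative
closure at `lambda_4`; conclusion: `D >= 3` and `D_KY > 3` — is exercised
as an executable theorem over 10,000 random spectra.

## Sweeps

Input pairs are sampled i.i.d. uniform over the open-closed rectangle
(0, 30] × (0, 10] ms⁻¹ (the biologically relevant thalamic range).  Each
point gets an independent seed via `SeedSequence((sweep_seed, index))`, so
results are identical under serial, parallel (joblib) or resumed execution;
the append-only checkpoint enables bitwise-identical kill/resume, and this
is tested.  Diverged points (any state component beyond 1e6) are recorded
with flags and excluded from denominators; the divergence rate is itself a
reported diagnostic.  Summary fractions (chaotic among valid, FDC among
chaotic, FDC among all) carry Wilson 95% binomial intervals
(statsmodels), which is what makes small sweeps comparable against
fractions measured on much larger published samples.  `k = 3` per point by
default (the shortcut needs no more); `k = 4` can be requested to verify
`D_KY > 3` directly on FDC hits.

## What the synthetic benchmarks do and do not show

The benchmark systems (diagonal linear, Hopf, Lorenz-63) have analytically
known or internally checkable Lyapunov structure and use the same ms/s unit
convention as the cortical model, so they exercise the full pipeline —
integration, both orthonormalization schemes, unit conversion,
classification — against exact truth.  They do not emulate the cortical
model's specific difficulties: its near-degenerate exponent pairs
(≈ −64, −65 s⁻¹ at the reference point), multistability, or slow
convergence of the zero exponent on long-period relaxation oscillations.
Passing benchmarks therefore validates the machinery, not any particular
physiological claim.

## Known limitations

* The fixture/transcription caveat above is the dominant one: absolute
  statements about the published chaos fractions cannot be reproduced with
  the shipped parameter set.
* Spatiotemporal (PDE) formulations, long-range propagation, stochastic
  input, covariant Lyapunov vectors and time-series (embedding) exponent
  estimation are out of scope.
* Near-degenerate exponents get no special treatment; ordering ties break
  by computation order.
* The continuous backend reports no trace average (its reduced system never
  forms the full frame); trace-identity checks use the discrete backend
  with `k = n`.
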