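# Methods

## The modeling problem

Deep brain stimulation (DBS) suppresses parkinsonian rest/postural tremor
when its parameters — pulse amplitude `A` (V), frequency `F` (Hz) and pulse
width `µ` (µs) — are chosen well. Mechanistic models of the basal
ganglia are too uncertain to support controller design, but the *input–
output* behaviour from stimulation amplitude to filtered tremor is simple:
the filtered tremor is close to a sinusoid in the 4–6 Hz band whose
amplitude depends on how far the stimulation sits from a patient- and
setting-specific **nominal amplitude** `A_n` at which the tremor vanishes.
`tremorloop` models that input–output map, estimates `A_n` online from the
measured tremor alone, and wraps the estimator in a grid search over
`(F, µ)`.

## Tremor plant

The plant is a second-order oscillator with time-varying strength `C(t)`
and angular frequency `ω(t)`:

```
dx1/dt = x2 + C(t) (u − A_n)
dx2/dt = −ω(t)² x1 − a φ(x1) − b x2          y = y_scale · x1
```

`u` is the commanded stimulation amplitude (V). With `a = b = 0` this is the
**linear model**: an undamped oscillator that no constant (open-loop)
stimulation can quiet once excited — stimulating exactly at `A_n` merely
stops pumping it. The **nonlinear model** adds a locally Lipschitz
nonlinearity `φ` (default `φ(x) = x³`; the FitzHugh–Nagumo cubic is also
provided) with coefficient `a`, and a stabilization (damping) term `b x2`.
The origin with `u = A_n` is an equilibrium of both variants (`φ(0) = 0`).

Two structural choices deserve comment, because the mathematical literature
on oscillator tremor models leaves both open:

* **Output map** `y = x1`. The measured tremor is the oscillating state;
  a scale factor converts to sensor units.
* **Input channel.** The stimulation mismatch `C (u − A_n)` enters the
  `x1` equation rather than the classic forced-oscillator `x2` channel.
  This is deliberate: it is the unique second-order structure for which a
  *strictly output-feedback* adaptive law (using only `y`, never `x2`)
  admits a Lyapunov function in which both uncertain cross terms cancel
  exactly (see below). With the input in the `x2` channel, output feedback
  of `x1` alone cannot yield a negative-definite state quadratic; the
  mismatch would have to be estimated from unmeasured velocity. The
  observable consequences are the same: open-loop tremor RMS grows
  linearly with `C |u − A_n| / ω`, the oscillation frequency is exactly
  `ω`, and stimulating at `A_n` silences the model. One consequence
  differs and is worth knowing: under an amplitude *shortfall* with
  damping `b > 0`, the model settles to a nonzero output offset
  `y ≈ −b C Δu / (ω² + b C k)` rather than a sustained oscillation — the
  "tremor persists" signature in the invalid-amplitude scenario is this
  offset plus re-excitation at parameter switches.

The drift is isolated in one function (`models.drift`) so alternative
couplings can be swapped without touching the integrator or controller.

Parameter schedules are constant, piecewise-constant (left-closed: a new
value applies *from* its breakpoint) or piecewise-linear, with constant
extrapolation. Integration is split at breakpoints so steps never degrade
the adaptive step-size control.

## Adaptive output-feedback law

With measured output `y` and one controller state `û` (the estimate of
`A_n`):

```
u_raw  = û − k y                (control law)
dû/dt  = −γ y                   (adaptation law)
```

At `y = 0` the control passes `û` through unchanged and the adaptation
freezes. Consider, for `ũ = û − A_n`,

```
V = x1² / (2 C(t)) + s x2² / 2 + ũ² / (2 γ)
```

which is positive definite (`C_min ≤ C(t) ≤ C_max`). Differentiating along
the raw closed loop:

* the input term `(x1/C) · C (ũ − k x1)` loses its unknown coefficient
  because of the `1/C` weight, leaving `x1 ũ − k x1²`;
* the adaptation contributes `ũ (−γ x1)/γ = −x1 ũ`, cancelling `x1 ũ`
  **exactly** (this identity is unit-tested);
* the weight's own time derivative contributes `−(Ċ/2C²) x1²`, bounded by
  `C_dot_max / (2 C_min²) · x1²`;
* the remaining cross terms are bounded using the parameter box and the
  Lipschitz bound `|φ(x1)| ≤ L |x1|`, splitting the nonlinearity term with
  a Young-inequality slack `ε`.

The result is `dV/dt ≤ zᵀ M z` with `z = (|x1|, |x2|)` and

```
M11 = −k + C_dot_max/(2 C_min²) + s a_max L ε / 2
M12 = θ/2,   θ = max over box corners of |1/C − s ω²|
M22 = −s b_min + s a_max L / (2 ε)
```

`M ≺ 0` (max eigenvalue below `−1e-9` by default; the strict inequality
needs a numeric margin) certifies `V` non-increasing, hence `y → 0`. If the
tremor reaches a steady state in finite time, the plant equilibrium forces
`C ũ = 0` with `b > 0`, i.e. `û = A_n`: the estimate is exact. Convergence
of the estimate genuinely needs the damping `b`; on the linear model the
loop still silences `y` but `û` can park away from `A_n` (the undamped
`x2` absorbs the mismatch). This is why `b` is called the stabilization
term and why the certificate requires a *lower* bound `b_min` on `b` while
the nonlinearity needs an *upper* bound `a_max` — the bound box stores
exactly those one-sided bounds.

The linearized constant-parameter loop `(x1, x2, ũ)` has characteristic
polynomial `λ³ + (b + Ck) λ² + (Ckb + ω² + Cγ) λ + Cγb`, Hurwitz for any
positive `k, γ, b, C, ω` — the certificate is conservative, which is its
job. The adaptation gain `γ` cancels out of `M`; its default
`ω_max²/C_min` makes the adaptation stiffness comparable to the plant's so
the slow (estimation) eigenvalue sits near `b` rather than far below it.

`V` is recorded along every simulated trajectory (the runtime needs the
instantaneous `C(t)`, so `lyapunov_value` takes it as an argument), and the
monotone decrease is *checked*, never assumed. Finite-time settling is
likewise detected (`steady_state_time`: a sliding window on `max |y|` and
on the increments of `û`), never assumed.

## Gain synthesis

The certificate involves only scalars, so synthesis is a deterministic
logarithmic grid (20 points/decade over 4 decades per scalar, centred on
analytic guesses: `s* = (1/C_min + 1/C_max)/(ω_min² + ω_max²)` minimizes
`θ`, `ε* = a_max L / b_min` balances the nonlinearity split). The first
feasible point in a fixed iteration order wins, followed by greedy
multiplicative coordinate descent on the **normalized** margin
`−λ_max(M)/‖M‖_F`. The normalization matters: the absolute margin grows
without bound in `k`, and refining it would drive the loop needlessly
stiff; the normalized margin rewards a well-conditioned negative `M`.
Negative definiteness is decided by `eigvalsh` and cross-checked against
the Sylvester leading-minor criterion in the tests. Infeasibility after
exhausting the box raises a structured report (bounds plus search ranges).
A convex feasibility refinement was considered and dropped: the 2×2 scalar
problem does not need an LMI solver.

## Actuator conditioning

Safety clamps the commanded amplitude to `[u_min, u_max]` (0–5 V default)
and limits its slew. The rate limiter is a first-order tracking law with a
hard clamp, `ds/dt = clip(rl_gain (u_in − s), −R, R)`; its state is the
delivered amplitude. Defaults `R = 1 V/s`, `rl_gain = 50/s`: visibly slower
than the control loop, faster than the tremor envelope. The slew bound
holds exactly in continuous time; sampled secant slopes can exceed it by
the dense-output interpolation error of the integrator (≲0.1%), which is
the tolerance the tests use. A zero-phase Butterworth band-pass (3–12 Hz
default) is provided for offline isolation of the tremor band.

The closed-loop simulator integrates plant ⊕ adaptation ⊕ rate limiter as
one augmented ODE (adaptation as a continuous state, not discretely
stepped, to keep the Lyapunov check free of sampling artifacts). Loop mode
`raw` feeds `u_raw` to the plant — the setting the certificate covers;
`conditioned` feeds the rate-limited output — the realistic actuator path.
Both signals are recorded either way. Before the controller-on time the
plant runs open loop at a configured baseline amplitude (default 0 V) with
`û` frozen.

Optional realism features, all off by default: anti-windup projection of
`û` onto the actuator range (the continuous projection can overshoot the
bound by one solver step, ~1e-5 V); seeded zero-order-hold Gaussian
measurement noise; and a causal continuous-time Butterworth band-pass
between sensor and controller. A known limitation of the last: the
adaptation integrates the *low-frequency* content of `y` (the amplitude
error appears as an output offset), so an in-loop band-pass that removes DC
degrades the estimate. The certified configuration is unfiltered.

## Stimulation-parameter selection

For each grid cell `(F_i, µ_j)` one conditioned closed-loop trial runs from
a fresh state (no carry-over between trials; trials are independent and
individually reproducible). Over a post-settling window `[T_s, T_e]` the
trial computes the amplitude estimate `Â_ij` — the arithmetic mean of the
delivered (rate-limited) amplitude, switchable to the saturated command —
and the tremor power `P_ij`, the RMS of `y`. `T_s` defaults to the detected
settling time, falling back to 50% of the trial length. The selected cell
is the row-major argmin of the power grid; the recommended DBS setting is
`(Â, F, µ)` at that cell. Because `Â` averages a continuously adapted
signal, the amplitude is chosen from the whole continuum `[u_min, u_max]`.

How `(F, µ)` shape the plant has no accepted biophysical model, so the map
is a user-supplied factory `(F, µ) → plant`. The packaged factory encodes
the essential dichotomy: some settings admit an in-range nominal amplitude
and some do not.

## Packaged scenarios (what the synthetic data does and does not emulate)

All numeric values are the package's own documented defaults
(`paper_exact: false` when serialized): tremor at 5 Hz (band 4–6 Hz),
actuator range 0–5 V, DBS pulse trains at 130/180 Hz with 90 µs width.
Case scenarios initialize on the open-loop equilibrium of the unstimulated
plant plus a unit tremor deflection, so the pre-controller baseline is
tremor, not an equilibrium transient.

* **Case I** (invalid amplitude): `A_n = 7 V > u_max`, plant
  `C = 50, b = 2, a = 0.5`, frequency step 5 → 4.5 Hz at `t = 25 s`,
  anti-windup projection enabled so the pinning of `û` at 5 V is visible in
  the estimate itself. Outcome: non-converged, trailing tremor power ≈ 34%
  of baseline.
* **Case II** (valid amplitude): `A_n = 3 V`, same plant family, different
  stimulation frequency at the same pulse width. Outcome: tremor suppressed
  to solver noise, `û → A_n` to ~1e-9 relative.
* **Amplitude sweep** (model validation): seven open-loop linear-model runs
  at constant amplitudes 0–5 V around `A_n = 2.5 V`; tremor RMS is exactly
  `C |A − A_n| / (ω√2)` from rest.
* **Recovery ensemble**: 20 randomized raw-mode scenarios, `A_n` uniform in
  `[0.5, 4.5] V`, constant `C ∈ [5, 15]`, `ω/2π ∈ [4, 6] Hz`,
  `a ∈ [0, 0.05]` (with `φ = x³` certified on `|x1| ≤ 6.5`, `L = 126.75`),
  `b ∈ [1, 2]`; 2 s open-loop, 20 s closed-loop at 1 kHz sampling. These
  sizes keep the whole ensemble under ~10 s of compute while leaving the
  slowest estimation eigenvalue (~`b/2`) a dozen time constants to settle.

What the generator does **not** emulate: sensor noise and quantization
(opt-in only, and not part of the certified configuration), stochastic
parameter drift (schedules are deterministic), pulse-level stimulus
waveforms (amplitude/frequency/width are abstract parameters), multi-joint
or intention/action tremor, and any physiological `(F, µ) → plant`
coupling. Passing tests therefore demonstrate correctness of the method
under its own model class, not clinical performance.

## Numerical choices

* Integrator: adaptive RK45, `rtol = 1e-8`, `atol = 1e-10`, output sampled
  at 1 kHz; segments split at `t_on` and all schedule breakpoints. Stiff
  behaviour is not expected (the refinement's normalized margin keeps `k`
  moderate precisely so the fast loop eigenvalue `≈ −(b + Ck)` stays
  resolvable).
* Negative definiteness: `λ_max < −1e-9`.
* Lipschitz estimation: adjacent-grid-pair secant slopes (the all-pairs
  maximum equals the adjacent-pair maximum, since every secant is a convex
  combination of adjacent ones), plus the analytic `sup |φ'|` where
  available, times a safety factor (default 1.05) because sampling
  under-estimates suprema.
* Ties in the power grid break row-major (lowest `i`, then `j`); a NaN
  power is an error naming the cell.
* Degenerate inputs (empty averaging windows, inverted ranges, non-finite
  states, bands outside Nyquist) raise `ValueError` rather than returning
  NaN.

## Known limitations

* The Lyapunov guarantee covers the raw loop with parameters inside the
  bound box; the conditioned loop (saturation + rate limiter) is validated
  empirically through the case scenarios, not certified.
* `û` has no convergence guarantee without plant damping (`b_min > 0`) or
  when `A_n` lies outside the actuator range — the latter is exactly what
  the tuning grid search detects and rejects.
* The certificate is conservative: feasibility requires a box small enough
  for the corner bound `θ`, so very wide `C`/`ω` ranges may be refused even
  though every individual plant in them is stabilizable.
* The `(F, µ)` dependence of the plant is declarative (a factory), not
  predictive.
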