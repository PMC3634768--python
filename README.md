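# tremorloop

Closed-loop deep-brain-stimulation (DBS) simulation and tuning: oscillator
tremor models, a Lyapunov-certified adaptive estimator of the nominal
stimulation amplitude, actuator signal conditioning, and an exhaustive
frequency × pulse-width grid search that selects the DBS setting minimizing
measured tremor power.

**Who it is for.** Researchers in computational neuroscience and control
engineering who want a reproducible sandbox for feedback-controlled DBS:
how much can be guaranteed when the only measurement is the filtered tremor
signal from a patient's fingers, the plant is a crude time-varying
oscillator, and the actuator is a 0–5 V stimulator with a slew limit?

## The model and the method

Filtered rest/postural tremor is nearly sinusoidal, so the map from
stimulation amplitude `u` (V) to tremor `y` is a second-order oscillator
with time-varying strength `C(t)` and angular frequency `ω(t)` (rad/s):

```
dx1/dt = x2 + C(t) (u − A_n)
dx2/dt = −ω(t)² x1 − a φ(x1) − b x2          y = x1
```

`A_n` is the nominal amplitude at which the tremor vanishes for the chosen
stimulation frequency `F` and pulse width `µ`; `a φ(x1)` is a Lipschitz
nonlinearity and `b x2` a stabilization (damping) term (`a = b = 0` is the
linear model). The adaptive output-feedback law

```
u = û − k y,        dû/dt = −γ y
```

carries the Lyapunov function `V = x1²/(2C) + s x2²/2 + (û − A_n)²/(2γ)`.
Given box bounds on `C`, `ω`, `|dC/dt|`, `|a|`, a lower bound on `b` and a
Lipschitz constant `L` for `φ`, a 2×2 certificate matrix `M` built from the
scalar gains `(k, s, ε)` satisfies `dV/dt ≤ zᵀ M z`, `z = (|x1|, |x2|)`:
if `M ≺ 0`, the tremor converges to zero, and if it settles in finite time
the estimate `û` equals `A_n` exactly. Gains are found by a deterministic
grid search over the scalars (`tremorloop.synthesize_gains`).

Around the certified core: saturation to `[0, 5] V`, a slew-rate limiter
(first-order tracking with hard clamp), optional measurement noise and
band-pass filtering, and a tuning loop that runs one adaptive-estimation
trial per `(F_i, µ_j)` cell, scores each by post-settling tremor power
(RMS), and returns the power-minimizing setting together with the averaged
delivered amplitude `Â`. See `docs/methods.md` for the full derivation and
design rationale.

## Worked example

`examples/run_closed_loop.py` runs the packaged valid-amplitude scenario
(`A_n = 3 V`, tremor at 5 Hz, controller on at `t = 5 s`, saturated and
rate-limited actuator):

```
scenario: case2 (A_n = 3.0 V, controller on at t = 5.0 s)
tremor RMS before control : 0.3773
tremor RMS, last 2 s      : 5.854e-11
suppression ratio         : 1.552e-10
final amplitude estimate  : 3.0000 V  (true A_n = 3.0 V)
settling time             : 11.10 s
```

The controller, measuring only `y`, suppresses the tremor to solver noise
and recovers the nominal amplitude exactly. `examples/tune_stimulation_grid.py`
then contrasts a setting where no in-range amplitude exists:

```
 F (Hz)  mu (us)  A_hat (V)   power P  converged
    130       90      5.000    0.2026      False
    180       90      3.000    0.0000       True

selected setting: F = 180 Hz, mu = 90 us, A = 3.000 V
```

At 130 Hz the required amplitude (7 V) exceeds the 5 V actuator limit: the
estimate pins at saturation, tremor power stays high, and the grid search
rejects the cell. The other examples print the gain-synthesis certificate
(`examples/synthesize_gains.py`) and the open-loop tremor-vs-amplitude
sweep (`examples/validate_tremor_model.py`).

A thin CLI wraps the same library calls:

```sh
tremorloop fixtures --out-dir scenarios/
tremorloop synthesize --bounds bounds.yaml --out gains.json
tremorloop simulate --scenario scenarios/case2.yaml \
    --out-csv traj.csv --out-summary summary.json --plot run.png
tremorloop tune --config grid.yaml --out report.json
```

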