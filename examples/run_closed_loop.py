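"""Closed-loop adaptive estimation of the nominal stimulation amplitude.

Runs the packaged valid-amplitude scenario: the plant's nominal amplitude is
A_n = 3 V, inside the 0-5 V actuator range.  The controller turns on at
t = 5 s, measures only the tremor output y, and adapts its amplitude
estimate u_hat; the delivered (saturated, rate-limited) amplitude converges
to A_n and the tremor converges to zero.
"""

from tremorloop import make_case2, run_scenario, scenario_gains, steady_state_time

scenario = make_case2()
gains = scenario_gains(scenario)
traj = run_scenario(scenario, gains=gains)

pre = traj.pre_controller_rms()
trail = traj.trailing_rms(2.0)
t_ss = steady_state_time(traj)

print(f"scenario: {scenario.name} (A_n = {scenario.model.A_n} V, "
      f"controller on at t = {scenario.t_on} s)")
print(f"tremor RMS before control : {pre:.4f}")
print(f"tremor RMS, last 2 s      : {trail:.3e}")
print(f"suppression ratio         : {trail / pre:.3e}")
print(f"final amplitude estimate  : {traj.u_hat[-1]:.4f} V  (true A_n = {scenario.model.A_n} V)")
print(f"settling time             : {t_ss:.2f} s")
print("\nThe estimate converges to the true nominal amplitude because the")
print("tremor reaches a steady state; the residual tremor is solver noise.")
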