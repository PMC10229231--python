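"""Periodic vs quasi-periodic switching: stochastic durations hinder rescue.

Phase durations are either fixed (sigma = 0) or drawn from a zero-truncated
normal.  For mean durations shorter than the harsh-phase survival time, the
occasional longer-than-average harsh phase is fatal, so duration noise
shortens persistence and lowers the rescue probability.
"""

from rescuekit import DurationDistribution, ModelParams, p_rescue_dn, total_extinction_time

params = ModelParams()
tau = 0.5 * params.tau_0H

print(f"mean duration tau = {tau:.2f} (= 0.5 tau_0H)\n")
print(f"{'sigma/tau':>9} {'T0 (no rescue)':>15} {'p_r_DN':>9}")
for frac in (0.0, 0.05, 0.1, 0.3, 1.0):
    dist = DurationDistribution(tau, frac * tau)
    T0 = total_extinction_time(ModelParams(mu=0.0), dist).T0
    pr = p_rescue_dn(params, dist)
    print(f"{frac:9.2f} {T0:15.0f} {pr:9.4f}")
print(
    "\nEven sigma = 0.05 tau cuts the expected persistence time severalfold;\n"
    "the rescue probability follows the same ordering."
)
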