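"""The three psychophysical transforms behind the extended mountain model.

Objective price -> subjective price, pulse frequency -> induced firing
frequency, and train duration -> half-maximal firing requirement.
"""

import rewardmountain as rm
from rewardmountain.transforms import StrengthDurationParams

print("subjective price (s) for objective prices 0, 1, 4, 10, 100 s:")
for p in (0.0, 1.0, 4.0, 10.0, 100.0):
    print(f"  P = {p:6.1f}  ->  SP = {rm.subjective_price(p):8.4f}")
print("very cheap rewards are all worth about the 1.75 s floor;")
print("above ~4 s the subjective price converges on the objective one.\n")

print("induced firing (spikes/s) for pulse frequencies 50, 200, 343, 1000 pps:")
for f in (50.0, 200.0, 343.0, 1000.0):
    print(f"  F = {f:6.0f}  ->  FF = {rm.frequency_following(f):8.2f}")
print(f"plateau = {rm.firing_plateau():.1f} spikes/s: beyond it extra pulses")
print("no longer evoke extra spikes in the directly stimulated neurons.\n")

res = rm.pulse_frequency_for_firing(400.0)
print(f"a 400 spikes/s demand is unreachable: {res.unreachable}")
print("(this regime is what silences the long-chronaxie integrator)\n")

sd = StrengthDurationParams(rheobase=100.0, chronaxie=1.0)
print("half-max firing requirement vs train duration (rheobase 100, chronaxie 1 s):")
for d in (0.25, 1.0, 4.0, 100.0):
    print(f"  D = {d:6.2f} s  ->  FFhm = {rm.half_max_firing_at_duration(d, sd):8.2f}")
print("short trains demand much faster firing; at D = chronaxie the demand")
print("is exactly twice the rheobase.")
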