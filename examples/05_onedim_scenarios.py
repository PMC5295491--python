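"""1-D pulse-wave scenarios: effect of a repaired coarctation on reflections.

Simulates the reduced aorta under three conditions - baseline, 25% narrowed
isthmus, and narrowed + 1e5-fold stiffened repair zone - and runs the same
wave-intensity pipeline on the root cycle as for in-vivo subjects.
The stiff case takes a minute or so: its wave speed dictates a tiny CFL step.
"""

from coawave.onedim import scenario_result, scenario_wia

for name in ("baseline", "narrow", "narrow_stiff"):
    res = scenario_result(name)
    w = scenario_wia(name)
    print(f"{name:13s} root P {res.pressure.max():5.1f}/{res.pressure.min():4.1f} mmHg  "
          f"BCW {w.bcw_magnitude:6.2f} cm^5 at {w.bcw_time*1e3:4.0f} ms  "
          f"(mass error {res.mass_error*100:.2f}%)")

print()
print("The backward compression wave grows from baseline (late peripheral")
print("reflection only) through the mild narrowing to the stiffened repair")
print("zone, and arrives earlier - the mechanism proposed for the elevated")
print("wave reflection seen after coarctation repair.")
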