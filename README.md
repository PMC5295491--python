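# coawave

Noninvasive central hemodynamics and wave intensity analysis for repaired
aortic coarctation.

## The problem

After surgical repair of aortic coarctation, patients often carry a hidden
afterload burden: brachial cuff pressure can be normal while the central
(ascending-aortic) systolic pressure is elevated, the aorta is stiffer, and
the stiff repair zone reflects arterial waves back toward the heart. Those
reflected waves — backward compression waves (BCWs) — load the left ventricle
and track with ventricular hypertrophy. Characterising all of this
noninvasively requires simultaneous aortic pressure and flow, which a single
high temporal-resolution phase-contrast MRI acquisition (area `A(t)` and flow
`Q(t)` at ~9.6 ms) plus an oscillometric brachial cuff can supply.

`coawave` implements that analysis chain for researchers working with such
data (or with simulated equivalents):

* **Central SBP** — the area waveform is turned into pressure through an
  exponential pressure–area law `p(t) = p_d · exp(β(A(t)/A_d − 1))`; starting
  from the theoretical maximum `β₀ = ln(SBP/DBP)·A_d/(A_s−A_d)`, β is reduced
  by bisection until the curve's time-mean equals the measured brachial mean
  BP (mean and diastolic pressure are nearly constant along the large
  arteries). c-SBP is the calibrated curve's peak.
* **Arterial stiffness** — local pulse wave velocity from the Bramwell–Hill
  relation `c = √(A_d·ΔP/(ρ·ΔA))` with ΔP the central pulse pressure, and
  characteristic impedance `Z_c = ρc/A_d` (ρ = 1060 kg/m³).
* **Resistance and compliance** — Woods-unit resistance `R = MBP/CO` and
  total arterial compliance by tuning a 2-element windkessel (closed-form
  periodic solution) until its pulse pressure matches the measured central or
  brachial pulse pressure.
* **Wave intensity analysis** — area/flow increments split exactly into
  forward and backward components, `dA± = (dA ± dQ/c)/2`, with per-increment
  intensity `dI = dA·dQ` (cm⁵ on summation). Waves are detected and
  classified (FCW/FEW/BCW/BEW), and the reflection magnitude is the amplitude
  ratio of the backward to forward integrated area waveforms.
* **1-D pulse-wave model** — a reduced tapered aorta (time-varying-elastance
  ventricle, lumped arch branches, windkessel terminations, MacCormack
  scheme) reproduces the scenario contrast: baseline vs. 25 % isthmus
  narrowing vs. narrowing with a 10⁵-fold stiffened repair zone.
* **Synthetic cohort + statistics** — a generator with known ground truth
  (β, wave speed, BCW magnitude/timing, compliance, resistance, c-SBP)
  stands in for patient data; the pipeline layer adds Welch-tested group
  summaries and the adjusted LV-mass regression on log BCW magnitude.

## Worked example

```python
import numpy as np
from coawave import analyze_subject, calibrate_beta
from coawave.synthetic import CohortParams, synthesize_subject

params = CohortParams(noise_sd_area=0.0, noise_sd_flow=0.0)
record, truth = synthesize_subject(params, "patient", np.random.default_rng(3))
m = analyze_subject(record)
print(m.csbp, m.pwv, m.bcw_magnitude, m.bcw_time)
```

Running `python examples/03_wave_intensity.py` (which does the above and
prints the comparison) gives:

```
injected BCW: 2.524 cm^5 at 83 ms
detected BCW: 2.474 cm^5 at 82 ms
FCW / FEW magnitudes: 36.63 / 36.62 cm^5
reflection magnitude (backward/forward area): 0.177
```

The analysis recovers the injected backward compression wave's magnitude
within a few percent and its arrival within one sample; the reflection
magnitude says the backward area waveform is ~18 % of the forward one.
The other scripts in `examples/` demonstrate central-pressure calibration,
the afterload measures, cohort statistics and the 1-D scenarios, each
printing what the numbers mean.

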