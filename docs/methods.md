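# Methods

This note documents the models, numerical choices and synthetic-data design
behind `coawave`, and what the tests do and do not demonstrate.

## Central pressure from area distension

The pressure–area relation of the large elastic arteries is modelled as
exponential, `p(t) = p_d exp(β (A(t)/A_d − 1))`, anchored at the brachial
diastolic pressure `p_d` and the diastolic area `A_d`. β is dimensionless and
jointly encodes wall stiffness and the calibration of area to pressure.

* **Diastolic anchor.** `A_d` is the global minimum of the area samples,
  earliest index on ties. With noisy area data this min-statistic is biased
  slightly low, which is the dominant error source in c-SBP at realistic
  noise (see *Synthetic data* below).
* **Initial β.** `β₀ = ln(SBP/DBP)·A_d/(A_s−A_d)` makes the synthesized peak
  equal brachial SBP. Because central SBP does not exceed brachial SBP in
  these vessels, β₀ is an upper bound and the calibrated β lies in (0, β₀].
* **Calibration target.** The time-mean of the synthesized curve must equal
  the measured oscillometric mean BP. "Mean" is the trapezoidal time average
  over the acquired cycle — the only support the data define. The map
  β ↦ mean(p(β)) is strictly increasing (exponential of a non-negative,
  somewhere-positive exponent), so bisection on [10⁻⁶, β₀] is guaranteed to
  converge; the tolerance is stated on pressure (default 0.01 mmHg), and the
  interval is additionally narrowed to float resolution so β itself is tight.
  An unreachable mean (mean at β₀ below measured MBP) raises a
  calibration-infeasible error rather than returning a boundary value.
* **Measured means only.** The oscillometric MBP is used as measured; the
  form-factor fallback `DBP + PP/3` exists behind an explicit call
  (`fallback_mean_bp`) and is never applied implicitly.

## Stiffness, resistance, compliance

* **Bramwell–Hill wave speed** uses the chord over the full excursion:
  `c = √(A_d·ΔP/(ρ·ΔA))` with ΔP strictly the *central* pulse pressure
  (c-SBP − DBP), ΔA = A_s − A_d, ρ = 1060 kg/m³. Single-site, so it is
  usable when early reflections corrupt transit-time or flow-area methods.
* **Characteristic impedance** `Z_c = ρc/A_d`, computed in SI and reported in
  mmHg·s/mL (÷133.322 ÷10⁶).
* **Resistance** in Woods units (mmHg·min/L), `R = MBP/CO`, indexed by
  multiplying with BSA; 1 WU = 0.06 mmHg·s/mL.
* **Total arterial compliance.** The 2-element windkessel
  `C dP/dt = Q(t) − P/R` is solved in periodic steady state by an exact
  exponential integrator for piecewise-linear flow (overflow-safe for
  arbitrarily small RC), and C is tuned by geometric bisection on an
  expanding bracket [10⁻³, 10²] mL/mmHg (×10 up to 4 times each way) until
  the model pulse pressure matches the measured one to 0.01 mmHg. Model PP is
  strictly decreasing in C and increasing in R, so the root is unique. Tuning
  is run twice per subject — central PP and brachial PP — and indexed by
  dividing by BSA. The windkessel's absolute pressure level is set by R and
  mean flow; only the pulse pressure is matched.
  A brute-force RK4 time-stepper serves as the independent oracle in the
  tests (agreement < 0.5 %); the closed form is used in production for
  determinism and speed.

## Wave intensity in the area–flow domain

Increments are plain first differences of area and flow ("incremental
wavefronts"), attributed to interval midpoints. With c in cm/s,

    dA± = (dA ± dQ/c)/2,   dQ± = (dQ ± c·dA)/2,   dQ± = ±c·dA±,

so conservation (`dA₊+dA₋ = dA`, `dQ₊+dQ₋ = dQ`) and the intensity split
(`dI₊+dI₋ = dA·dQ`, `dI₊ ≥ 0 ≥ dI₋`) hold identically. Intensity is defined
per increment, `dI = dA·dQ`, so wave magnitudes (sums over a wave's support)
carry cm⁵ — the natural unit of this noninvasive variant; they are
proportional to conventional W/m² quantities only under a linear
pressure–area relation.

Implementation conventions the data do not dictate (all exposed as config):

* **Wave support**: contiguous runs where |dI±| exceeds 5 % of that
  channel's own peak; a channel at rounding level relative to the other is
  treated as empty.
* **Classification**: sign of the run-integral of dA± (positive →
  compression).
* **BCW arrival**: time of peak |dI₋| of the wave — more robust to the
  support threshold than the onset.
* **Systole gate**: the reported BCW is the largest one peaking before the
  end of ejection (flow above 5 % of its peak, contiguous run containing the
  flow maximum).
* **Wave speed for separation** is the Bramwell–Hill estimate from the same
  cycle; the injected-wave recovery tests quantify the bias this chain
  introduces (<3 % in magnitude at zero noise, entirely from support
  truncation and discretisation).

Reflection magnitude = (max−min of cumulated A₋)/(max−min of cumulated A₊).

## Synthetic cohort

No patient recordings ship with the package, so every stage is validated by
parameter recovery on generated subjects. Design choices:

* **Waves are built in the separated domain** (forward ejection template,
  plus a compact Gaussian backward-compression bump scaled to an exact
  intensity integral) and then summed into `A(t)`, `Q(t)`. The analysis must
  undo the sum — recovery is a genuine inverse problem, not a tautology.
* **Chord-linked stiffness.** β is derived from the drawn wave speed through
  the chord of the exponential law over the realised excursion,
  `β = ln(1+ρc²x/p_d)/x`, `x = ΔA/A_d` (pressures in Pa). The Bramwell–Hill
  estimate is chord-based by definition, so at zero noise the pipeline
  recovers c, β, c-SBP and the injected BCW exactly — every discrepancy seen
  in tests is attributable to the analysis, not to a modelling mismatch.
* **Post-wave relaxation.** The injected BCW leaves a cumulative offset in
  flow and area; a slow backward-expansion ramp over 0.25 s returns both to
  baseline. Its per-increment intensity is ~1 % of the BCW peak — below the
  detection floor — so it does not contaminate wave metrics.
* **Study conditions.** Defaults are sized like the emulated study: 50
  patients / 25 controls at dt = 9.6 ms, period 0.8–1.0 s. Patients draw
  stiffer aortas (wave speed 5–7 vs 3.5–5.5 m/s), slightly larger roots,
  larger backward waves (2–5 % vs 0.8–2 % of the forward intensity) arriving
  earlier (80–97 vs 99–123 ms); both groups share DBP (64–78 mmHg), stroke
  volume (75–100 mL) and brachial amplification (1.05–1.18). These effect
  sizes were fixed at design time so the constructed contrasts are detectable
  at n = 75 with Welch tests.
* **LV mass** is generated as
  `LVM = 30 + 12·ln(BCW) + 45·BSA + 20·[male] + N(0,12)` g, so the adjusted
  regression has a known slope (12 g per log-unit) to recover.
* **Noise.** Gaussian, per sample: 0.004 cm² on area, 2 mL/s on flow —
  representing segmentation jitter after the temporal regularisation inherent
  in registration-based area measurement; flow is left noisier. The
  c-SBP error at these defaults (median ≈ 1.6 mmHg) is dominated by the
  diastolic-anchor min-statistic bias, which grows linearly with area noise.

What the synthetic data do **not** emulate: beat-to-beat variability,
diastolic area decay (diastole is flat at the diastolic area, so the
min-statistic bias above is if anything pessimistic in shape), measurement
error in the cuff pressures, multiple interacting reflection sites, and any
realistic covariance structure beyond the LVM model. Passing recovery tests
therefore demonstrates correctness of the analysis chain under its own model
assumptions, not clinical validity on real MRI data.

## Reduced 1-D aorta

A single tapered vessel (37 cm, root diameter 3.0 cm tapering to 2.0 cm,
uniform distensibility 4.5×10⁻³ /mmHg, five segments) discretised on one
uniform grid (dx = 0.25 cm). The head-and-neck vessels are lumped into a
3-element windkessel attached at the arch; the descending aorta ends in a
second windkessel; both take their proximal resistance equal to the local
characteristic impedance so the baseline run carries only the mild taper
reflection plus the late peripheral wave. The inlet is a time-varying
elastance ventricle (E 0.08–2.0 mmHg/mL, squared-sine activation over 0.3 s)
behind a diode valve; simulated waves thus originate from heart–vessel
interaction. The published whole-body arterial trees are deliberately not
replicated: only the qualitative scenario contrast is claimed, and defaults
were chosen to give control-like root pressure (~97/56 mmHg).

* **Tube law** linear-elastic, `A(P) = A₀(1 + D(P−P_ref))`, giving
  `c(A) = √(A/(ρDA₀))` and Riemann invariants `u ± 2c`.
* **Scheme**: explicit two-step MacCormack (forward predictor / backward
  corrector) on mass and momentum with Poiseuille friction; boundaries and
  the branch sink couple through the outgoing characteristic with scalar
  Newton solves; the inner loop is numba-compiled. CFL number 0.8 against
  the maximal `c` (with headroom for systolic distension and advection).
* **Scenarios**: `narrow` multiplies the repair-segment diameters by exactly
  0.75; `narrow_stiff` additionally divides its distensibility by exactly
  10⁵. On the grid, property transitions are smoothed in log space over a
  fixed ~0.5 cm length — far shorter than any wavelength, so physical
  reflections are preserved, but resolution-independent (required for grid
  convergence; a node-based ramp would change the reflection when dx
  changes). The repair segment is 8 cm: long enough that its impedance
  mismatch reflects the pulse's dominant frequencies rather than cancelling
  between its two faces.
* **Convergence**: cycles are advanced until the root pressure trace changes
  by < 0.5 mmHg max-norm between cycles (typically 8–9 cycles, ≤ 20); mass
  balance closes to < 0.3 %. Halving dx changes the narrow-scenario BCW by
  < 1 %. The stiffened segment raises the maximal wave speed ~300-fold and
  dictates the time step, making `narrow_stiff` the one expensive run
  (~20–30 s); results for the three canonical scenarios are cached per
  process.
* **Validation limit**: a uniform non-tapered tube driven by a small
  prescribed inflow pulse and terminated in its characteristic impedance is
  reflectionless in transmission-line theory; the solver yields reflection
  magnitude ≈ 0.01 (residual from the tube law's mild nonlinearity and
  friction), and > 0.6 when mismatched.
* Like the reference it emulates, the model produces an early backward
  *expansion* wave and a two-humped backward pattern not typical of in-vivo
  recordings; these are artefacts of the reduced geometry and are not
  asserted on.

## Statistics

Group summaries report means with 95 % t-intervals, or geometric means after
natural-log transform for skewed metrics (BCW magnitude by default). Both
Welch and pooled t-tests are computed; the headline p-value follows a
variance-ratio pre-check (> 2 → Welch). Binary metrics get two-proportion
z-tests. The LV-mass model is OLS of LVM (g) on one predictor plus BSA, age,
sex and case/control, mirroring an adjusted univariable design; rank
deficiency is reported with the offending columns, and log transforms of
nonpositive values raise rather than silently dropping subjects. α = 0.05,
no multiplicity correction. The natural log is used for BCW_log; slope
inference is base-independent.

## Degenerate inputs and tie-breaks

Flat area waveforms raise a degenerate-waveform error (β undefined);
constant flow makes the windkessel target unreachable (explicit error);
missing arch diameters yield absent morphology indices, not errors; subjects
failing any stage in batch mode are logged with reasons and excluded, never
silently dropped. Ties in the diastolic-area minimum break to the earliest
sample; if two BCWs tie in magnitude the earlier-listed (earlier-onset) one
is kept.

## Problem sizes used in the shipped checks

Recovery suites use 40 zero-noise subjects and the 75-subject default
cohort; separation identities are exercised on 1000 random sequences;
windkessel cross-checks on 20 random (R, C, flow) triples; the 1-D grid
convergence check runs the narrow scenario at dx and dx/2. These sizes make
the full suite complete in about a minute on one CPU while keeping every
statistical check far from its decision boundary.
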