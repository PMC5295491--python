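"""Study-level statistics on a seeded synthetic cohort (50 patients / 25
controls): group contrasts with Welch t-tests and the adjusted LV-mass
regression on log backward-wave magnitude.
"""

from coawave import analyze_cohort, lvm_regression, summarize_groups
from coawave.synthetic import CohortParams, generate_cohort

records, truths, _ = generate_cohort(CohortParams(seed=5))
metrics, failures = analyze_cohort(records)
assert not failures

table = summarize_groups(metrics)
for name in ("csbp", "pwv", "tac_central", "bcw_magnitude", "bcw_time"):
    row = table[table.metric == name].iloc[0]
    print(f"{name:14s} patients {row.patient_mean:8.3f}  controls {row.control_mean:8.3f}"
          f"  Welch p = {row.p_welch:.2e}")

fit = lvm_regression(metrics)
row = fit.loc["bcw_magnitude_log"]
print(f"\nLVM ~ log(BCW) slope: {row.coef:.1f} +- {row.se:.1f} g per log-unit "
      f"(p = {row.p_value:.3f}; generator truth {CohortParams().lvm_model[1]:.0f})")
print("\nPatients show higher central SBP, stiffer aortas (higher PWV, lower")
print("TAC) and larger, earlier backward compression waves; LV mass tracks")
print("the log BCW magnitude after adjustment for body size, age, sex, group.")
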