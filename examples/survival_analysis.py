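"""Encapsulation-stratified survival analysis on a synthetic cohort.

Generates 250 patients whose overall-survival hazard decreases with
encapsulation (true HR 0.91 per 0.1-fraction increment), then runs the
standard workup: log-rank across the three encapsulation strata, a
continuous per-0.1-fraction Cox model, and the multivariate model with
clinical covariates.
"""

from capsulezone import GeneratorConfig, build_survival_report, generate_cohort

cohort, _ = generate_cohort(GeneratorConfig(seed=1, n_patients=250))
report = build_survival_report(cohort, endpoint="os")

print(f"n = {report['n']} patients, "
      f"{cohort.os_event.sum()} deaths ({100 * (1 - cohort.os_event.mean()):.0f}% censored)")
print(f"strata sizes: {cohort.encapsulation_stratum.value_counts().to_dict()}")

lr = report["logrank_stratum"]
print(f"\nlog-rank across encapsulation strata: chi2 = {lr['chi2']:.1f}, p = {lr['p']:.2e}")

fit = report["cox_continuous"]
hr = fit.hazard_ratios.iloc[0]
lo, hi = fit.ci_lower.iloc[0], fit.ci_upper.iloc[0]
print(f"Cox, encapsulation per 0.1 fraction: HR = {hr:.2f} "
      f"(95% CI {lo:.2f}-{hi:.2f}), p = {fit.p_values.iloc[0]:.1e}  [truth: 0.91]")

mv = report["cox_multivariate"]
print("\nmultivariate model:")
print(mv.summary().round(3).to_string())
print("\n(HR < 1 for the medium/high strata reproduces the protective,"
      " proportion-dependent effect of encapsulation)")
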