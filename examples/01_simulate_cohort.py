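"""Generate a synthetic bilateral-carotid cohort and inspect its structure.

The generator draws log-normal IMT and diameter for both sides with a
Kronecker latent correlation (within-side 0.426, between-side 0.35),
proportional-hazards stroke outcomes and uniform 10-12 year censoring.
"""

from bicarotid import CohortConfig, generate_cohort

cfg = CohortConfig(n_subjects=7437, seed=42)
cohort = generate_cohort(cfg)

print(cohort.head())
print(f"\ncohort size: {len(cohort)}")
print(f"women: {(cohort.sex == 'F').mean():.1%}")
print(f"incident strokes: {cohort.event.sum()} "
      f"({100 * cohort.event.mean():.1f}% cumulative incidence)")
print(f"median follow-up: {cohort.time_years.median():.1f} years")
for sex, label in (("M", "men"), ("F", "women")):
    med = cohort.loc[cohort.sex == sex, "r_imt_mm"].median()
    print(f"{label} right CCA IMT median: {med:.3f} mm")
# The medians land near the calibration targets (men 0.663, women 0.609 mm)
# and the stroke count reflects the phenotype hazard gradient.
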