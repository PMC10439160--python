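"""Score growth-pattern fractions of synthetic slides and pool per patient.

Builds two synthetic slides for one patient (60/40 and 20/80 encapsulated vs
replacement interface), scores each slide by length-weighted annotation
shares, pools them into a patient-level score and assigns the encapsulation
stratum used for survival stratification.
"""

from capsulezone import aggregate, assign_strata, generate_geometry, score_slide

slides = [
    generate_geometry(seed, {"encapsulated": enc, "replacement": 100 - enc},
                      slide_id=f"slide_{i}", patient_id="patient_01")
    for i, (seed, enc) in enumerate([(1, 60.0), (2, 20.0)])
]

slide_scores = [score_slide(s.annotation_set) for s in slides]
for score in slide_scores:
    print(f"{score.unit_id}: encapsulated {score.percent_encapsulated:.1f}% | "
          f"replacement {score.percent_replacement:.1f}% | "
          f"interface {score.total_interface_length / 1000:.1f} mm | "
          f"predominant: {score.predominant}")

patient = aggregate(slide_scores, unit_id="patient_01")
strata = assign_strata(patient)
print(f"\npatient_01 pooled: encapsulated {patient.percent_encapsulated:.1f}% "
      f"(length-weighted across slides, not a mean of percentages)")
print(f"encapsulation stratum: {strata.encapsulation_stratum} "
      "(low <33%, medium 33-<100%, high =100%)")
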