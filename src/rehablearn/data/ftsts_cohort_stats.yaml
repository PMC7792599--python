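# Default per-class generation parameters for the FTSTS condition cohort.
#
# NON-CANONICAL: synthetic stand-in values chosen once to be clinically
# plausible and to lie inside published cohort ranges (age (11, 93] y,
# height [0.94, 2.35) m, weight (22, 120) kg). Not harvested from any
# specific study; results depending on them are illustrative.
test_type: FTSTS
non_canonical: true
source_note: >
  Synthetic stand-in parameter set. Completion-time means grow with
  clinical severity; higher BMI/height variability than TUG reflects the
  weaker coupling of these features to sit-to-stand times.
classes:
  healthy:
    {n: 240, mu_time: 8.5, sigma_time: 1.6, mu_age: 44.0, sigma_age: 13.0,
     mu_bmi: 24.0, sigma_bmi: 3.4, mu_weight: 71.0, sigma_weight: 12.0,
     mu_height: 1.70, sigma_height: 0.10, pct_female: 0.50}
  geriatric:
    {n: 240, mu_time: 14.0, sigma_time: 2.8, mu_age: 78.0, sigma_age: 6.0,
     mu_bmi: 26.0, sigma_bmi: 3.8, mu_weight: 67.0, sigma_weight: 11.0,
     mu_height: 1.62, sigma_height: 0.09, pct_female: 0.60}
  geriatric_fallers:
    {n: 240, mu_time: 18.0, sigma_time: 3.8, mu_age: 80.0, sigma_age: 6.0,
     mu_bmi: 25.5, sigma_bmi: 3.8, mu_weight: 65.0, sigma_weight: 11.0,
     mu_height: 1.61, sigma_height: 0.09, pct_female: 0.62}
  parkinsons_stage_1:
    {n: 240, mu_time: 11.0, sigma_time: 2.2, mu_age: 63.0, sigma_age: 8.0,
     mu_bmi: 25.0, sigma_bmi: 3.4, mu_weight: 72.0, sigma_weight: 11.0,
     mu_height: 1.69, sigma_height: 0.09, pct_female: 0.40}
  parkinsons_stage_2:
    {n: 240, mu_time: 13.0, sigma_time: 2.6, mu_age: 66.0, sigma_age: 8.0,
     mu_bmi: 25.0, sigma_bmi: 3.4, mu_weight: 72.0, sigma_weight: 11.0,
     mu_height: 1.69, sigma_height: 0.09, pct_female: 0.40}
  parkinsons_stage_2_5:
    {n: 240, mu_time: 14.0, sigma_time: 2.8, mu_age: 67.0, sigma_age: 8.0,
     mu_bmi: 25.0, sigma_bmi: 3.4, mu_weight: 72.0, sigma_weight: 11.0,
     mu_height: 1.69, sigma_height: 0.09, pct_female: 0.40}
  parkinsons_stage_3:
    {n: 240, mu_time: 16.0, sigma_time: 3.2, mu_age: 69.0, sigma_age: 8.0,
     mu_bmi: 25.0, sigma_bmi: 3.4, mu_weight: 71.0, sigma_weight: 11.0,
     mu_height: 1.68, sigma_height: 0.09, pct_female: 0.40}
  parkinsons_stage_4:
    {n: 240, mu_time: 20.0, sigma_time: 4.2, mu_age: 72.0, sigma_age: 8.0,
     mu_bmi: 24.5, sigma_bmi: 3.4, mu_weight: 70.0, sigma_weight: 11.0,
     mu_height: 1.68, sigma_height: 0.09, pct_female: 0.40}
  parkinsons:
    {n: 240, mu_time: 14.5, sigma_time: 3.0, mu_age: 68.0, sigma_age: 9.0,
     mu_bmi: 25.0, sigma_bmi: 3.4, mu_weight: 72.0, sigma_weight: 11.0,
     mu_height: 1.69, sigma_height: 0.09, pct_female: 0.40}
  arthritis:
    {n: 240, mu_time: 13.5, sigma_time: 2.8, mu_age: 65.0, sigma_age: 9.0,
     mu_bmi: 29.0, sigma_bmi: 4.2, mu_weight: 80.0, sigma_weight: 12.0,
     mu_height: 1.66, sigma_height: 0.09, pct_female: 0.60}
  arthritis_knee_arthroplasty:
    {n: 240, mu_time: 15.5, sigma_time: 3.2, mu_age: 68.0, sigma_age: 7.0,
     mu_bmi: 29.5, sigma_bmi: 4.2, mu_weight: 81.0, sigma_weight: 12.0,
     mu_height: 1.66, sigma_height: 0.09, pct_female: 0.62}
  stroke:
    {n: 240, mu_time: 22.0, sigma_time: 5.5, mu_age: 65.0, sigma_age: 10.0,
     mu_bmi: 26.0, sigma_bmi: 3.8, mu_weight: 74.0, sigma_weight: 12.0,
     mu_height: 1.68, sigma_height: 0.10, pct_female: 0.45}
  vestibular_disorder:
    {n: 240, mu_time: 16.5, sigma_time: 3.4, mu_age: 58.0, sigma_age: 12.0,
     mu_bmi: 25.5, sigma_bmi: 3.6, mu_weight: 73.0, sigma_weight: 12.0,
     mu_height: 1.68, sigma_height: 0.09, pct_female: 0.55}
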