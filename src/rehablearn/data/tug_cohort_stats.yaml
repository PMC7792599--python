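# Default per-class generation parameters for the TUG condition cohort.
#
# NON-CANONICAL: these (mu, sigma) values are a synthetic stand-in chosen
# once to be clinically plausible and to lie inside published cohort
# ranges (age [5, 112] y, height [0.81, 2.20) m, weight (30, 136) kg).
# They are NOT harvested from any specific study; results that depend on
# them are illustrative, not reference values.
test_type: TUG
non_canonical: true
source_note: >
  Synthetic stand-in parameter set. Completion-time means grow with
  clinical severity (healthy fastest, tetraplegia slowest); demographics
  follow typical cohort compositions for each condition.
classes:
  healthy:
    {n: 280, mu_time: 8.0, sigma_time: 1.4, mu_age: 45.0, sigma_age: 14.0,
     mu_bmi: 24.0, sigma_bmi: 3.0, mu_weight: 72.0, sigma_weight: 12.0,
     mu_height: 1.70, sigma_height: 0.09, pct_female: 0.50}
  geriatric:
    {n: 280, mu_time: 12.5, sigma_time: 2.5, mu_age: 79.0, sigma_age: 6.0,
     mu_bmi: 26.0, sigma_bmi: 3.5, mu_weight: 68.0, sigma_weight: 11.0,
     mu_height: 1.62, sigma_height: 0.08, pct_female: 0.60}
  parkinsons:
    {n: 280, mu_time: 14.0, sigma_time: 3.0, mu_age: 68.0, sigma_age: 8.0,
     mu_bmi: 25.5, sigma_bmi: 3.2, mu_weight: 73.0, sigma_weight: 12.0,
     mu_height: 1.69, sigma_height: 0.08, pct_female: 0.40}
  parkinsons_nonfallers_medication:
    {n: 280, mu_time: 12.0, sigma_time: 2.4, mu_age: 66.0, sigma_age: 8.0,
     mu_bmi: 25.0, sigma_bmi: 3.0, mu_weight: 72.0, sigma_weight: 11.0,
     mu_height: 1.69, sigma_height: 0.08, pct_female: 0.40}
  parkinsons_nonfallers_no_medication:
    {n: 280, mu_time: 13.0, sigma_time: 2.6, mu_age: 66.0, sigma_age: 8.0,
     mu_bmi: 25.0, sigma_bmi: 3.0, mu_weight: 72.0, sigma_weight: 11.0,
     mu_height: 1.69, sigma_height: 0.08, pct_female: 0.40}
  parkinsons_fallers:
    {n: 280, mu_time: 18.0, sigma_time: 4.0, mu_age: 71.0, sigma_age: 7.0,
     mu_bmi: 25.0, sigma_bmi: 3.2, mu_weight: 71.0, sigma_weight: 11.0,
     mu_height: 1.68, sigma_height: 0.08, pct_female: 0.40}
  dementia_mild_moderate:
    {n: 280, mu_time: 15.0, sigma_time: 3.2, mu_age: 78.0, sigma_age: 6.0,
     mu_bmi: 24.5, sigma_bmi: 3.2, mu_weight: 65.0, sigma_weight: 10.0,
     mu_height: 1.63, sigma_height: 0.08, pct_female: 0.55}
  dementia_severe:
    {n: 280, mu_time: 25.0, sigma_time: 6.0, mu_age: 82.0, sigma_age: 6.0,
     mu_bmi: 23.5, sigma_bmi: 3.2, mu_weight: 61.0, sigma_weight: 10.0,
     mu_height: 1.61, sigma_height: 0.08, pct_female: 0.60}
  arthritis_improvement:
    {n: 280, mu_time: 11.0, sigma_time: 2.2, mu_age: 66.0, sigma_age: 8.0,
     mu_bmi: 28.5, sigma_bmi: 4.0, mu_weight: 80.0, sigma_weight: 13.0,
     mu_height: 1.66, sigma_height: 0.08, pct_female: 0.60}
  arthritis_knee_arthroplasty:
    {n: 280, mu_time: 13.5, sigma_time: 2.8, mu_age: 68.0, sigma_age: 7.0,
     mu_bmi: 29.5, sigma_bmi: 4.2, mu_weight: 82.0, sigma_weight: 13.0,
     mu_height: 1.66, sigma_height: 0.08, pct_female: 0.62}
  arthritis:
    {n: 280, mu_time: 12.5, sigma_time: 2.6, mu_age: 65.0, sigma_age: 9.0,
     mu_bmi: 29.0, sigma_bmi: 4.0, mu_weight: 81.0, sigma_weight: 13.0,
     mu_height: 1.66, sigma_height: 0.08, pct_female: 0.60}
  stroke:
    {n: 280, mu_time: 20.0, sigma_time: 5.0, mu_age: 66.0, sigma_age: 10.0,
     mu_bmi: 26.0, sigma_bmi: 3.5, mu_weight: 74.0, sigma_weight: 12.0,
     mu_height: 1.68, sigma_height: 0.09, pct_female: 0.45}
  brain_injury:
    {n: 280, mu_time: 22.0, sigma_time: 5.5, mu_age: 48.0, sigma_age: 13.0,
     mu_bmi: 25.0, sigma_bmi: 3.2, mu_weight: 74.0, sigma_weight: 12.0,
     mu_height: 1.71, sigma_height: 0.09, pct_female: 0.35}
  bilateral_vestibular_hypofunction:
    {n: 280, mu_time: 16.0, sigma_time: 3.4, mu_age: 60.0, sigma_age: 11.0,
     mu_bmi: 25.5, sigma_bmi: 3.2, mu_weight: 73.0, sigma_weight: 12.0,
     mu_height: 1.68, sigma_height: 0.08, pct_female: 0.55}
  unilateral_vestibular_hypofunction:
    {n: 280, mu_time: 14.0, sigma_time: 3.0, mu_age: 58.0, sigma_age: 12.0,
     mu_bmi: 25.5, sigma_bmi: 3.2, mu_weight: 73.0, sigma_weight: 12.0,
     mu_height: 1.68, sigma_height: 0.08, pct_female: 0.55}
  spinal_injury:
    {n: 280, mu_time: 28.0, sigma_time: 7.0, mu_age: 45.0, sigma_age: 13.0,
     mu_bmi: 24.5, sigma_bmi: 3.2, mu_weight: 72.0, sigma_weight: 12.0,
     mu_height: 1.71, sigma_height: 0.09, pct_female: 0.30}
  paraplegia:
    {n: 280, mu_time: 35.0, sigma_time: 8.0, mu_age: 42.0, sigma_age: 12.0,
     mu_bmi: 24.0, sigma_bmi: 3.2, mu_weight: 70.0, sigma_weight: 12.0,
     mu_height: 1.72, sigma_height: 0.09, pct_female: 0.28}
  tetraplegia:
    {n: 280, mu_time: 45.0, sigma_time: 10.0, mu_age: 40.0, sigma_age: 12.0,
     mu_bmi: 23.5, sigma_bmi: 3.2, mu_weight: 68.0, sigma_weight: 12.0,
     mu_height: 1.73, sigma_height: 0.09, pct_female: 0.25}
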