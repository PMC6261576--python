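# Canonical cohort CSV schema.
# Symptom items are 0-4 Likert ratings; vas is 0-100; booleans are 0/1;
# sex is F/M; region is an integer code (legend below).
symptoms:
  - nasal_congestion
  - nasal_obstruction
  - rhinorrhea
  - nasal_itching
  - sneezing
  - headache
  - tiredness
  - loss_of_appetite
  - irritability
  - lacrimation
  - eye_itching
  - painful_throat
  - cough
  - itching_throat
  - earache
  - daily_activity_alteration
  - sleep_alteration
arphys_items:
  - nasal_obstruction
  - rhinorrhea
  - sneezing
  - nasal_itching
  - eye_itching
other_columns:
  - id
  - vas
  - age
  - sex
  - rural
  - onset
  - episode_duration
  - asthma
  - conjunctivitis
  - atopic_dermatitis
  - food_allergy
  - hives
  - spt_positive
  - ige_positive
  - ait
  - region
region_legend:
  1: center
  2: east
  3: north-west
  4: paris-agglomeration
  5: south-east
  6: south-west
  7: west
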