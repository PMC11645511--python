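# Synthetic general-health instrument: 39 ordinal items (1-5), a health-condition
# checklist with two embedded fake conditions, and six weighting demographics.
response_range: [1, 5]

# Survey order. Items sharing a block prefix form consecutive same-response-category sets.
items:
  [pf1, pf2, pf3, pf4, pf5, pf6, px_trouble,
   anx1, anx2, anx3, anx4,
   dep1, dep2, dep3, dep4,
   fat1, fat2, fat3, fat4,
   sd1, sd2, sd3, sd4, sd5, sd6, px_sleep,
   ap1, ap2, ap3, ap4,
   pi1, pi2, pi3, pi4, px_pain,
   cog1, cog2, px_conc, px_mem]

# Items asked in the opposite direction from the rest of their block; raw
# responses are inverted (6 - r) before scale scoring.
reverse_items: [sd1, sd4]

scales:
  physical_function:     {items: [pf1, pf2, pf3, pf4]}
  anxiety:               {items: [anx1, anx2, anx3, anx4]}
  depressive_symptoms:   {items: [dep1, dep2, dep3, dep4]}
  fatigue:               {items: [fat1, fat2, fat3, fat4]}
  sleep_disturbance:     {items: [sd1, sd2, sd3, sd4], reverse_items: [sd1, sd4]}
  ability_to_participate: {items: [ap1, ap2, ap3, ap4]}
  pain_interference:     {items: [pi1, pi2, pi3, pi4]}
  cognitive_function:    {items: [cog1, cog2]}

# Extra (non-scale) items keyed to the latent domain they draw on.
extra_item_traits:
  pf5: physical_function
  pf6: physical_function
  px_trouble: physical_function
  sd5: sleep_disturbance
  sd6: sleep_disturbance
  px_sleep: sleep_disturbance
  px_pain: pain_interference
  px_conc: cognitive_function
  px_mem: cognitive_function

# All consecutive same-response-category sets (straight-lining rule 1 applies
# to every one of these).
consecutive_sets:
  physical_block:   [pf1, pf2, pf3, pf4, pf5, pf6, px_trouble]
  anxiety_block:    [anx1, anx2, anx3, anx4]
  depression_block: [dep1, dep2, dep3, dep4]
  fatigue_block:    [fat1, fat2, fat3, fat4]
  sleep_block:      [sd1, sd2, sd3, sd4, sd5, sd6, px_sleep]
  ability_block:    [ap1, ap2, ap3, ap4]
  pain_block:       [pi1, pi2, pi3, pi4, px_pain]
  cognitive_block:  [cog1, cog2, px_conc, px_mem]

# Batteries with category allowances for the targeted straight-lining rules:
# identical "without any difficulty" (5) answers are plausible on physical
# function; identical "somewhat/sometimes" (3) answers are plausible on the
# mixed-direction sleep sets.
special_batteries:
  physical_function_6:
    items: [pf1, pf2, pf3, pf4, pf5, pf6]
    allowed_category: 5
  sleep_set_1:
    items: [sd1, sd2, sd3]
    allowed_category: 3
    reverse_items: [sd1]
  sleep_set_2:
    items: [sd4, sd5, sd6]
    allowed_category: 3
    reverse_items: [sd4]

# Similar-topic item pairs with identical response categories, for weighted-kappa
# response consistency.
item_pairs:
  - {item_a: pi1, item_b: px_pain, label: pain interference}
  - {item_a: pf2, item_b: px_trouble, label: trouble doing}
  - {item_a: sd2, item_b: px_sleep, label: problems with sleep}
  - {item_a: cog1, item_b: px_conc, label: ability to concentrate or focus}
  - {item_a: cog2, item_b: px_mem, label: memory}

# Health-condition checklist: id -> base prevalence among candid respondents.
conditions:
  back_pain: 0.40
  neck_pain: 0.16
  hypertension: 0.38
  high_cholesterol: 0.30
  arthritis: 0.24
  asthma: 0.13
  diabetes: 0.13
  depression: 0.20
  anxiety_disorder: 0.19
  heart_attack: 0.03
  coronary_heart_disease: 0.04
  angina: 0.02
  copd: 0.05
  cancer: 0.08
  stroke: 0.03
  migraine: 0.15
  kidney_disease: 0.03
  liver_disease: 0.015
  thyroid_disease: 0.07
  stomach_ulcer: 0.06
  osteoporosis: 0.05
  seasonal_allergies: 0.30
  insomnia: 0.15
  obesity: 0.30

fake_conditions: [syndomitis, chekalism]

demographic_variables:
  age_group: ["18-29", "30-44", "45-60", "60+"]
  gender: [female, male]
  race_ethnicity: [hispanic, multiracial, nh_black, nh_white, nh_other]
  education: [no_hs, hs_grad, some_college, bachelors, masters_plus]
  income: ["<10k", "10k-50k", "50k-100k", "100k+"]
  region: [northeast, midwest, south, west]

# Items a respondent is assigned beyond the ordinal matrix: 26 condition
# checkboxes, 6 demographics, 1 open-text prompt.
extra_assigned_items: 33
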