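# Opt-in convenience-panel cohort: a behavioral mix with a large misrepresenter
# share (fake-condition endorsers), planted straight-liners and copy-paste text
# responders, and selection skewed young, highly educated, and lower income.
n_respondents: 3000
persona_mix:
  attentive: 0.816
  straightliner: 0.02
  speeder: 0.0
  misrepresenter: 0.144
  copier: 0.02
fake_endorse_prob: 0.95
overendorse_prob: 0.6
# a share of misrepresenters also straight-line, so excluding fake-condition
# endorsers lowers the straight-lining rate (the pattern seen in fielded
# convenience-panel data)
misrepresenter_straightline_frac: 0.1
missing_rate: 0.02
incomplete_frac: 0.035
trait_corr: {exchangeable: 0.4}
health_loading: 0.5
duration_median_spi: 12.0
duration_sigma: 0.5
demo_bias:
  age_group: {"18-29": 1.2, "30-44": 2.5, "45-60": 1.0, "60+": 0.3}
  gender: {female: 0.9, male: 1.1}
  race_ethnicity: {hispanic: 1.3, multiracial: 1.2, nh_black: 0.8, nh_white: 1.0, nh_other: 1.0}
  education: {no_hs: 0.05, hs_grad: 0.3, some_college: 0.9, bachelors: 2.6, masters_plus: 1.1}
  income: {"<10k": 1.2, "10k-50k": 1.8, "50k-100k": 1.5, "100k+": 0.35}
  region: {northeast: 1.0, midwest: 1.0, south: 1.0, west: 1.0}
demo_trait_effects:
  age_group: {"18-29": 0.3, "30-44": 0.1, "45-60": -0.1, "60+": -0.3}
  income: {"<10k": -0.3, "10k-50k": -0.1, "50k-100k": 0.1, "100k+": 0.3}
  education: {no_hs: -0.2, hs_grad: -0.1, some_college: 0.0, bachelors: 0.1, masters_plus: 0.2}
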