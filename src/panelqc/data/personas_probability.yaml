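# Probability-based panel cohort: nearly all attentive respondents, negligible
# misrepresentation, no selection bias (address-based sampling emulated as
# draws from the population margins), slightly higher item skipping.
n_respondents: 2000
persona_mix:
  attentive: 0.985
  straightliner: 0.005
  speeder: 0.0
  misrepresenter: 0.005
  copier: 0.005
fake_endorse_prob: 0.95
overendorse_prob: 0.6
missing_rate: 0.05
incomplete_frac: 0.004
trait_corr: {exchangeable: 0.4}
health_loading: 0.5
duration_median_spi: 7.0
duration_sigma: 0.4
demo_trait_effects:
  age_group: {"18-29": 0.3, "30-44": 0.1, "45-60": -0.1, "60+": -0.3}
  income: {"<10k": -0.3, "10k-50k": -0.1, "50k-100k": 0.1, "100k+": 0.3}
  education: {no_hs: -0.2, hs_grad: -0.1, some_college: 0.0, bachelors: 0.1, masters_plus: 0.2}
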