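# Raking targets: national adult population margins (percent) for the six
# weighting demographics, from the Current Population Survey Annual Social and
# Economic Supplement (March 2022). Values are normalized to proportions at load.
# The combined bachelor's-or-higher share (34.8%) is split between the two top
# education categories in proportion to the weighted probability-panel sample.
age_group:
  "18-29": 19.9
  "30-44": 25.9
  "45-60": 24.0
  "60+": 30.3
gender:
  female: 50.7
  male: 49.3
race_ethnicity:
  hispanic: 17.2
  multiracial: 1.4
  nh_black: 12.0
  nh_white: 62.0
  nh_other: 7.3
education:
  no_hs: 9.6
  hs_grad: 29.2
  some_college: 26.4
  bachelors: 19.1
  masters_plus: 15.7
income:
  "<10k": 3.6
  "10k-50k": 24.9
  "50k-100k": 28.6
  "100k+": 42.9
region:
  northeast: 17.4
  midwest: 20.6
  south: 38.3
  west: 23.7
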