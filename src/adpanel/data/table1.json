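{
  "comment": "Reference cohort demographic summary (n=527) used to parameterize the synthetic generator and to recompute the group-comparison tests.",
  "groups": ["CN_Aneg", "CN_Apos", "CI"],
  "n": [211, 228, 88],
  "sex_female": [111, 126, 43],
  "race_nhw": [190, 209, 82],
  "apoe4_carrier": [52, 94, 50],
  "age_mean": [69.72, 71.67, 72.11],
  "age_sd": [7.61, 6.53, 6.39],
  "education_mean": [15.97, 15.92, 15.81],
  "education_sd": [2.57, 2.32, 2.69]
}
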