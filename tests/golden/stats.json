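{
  "config_hash": "4cb1695a2659e456",
  "intact_proportion_welch_t": {
    "df": 2.0924269333195555,
    "method": "welch_t",
    "p_value": 0.0018494828757008599,
    "statistic": 20.80364667857882
  },
  "intrinsic_chi_square": {
    "df": 1.0,
    "method": "chi_square",
    "p_value": 0.6634439308393304,
    "statistic": 0.1893670599552957
  },
  "length_distribution_anova": {
    "df": [
      1.0,
      54.0
    ],
    "method": "two_way_anova",
    "p_value": 0.9999999999999923,
    "statistic": 9.209393873635113e-29
  }
}
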