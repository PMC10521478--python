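{
  "config_hash": "4cb1695a2659e456",
  "excluded_samples": [],
  "group_means": {
    "Exo": 0.3571614682866798,
    "MV": 0.2522319987224493
  },
  "intact_threshold": 0.9,
  "notice": null,
  "overall_intact_proportion": 0.30480756153950767,
  "per_sample": {
    "Exo_1": {
      "intact_proportion_read_weighted": 0.3472222222222222,
      "intact_proportion_transcript_weighted": 0.8928571428571429,
      "n_reads": 4896
    },
    "Exo_2": {
      "intact_proportion_read_weighted": 0.3614213197969543,
      "intact_proportion_transcript_weighted": 0.9363957597173145,
      "n_reads": 4925
    },
    "Exo_3": {
      "intact_proportion_read_weighted": 0.36284086284086287,
      "intact_proportion_transcript_weighted": 0.9326241134751773,
      "n_reads": 4914
    },
    "MV_1": {
      "intact_proportion_read_weighted": 0.2518896833503575,
      "intact_proportion_transcript_weighted": 0.8458781362007168,
      "n_reads": 4895
    },
    "MV_2": {
      "intact_proportion_read_weighted": 0.2511238250919493,
      "intact_proportion_transcript_weighted": 0.8369565217391305,
      "n_reads": 4894
    },
    "MV_3": {
      "intact_proportion_read_weighted": 0.25368248772504093,
      "intact_proportion_transcript_weighted": 0.8315412186379928,
      "n_reads": 4888
    }
  },
  "welch_t": {
    "df": 2.0924269333195555,
    "method": "welch_t",
    "p_value": 0.0018494828757008599,
    "statistic": 20.80364667857882
  }
}
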