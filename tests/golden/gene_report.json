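{
  "config_hash": "4cb1695a2659e456",
  "degradation_machinery": {
    "CNOT1": {
      "Exo_1": true,
      "Exo_2": true,
      "Exo_3": true,
      "MV_1": true,
      "MV_2": true,
      "MV_3": true
    },
    "LSM1": {
      "Exo_1": true,
      "Exo_2": true,
      "Exo_3": true,
      "MV_1": true,
      "MV_2": true,
      "MV_3": true
    },
    "LSM3": {
      "Exo_1": true,
      "Exo_2": true,
      "Exo_3": true,
      "MV_1": true,
      "MV_2": true,
      "MV_3": true
    },
    "LSM7": {
      "Exo_1": true,
      "Exo_2": true,
      "Exo_3": true,
      "MV_1": true,
      "MV_2": true,
      "MV_3": true
    },
    "PARN": {
      "Exo_1": true,
      "Exo_2": true,
      "Exo_3": true,
      "MV_1": true,
      "MV_2": true,
      "MV_3": true
    },
    "SMG5": {
      "Exo_1": true,
      "Exo_2": true,
      "Exo_3": true,
      "MV_1": true,
      "MV_2": true,
      "MV_3": true
    }
  },
  "group_specific": {
    "Exo": {
      "genes": [
        "GENE00075",
        "GENE00087",
        "GENE00142",
        "GENE00192"
      ],
      "n_genes": 4,
      "n_transcripts": 15,
      "transcripts": [
        "TX00051",
        "TX00087",
        "TX00109",
        "TX00110",
        "TX00126",
        "TX00132",
        "TX00149",
        "TX00177",
        "TX00181",
        "TX00187",
        "TX00209",
        "TX00221",
        "TX00270",
        "TX00281",
        "TX00284"
      ]
    },
    "MV": {
      "genes": [
        "GENE00025",
        "GENE00040",
        "GENE00081",
        "GENE00085",
        "GENE00086",
        "GENE00113",
        "GENE00155",
        "GENE00164",
        "GENE00185"
      ],
      "n_genes": 9,
      "n_transcripts": 16,
      "transcripts": [
        "TX00018",
        "TX00032",
        "TX00059",
        "TX00119",
        "TX00124",
        "TX00125",
        "TX00148",
        "TX00157",
        "TX00166",
        "TX00217",
        "TX00227",
        "TX00241",
        "TX00247",
        "TX00272",
        "TX00275",
        "TX00293"
      ]
    }
  },
  "intrinsic": {
    "chi_square": {
      "df": 1.0,
      "method": "chi_square",
      "p_value": 0.6634439308393304,
      "statistic": 0.1893670599552957
    },
    "n_intrinsic": 178,
    "n_union": 201,
    "notice": null,
    "proportion": 0.8855721393034826,
    "proportion_denominator": "union_of_detected_genes",
    "table": [
      [
        178,
        178
      ],
      [
        11,
        9
      ]
    ]
  },
  "shared": {
    "n_genes": 188,
    "n_transcripts": 269
  }
}
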