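{
  "ambiguous_as": null,
  "config_hash": "4cb1695a2659e456",
  "end_tolerance_fraction": 0.1,
  "end_tolerance_min": 20,
  "overall": {
    "n_ambiguous": 0,
    "n_directional": 20447,
    "proportions": {
      "deg_3to5": 0.4243165256516848,
      "deg_5to3": 0.22291778745048174,
      "endo": 0.35276568689783344
    }
  },
  "per_group": {
    "Exo": {
      "n_ambiguous": 0,
      "n_directional": 9472,
      "proportions": {
        "deg_3to5": 0.42863175675675674,
        "deg_5to3": 0.22065033783783783,
        "endo": 0.35071790540540543
      }
    },
    "MV": {
      "n_ambiguous": 0,
      "n_directional": 10975,
      "proportions": {
        "deg_3to5": 0.42059225512528475,
        "deg_5to3": 0.22487471526195899,
        "endo": 0.3545330296127563
      }
    }
  },
  "per_sample": {
    "Exo_1": {
      "n_ambiguous": 0,
      "n_directional": 3196,
      "proportions": {
        "deg_3to5": 0.438360450563204,
        "deg_5to3": 0.21526908635794745,
        "endo": 0.34637046307884856
      }
    },
    "Exo_2": {
      "n_ambiguous": 0,
      "n_directional": 3145,
      "proportions": {
        "deg_3to5": 0.4174880763116057,
        "deg_5to3": 0.2289348171701113,
        "endo": 0.353577106518283
      }
    },
    "Exo_3": {
      "n_ambiguous": 0,
      "n_directional": 3131,
      "proportions": {
        "deg_3to5": 0.42989460236346216,
        "deg_5to3": 0.21782178217821782,
        "endo": 0.35228361545832004
      }
    },
    "MV_1": {
      "n_ambiguous": 0,
      "n_directional": 3662,
      "proportions": {
        "deg_3to5": 0.4197160021845986,
        "deg_5to3": 0.22119060622610595,
        "endo": 0.3590933915892955
      }
    },
    "MV_2": {
      "n_ambiguous": 0,
      "n_directional": 3665,
      "proportions": {
        "deg_3to5": 0.4120054570259209,
        "deg_5to3": 0.22783083219645292,
        "endo": 0.3601637107776262
      }
    },
    "MV_3": {
      "n_ambiguous": 0,
      "n_directional": 3648,
      "proportions": {
        "deg_3to5": 0.4300986842105263,
        "deg_5to3": 0.2256030701754386,
        "endo": 0.3442982456140351
      }
    }
  }
}
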