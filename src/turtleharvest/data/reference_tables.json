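{
  "description": "Published reference values for freshwater turtle demography: AICc columns of the four-candidate trait model comparison, stage-elasticity tables, and zone-level demographic parameters (observed / predicted / minimum values giving r >= 0) for temperate and tropical species.",
  "aicc_by_trait": {
    "clutch_size": {
      "latitude": 168.09,
      "lat_class": 193.80,
      "bio17": 218.85,
      "bio10": 224.98
    },
    "clutch_frequency": {
      "latitude": 54.94,
      "bio10": 61.22,
      "bio17": 62.00,
      "lat_class": 64.84
    },
    "age_maturity": {
      "latitude": 68.52,
      "bio10": 69.13,
      "bio17": 76.08,
      "lat_class": 79.42
    },
    "adult_survival": {
      "bio10": -16.31,
      "latitude": -12.19,
      "bio17": -10.18,
      "lat_class": 0.73
    }
  },
  "elasticities": {
    "observed": {
      "temperate": {
        "egg_survival": 0.090,
        "juvenile_P": 0.183,
        "juvenile_G": 0.090,
        "adult_survival": 0.546,
        "fecundity": 0.090
      },
      "tropical": {
        "egg_survival": 0.110,
        "juvenile_P": 0.252,
        "juvenile_G": 0.110,
        "adult_survival": 0.419,
        "fecundity": 0.110
      }
    },
    "predicted": {
      "temperate": {
        "egg_survival": 0.076,
        "juvenile_P": 0.208,
        "juvenile_G": 0.076,
        "adult_survival": 0.564,
        "fecundity": 0.076
      },
      "tropical": {
        "egg_survival": 0.082,
        "juvenile_P": 0.216,
        "juvenile_G": 0.082,
        "adult_survival": 0.537,
        "fecundity": 0.082
      }
    }
  },
  "demography": {
    "temperate": {
      "observed": {
        "egg_survival": 0.200,
        "juvenile_survival": 0.766,
        "adult_survival": 0.880,
        "clutch_size": 8.8,
        "clutch_frequency": 2.0,
        "age_maturity": 8.3,
        "fecundity": 7.3
      },
      "predicted": {
        "egg_survival": 0.200,
        "juvenile_survival": 0.746,
        "adult_survival": 0.857,
        "clutch_size": 7.3,
        "clutch_frequency": 2.0,
        "age_maturity": 8.6,
        "fecundity": 7.3
      },
      "r_min": {
        "egg_survival": 0.170,
        "juvenile_survival": 0.630,
        "adult_survival": 0.800,
        "fecundity": 6.4
      }
    },
    "tropical": {
      "observed": {
        "egg_survival": 0.200,
        "juvenile_survival": 0.767,
        "adult_survival": 0.882,
        "clutch_size": 7.0,
        "clutch_frequency": 2.3,
        "age_maturity": 7.8,
        "fecundity": 6.0
      },
      "predicted": {
        "egg_survival": 0.200,
        "juvenile_survival": 0.694,
        "adult_survival": 0.798,
        "clutch_size": 5.2,
        "clutch_frequency": 2.3,
        "age_maturity": 7.3,
        "fecundity": 6.0
      },
      "r_min": {
        "egg_survival": 0.130,
        "juvenile_survival": 0.530,
        "adult_survival": 0.760,
        "fecundity": 4.3
      }
    }
  },
  "results_margins_percent": {
    "temperate": {
      "egg_survival": 15,
      "juvenile_survival": 16,
      "adult_survival": 7,
      "fecundity": 12
    },
    "tropical": {
      "egg_survival": 35,
      "juvenile_survival": 24,
      "adult_survival": 5,
      "fecundity": 28
    }
  },
  "top_akaike_weights": {
    "clutch_frequency": 0.93,
    "age_maturity": 0.57
  }
}
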