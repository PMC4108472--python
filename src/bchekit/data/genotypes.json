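{
  "_comment": "Genotype-labeled generative ground truth for synthetic plasma panels. BTC kinetics follow published family/control parameter sets where available; vmax values marked free_constants and all BzCh parameters, Ki values and non-proband analyzer activities are generator calibration constants, not published measurements.",
  "UU": {
    "description": "usual/usual homozygote (control)",
    "btc": {"vmax": 7.5, "km_um": 18.0, "kss_mm": 1.0, "b": 3.2},
    "bzch": {"v50": 0.71, "km_um": 5.0},
    "dn_target": 78.8,
    "fn_target": 52.1,
    "analyzer_activity_iu_l": 9100.0,
    "reference_group": "men",
    "expected_label": "usual",
    "free_constants": ["btc.vmax"]
  },
  "US": {
    "description": "usual/silent heterozygote (father, I-1)",
    "btc": {"vmax": 7.51, "km_um": 21.0, "kss_mm": 0.49, "b": 2.4},
    "bzch": {"v50": 0.61, "km_um": 5.0},
    "dn_target": 75.3,
    "fn_target": 51.6,
    "analyzer_activity_iu_l": 7000.0,
    "reference_group": "men",
    "expected_label": "usual"
  },
  "AKU": {
    "description": "usual/atypical-Kalow heterozygote (mother, I-2)",
    "btc": {"vmax": 6.07, "km_um": 27.0, "kss_mm": 0.51, "b": 2.5},
    "bzch": {"v50": 0.63, "km_um": 5.0},
    "dn_target": 58.3,
    "fn_target": 42.6,
    "analyzer_activity_iu_l": 7800.0,
    "reference_group": "women_under_39",
    "expected_label": "heterozygous_atypical_or_silent"
  },
  "AKS": {
    "description": "atypical-Kalow/silent compound heterozygote (proband, II-1)",
    "btc": {"vmax": 0.50, "km_um": 265.0, "kss_mm": null, "b": 1.0},
    "bzch": {"v50": 0.16, "km_um": 25.0},
    "dn_target": 7.2,
    "fn_target": 15.7,
    "analyzer_activity_iu_l": 1270.0,
    "reference_group": "infants",
    "expected_label": "atypical_silent_like"
  },
  "AA": {
    "description": "atypical homozygote (control)",
    "btc": {"vmax": 1.22, "km_um": 150.0, "kss_mm": 1.1, "b": 1.2},
    "bzch": {"v50": 0.39, "km_um": 25.0},
    "dn_target": 5.1,
    "fn_target": 13.0,
    "analyzer_activity_iu_l": 6000.0,
    "reference_group": "men",
    "expected_label": "atypical_homozygous_like",
    "free_constants": ["btc.vmax"]
  },
  "AS": {
    "description": "atypical/silent compound heterozygote (control)",
    "btc": {"vmax": 0.34, "km_um": 150.0, "kss_mm": 1.1, "b": 1.2},
    "bzch": {"v50": 0.12, "km_um": 25.0},
    "dn_target": 11.1,
    "fn_target": 15.0,
    "analyzer_activity_iu_l": 2000.0,
    "reference_group": "men",
    "expected_label": "atypical_silent_like",
    "free_constants": ["btc.vmax"]
  }
}
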