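{
  "rounding_dp": 2,
  "internal_standards": {
    "QX": 500.0,
    "ATE-D7": 250.0,
    "NFD-13C8": 25.0,
    "AML-D4": 25.0,
    "TEL-13CD3": 25.0
  },
  "analytes": [
    {"name": "CLN", "std9_ng_ml": 10.0, "lod_ng_ml": 0.02, "is_name": "QX", "polarity": "positive"},
    {"name": "DOX", "std9_ng_ml": 10.0, "lod_ng_ml": 0.02, "is_name": "QX", "polarity": "positive"},
    {"name": "NBV", "std9_ng_ml": 10.0, "lod_ng_ml": 0.02, "is_name": "QX", "polarity": "positive"},
    {"name": "AML", "std9_ng_ml": 20.0, "lod_ng_ml": 0.04, "is_name": "AML-D4", "polarity": "positive"},
    {"name": "HCTZ", "std9_ng_ml": 100.0, "lod_ng_ml": 0.19, "is_name": "QX", "polarity": "negative"},
    {"name": "NFD", "std9_ng_ml": 100.0, "lod_ng_ml": 0.19, "is_name": "NFD-13C8", "polarity": "positive"},
    {"name": "IDP", "std9_ng_ml": 100.0, "lod_ng_ml": 0.19, "is_name": "QX", "polarity": "positive"},
    {"name": "TEL", "std9_ng_ml": 100.0, "lod_ng_ml": 0.19, "is_name": "TEL-13CD3", "polarity": "positive"},
    {"name": "RAM", "std9_ng_ml": 100.0, "lod_ng_ml": 0.19, "is_name": "QX", "polarity": "positive"},
    {"name": "OLM", "std9_ng_ml": 250.0, "lod_ng_ml": 0.49, "is_name": "QX", "polarity": "positive"},
    {"name": "ATE", "std9_ng_ml": 1000.0, "lod_ng_ml": 1.91, "is_name": "ATE-D7", "polarity": "positive"},
    {"name": "CHL", "std9_ng_ml": 1000.0, "lod_ng_ml": 1.91, "is_name": "QX", "polarity": "negative"},
    {"name": "SCB", "std9_ng_ml": 2000.0, "lod_ng_ml": 0.98, "is_name": "QX", "polarity": "positive"},
    {"name": "VAL", "std9_ng_ml": 3000.0, "lod_ng_ml": 0.73, "is_name": "QX", "polarity": "positive"},
    {"name": "RAM-M", "std9_ng_ml": 100.0, "lod_ng_ml": 0.09, "is_name": "QX", "polarity": "positive"},
    {"name": "SCB-M", "std9_ng_ml": 8000.0, "lod_ng_ml": 1.95, "is_name": "QX", "polarity": "positive"}
  ]
}
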