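{
  "schema_version": 1,
  "units": "kcal/g",
  "description": "Actualized representative heats of combustion and overall intervals for the six carbohydrate classes of vegetal foods (maltose in both crystal forms), merging bibliographic and new bomb-calorimetry data.",
  "carbohydrates": [
    {"carb_id": "glucose", "representative": 3.74, "low": 3.69, "high": 3.78},
    {"carb_id": "fructose", "representative": 3.76, "low": 3.70, "high": 3.81},
    {"carb_id": "sucrose", "representative": 3.95, "low": 3.91, "high": 4.00},
    {"carb_id": "maltose_monohydrate", "representative": 3.76, "low": 3.71, "high": 3.81},
    {"carb_id": "maltose_anhydrous", "representative": 3.99, "low": 3.93, "high": 4.04},
    {"carb_id": "starch", "representative": 4.16, "low": 4.07, "high": 4.25},
    {"carb_id": "cellulose", "representative": 4.15, "low": 4.05, "high": 4.25}
  ]
}
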