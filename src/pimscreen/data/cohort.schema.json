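{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "pimscreen cohort interchange format (documentation; validation is performed by pimscreen.cohort)",
  "type": "object",
  "required": ["patients"],
  "properties": {
    "format_version": {"type": "string"},
    "source": {"type": "string"},
    "seed": {"type": ["integer", "null"]},
    "patients": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["patient_id", "age_years", "sex", "medications"],
        "properties": {
          "patient_id": {"type": "string", "minLength": 1},
          "age_years": {"type": "integer", "minimum": 60},
          "sex": {"enum": ["male", "female"]},
          "conditions": {
            "type": "array",
            "items": {"type": "string"},
            "description": "codes from the packaged condition vocabulary"
          },
          "labs": {
            "type": "object",
            "description": "optional measurements; units fixed per field and never converted",
            "properties": {
              "egfr": {"type": "number", "exclusiveMinimum": 0},
              "serum_k": {"type": "number", "exclusiveMinimum": 0},
              "serum_na": {"type": "number", "exclusiveMinimum": 0},
              "corrected_ca": {"type": "number", "exclusiveMinimum": 0},
              "systolic_bp": {"type": "number", "exclusiveMinimum": 0},
              "diastolic_bp": {"type": "number", "exclusiveMinimum": 0},
              "heart_rate": {"type": "number", "exclusiveMinimum": 0},
              "qtc_ms": {"type": "number", "exclusiveMinimum": 0},
              "po2_kpa": {"type": "number", "exclusiveMinimum": 0},
              "pco2_kpa": {"type": "number", "exclusiveMinimum": 0},
              "tsh_mu_l": {"type": "number", "exclusiveMinimum": 0},
              "free_t4_status": {"enum": ["low", "normal", "high"]},
              "bmi": {"type": "number", "exclusiveMinimum": 0}
            }
          },
          "medications": {
            "type": "array",
            "minItems": 1,
            "items": {
              "type": "object",
              "required": ["atc_code"],
              "properties": {
                "atc_code": {"type": "string", "pattern": "^[A-Z][0-9]{2}[A-Z]{2}[0-9]{2}$"},
                "name": {"type": "string"},
                "daily_dose": {"type": "number", "minimum": 0},
                "dose_unit": {"enum": ["mg", "ug", "g"]},
                "route": {"enum": ["oral", "parenteral", "topical", "transdermal", "inhaled", "other"]},
                "prn": {"type": "boolean"},
                "duration_days": {"type": "integer", "minimum": 0},
                "indication_code": {"type": ["string", "null"]}
              }
            }
          }
        }
      }
    }
  }
}
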