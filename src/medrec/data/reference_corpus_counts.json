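{
  "patients": 271,
  "encounters": 975,
  "overview_notes": 4025,
  "discharge_summaries": 300,
  "discharge_summaries_available": 1717,
  "entities_total": 29596,
  "entities_discrepant": 2218,
  "entities_overview": 13759,
  "entities_discharge_summaries": 15837,
  "patients_with_discrepancy": 164,
  "encounters_with_discrepancy": 423
}
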