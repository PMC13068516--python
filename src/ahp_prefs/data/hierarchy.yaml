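# Default two-level endpoint hierarchy for antihypertensive treatment:
# four efficacy endpoints plus an aggregated Adverse-events criterion that
# is subdivided into four medication-related adverse events.
goal: endpoint_importance
criteria:
  - mortality
  - myocardial_infarction
  - stroke
  - heart_failure
  - adverse_events
children:
  adverse_events:
    - pain
    - dyspnea
    - cough
    - edema
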