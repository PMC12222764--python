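# Default pseudo-note templates, one per EHR concept.  Each template has a
# skeleton with named fill slots, a per-row phrase joined by row_separator,
# and a fixed fallback sentence used when the concept has no rows.  The
# wording is a repo-chosen declarative-sentence style; institutions can ship
# their own file in the same shape.
arrival:
  skeleton: "{rows}"
  row_phrase: >-
    The patient is a {age} year old {sex} patient of {race} race who arrived
    at the emergency department by {arrival_mode}.
  row_separator: " "
  missing_sentence: "Arrival information was not recorded."
triage:
  skeleton: "At triage: {rows}"
  row_phrase: >-
    heart rate was {heart_rate} bpm, blood pressure was {sbp}/{dbp} mmHg,
    respiratory rate was {resp_rate} breaths per minute, temperature was
    {temperature} degrees, and oxygen saturation was {spo2} percent.
    The triage acuity was {acuity}. The chief complaint was {chief_complaint}.
  row_separator: " "
  missing_sentence: "Triage information was not recorded."
medrecon:
  skeleton: "Medication reconciliation listed the following medications: {rows}."
  row_phrase: "{drug_name}"
  row_separator: ", "
  missing_sentence: "Medications were not administered."
vitals:
  skeleton: "Vital signs recorded during the stay: {rows}"
  row_phrase: >-
    at {charttime} heart rate {heart_rate} bpm, blood pressure {sbp}/{dbp}
    mmHg, respiratory rate {resp_rate} per minute, temperature {temperature}
    degrees, oxygen saturation {spo2} percent.
  row_separator: " "
  missing_sentence: "No vital signs were recorded during the stay."
pyxis:
  skeleton: "Medications dispensed during the stay: {rows}."
  row_phrase: "{drug_name} at {charttime}"
  row_separator: ", "
  missing_sentence: "No medications were dispensed during the stay."
diagnosis:
  skeleton: "Discharge diagnoses: {rows}."
  row_phrase: "{icd_title} (ICD-{icd_version} {icd_code})"
  row_separator: ", "
  missing_sentence: "No diagnoses were coded for this visit."
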