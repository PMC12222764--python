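# UCLA-like dialect: five concept tables (no medication reconciliation),
# keyed by a visit identifier with locally renamed columns.
name: ucla_like
files:
  arrival: encounters.csv
  triage: triage.csv
  vitals: vitals.csv
  pyxis: meds_dispensed.csv
  diagnosis: diagnoses.csv
columns:
  arrival:
    encounter_id: visit_id
    patient_id: mrn
    age: age_years
    sex: sex
    race: race
    arrival_mode: mode_of_arrival
    arrival_time: arrival_dttm
    depart_time: depart_dttm
    disposition: ed_disposition
    discharge_home: discharge_home
    icu: icu
    mortality: mortality
  triage:
    encounter_id: visit_id
    heart_rate: pulse
    sbp: bp_systolic
    dbp: bp_diastolic
    resp_rate: respirations
    temperature: temp
    spo2: pulse_ox
    acuity: esi_level
    chief_complaint: reason_for_visit
  vitals:
    encounter_id: visit_id
    charttime: recorded_dttm
    heart_rate: pulse
    sbp: bp_systolic
    dbp: bp_diastolic
    resp_rate: respirations
    temperature: temp
    spo2: pulse_ox
  pyxis:
    encounter_id: visit_id
    charttime: dispense_dttm
    drug_name: medication
  diagnosis:
    encounter_id: visit_id
    icd_code: icd_code
    icd_version: icd_version
    icd_title: dx_name
    seq_num: dx_rank
admit_codes: [ADMITTED, ADMIT]
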