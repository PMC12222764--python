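# MIMIC-IV-ED-like dialect: six concept tables keyed by stay_id.
name: mimic_ed
files:
  arrival: edstays.csv
  triage: triage.csv
  medrecon: medrecon.csv
  vitals: vitalsign.csv
  pyxis: pyxis.csv
  diagnosis: diagnosis.csv
columns:
  arrival:
    encounter_id: stay_id
    patient_id: subject_id
    age: age
    sex: gender
    race: race
    arrival_mode: arrival_transport
    arrival_time: intime
    depart_time: outtime
    disposition: disposition
    discharge_home: discharge_home
    icu: icu
    mortality: mortality
  triage:
    encounter_id: stay_id
    heart_rate: heartrate
    sbp: sbp
    dbp: dbp
    resp_rate: resprate
    temperature: temperature
    spo2: o2sat
    acuity: acuity
    chief_complaint: chiefcomplaint
  medrecon:
    encounter_id: stay_id
    drug_name: name
    drug_code: gsn
  vitals:
    encounter_id: stay_id
    charttime: charttime
    heart_rate: heartrate
    sbp: sbp
    dbp: dbp
    resp_rate: resprate
    temperature: temperature
    spo2: o2sat
  pyxis:
    encounter_id: stay_id
    charttime: charttime
    drug_name: name
  diagnosis:
    encounter_id: stay_id
    icd_code: icd_code
    icd_version: icd_version
    icd_title: icd_title
    seq_num: seq_num
admit_codes: [ADMITTED]
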