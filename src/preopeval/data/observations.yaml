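# Demonstrator observation dictionary for preoperative evaluation.
# Dotted ids encode the organ-system hierarchy; parent_id is authoritative.
# Children with activation {op: is_yes} are only queried on a positive
# screening answer; activation "always" marks organisational levels.
observations:
  # -- 1: surgical procedure ------------------------------------------------
  - {id: "1", label: "Surgical procedure factors", value_kind: dichotomous}
  - {id: "1.1", label: "Procedure risk profile assessed", value_kind: dichotomous,
     parent_id: "1", activation: always}
  - {id: "1.1.3", label: "High-risk surgical conditions", value_kind: dichotomous,
     parent_id: "1.1", activation: always}
  # -- 2: cardiovascular system --------------------------------------------
  - {id: "2", label: "Cardiovascular system", value_kind: dichotomous}
  - {id: "2.1", label: "Functional capacity limited", value_kind: dichotomous,
     parent_id: "2", activation: always}
  - {id: "2.1.4", label: "< 4 MET on structured questionnaire", value_kind: dichotomous,
     parent_id: "2.1", activation: {op: is_yes}}
  - {id: "2.1.5", label: "< 4 MET: unable to climb two flights of stairs", value_kind: dichotomous,
     parent_id: "2.1", activation: {op: is_yes}}
  - {id: "2.1.6", label: "< 4 MET by Duke Activity Status Index", value_kind: dichotomous,
     parent_id: "2.1", activation: {op: is_yes}}
  - {id: "2.2", label: "Cardiac risk factors present", value_kind: dichotomous,
     parent_id: "2", activation: always}
  - {id: "2.2.1", label: "History of ischaemic heart disease", value_kind: dichotomous,
     parent_id: "2.2", activation: {op: is_yes}}
  - {id: "2.2.2", label: "History of congestive heart failure", value_kind: dichotomous,
     parent_id: "2.2", activation: {op: is_yes}}
  - {id: "2.2.3", label: "History of cerebrovascular disease", value_kind: dichotomous,
     parent_id: "2.2", activation: {op: is_yes}}
  - {id: "2.2.4", label: "Insulin-dependent diabetes mellitus", value_kind: dichotomous,
     parent_id: "2.2", activation: {op: is_yes}}
  - {id: "2.2.5", label: "Serum creatinine > 2.0 mg/dL", value_kind: dichotomous,
     parent_id: "2.2", activation: {op: is_yes}}
  - {id: "2.3", label: "Serum creatinine", value_kind: numeric, unit: "mg/dL",
     parent_id: "2", activation: always}
  # -- 3: airway and sleep --------------------------------------------------
  - {id: "3", label: "Airway and sleep", value_kind: dichotomous}
  - {id: "3.1", label: "Obstructive sleep apnoea screening", value_kind: dichotomous,
     parent_id: "3", activation: always}
  - {id: "3.1.1", label: "Loud snoring", value_kind: dichotomous,
     parent_id: "3.1", activation: always}
  - {id: "3.1.2", label: "Daytime tiredness", value_kind: dichotomous,
     parent_id: "3.1", activation: always}
  - {id: "3.1.3", label: "Observed apnoea", value_kind: dichotomous,
     parent_id: "3.1", activation: always}
  - {id: "3.1.4", label: "Treated or untreated hypertension", value_kind: dichotomous,
     parent_id: "3.1", activation: always}
  - {id: "3.1.5", label: "Neck circumference > 40 cm", value_kind: dichotomous,
     parent_id: "3.1", activation: always}
  # -- 4: renal and abdominal ----------------------------------------------
  - {id: "4", label: "Renal and abdominal", value_kind: dichotomous}
  - {id: "4.1", label: "Intraperitoneal procedure planned", value_kind: dichotomous,
     parent_id: "4", activation: always}
  - {id: "4.2", label: "Ascites", value_kind: dichotomous,
     parent_id: "4", activation: always}
  - {id: "4.3", label: "Mild or moderate renal insufficiency", value_kind: dichotomous,
     parent_id: "4", activation: always}
  - {id: "4.4", label: "Diabetes mellitus on oral therapy", value_kind: dichotomous,
     parent_id: "4", activation: always}
  # -- 5: chronic comorbidity inventory (Charlson conditions) ---------------
  - {id: "5", label: "Chronic comorbidities", value_kind: dichotomous}
  - {id: "5.1", label: "Myocardial infarction", value_kind: dichotomous,
     parent_id: "5", activation: always}
  - {id: "5.2", label: "Congestive heart failure", value_kind: dichotomous,
     parent_id: "5", activation: always}
  - {id: "5.3", label: "Peripheral vascular disease", value_kind: dichotomous,
     parent_id: "5", activation: always}
  - {id: "5.4", label: "Cerebrovascular disease", value_kind: dichotomous,
     parent_id: "5", activation: always}
  - {id: "5.5", label: "Dementia", value_kind: dichotomous,
     parent_id: "5", activation: always}
  - {id: "5.6", label: "Chronic pulmonary disease", value_kind: dichotomous,
     parent_id: "5", activation: always}
  - {id: "5.7", label: "Connective tissue disease", value_kind: dichotomous,
     parent_id: "5", activation: always}
  - {id: "5.8", label: "Peptic ulcer disease", value_kind: dichotomous,
     parent_id: "5", activation: always}
  - {id: "5.9", label: "Mild liver disease", value_kind: dichotomous,
     parent_id: "5", activation: always}
  - {id: "5.10", label: "Diabetes mellitus", value_kind: dichotomous,
     parent_id: "5", activation: always}
  - {id: "5.11", label: "Diabetes with end-organ damage", value_kind: dichotomous,
     parent_id: "5", activation: always}
  - {id: "5.12", label: "Hemiplegia", value_kind: dichotomous,
     parent_id: "5", activation: always}
  - {id: "5.13", label: "Moderate or severe renal disease", value_kind: dichotomous,
     parent_id: "5", activation: always}
  - {id: "5.14", label: "Any tumour", value_kind: dichotomous,
     parent_id: "5", activation: always}
  - {id: "5.15", label: "Leukaemia", value_kind: dichotomous,
     parent_id: "5", activation: always}
  - {id: "5.16", label: "Lymphoma", value_kind: dichotomous,
     parent_id: "5", activation: always}
  - {id: "5.17", label: "Moderate or severe liver disease", value_kind: dichotomous,
     parent_id: "5", activation: always}
  - {id: "5.18", label: "Metastatic solid tumour", value_kind: dichotomous,
     parent_id: "5", activation: always}
  - {id: "5.19", label: "AIDS", value_kind: dichotomous,
     parent_id: "5", activation: always}
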