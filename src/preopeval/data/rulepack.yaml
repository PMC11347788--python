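# Demonstrator rule pack for preoperative evaluation.
#
# The non-invasive cardiac stress-test rule follows the published AND/OR
# encoding exactly (poor functional capacity by any of three MET observations,
# >= 3 clinical cardiac risk factors, high-risk surgical conditions). The ECG
# decision tree and the remaining examination rules are documented
# demonstrator encodings (risk-factor count x surgical risk class); they are
# representative, not a transcription of any guideline corpus.
version: "demo-1"
observations: observations.yaml
scores:
  - rcri_clinical_factors
  - rcri_total
  - stop_bang
  - aki_factor_count
  - charlson
  - surgical_risk
  - age
  - bmi
rules:
  - rule_id: stress_test_met_rcri
    action: cardiac_stress_test
    source: ESC
    conditions:
      - grade: "1C"
        all_of:
          - any_of:
              - {atom: {target: "2.1.4", op: is_yes}}
              - {atom: {target: "2.1.5", op: is_yes}}
              - {atom: {target: "2.1.6", op: is_yes}}
          - {atom: {target: rcri_clinical_factors, op: ge, value: 3}}
          - {atom: {target: "1.1.3", op: is_yes}}
  - rule_id: ecg_risk_tree
    action: ECG
    source: ESC
    conditions:
      - grade: "1C"
        tree:
          if: {target: rcri_clinical_factors, op: ge, value: 1}
          then:
            if: {target: surgical_risk, op: in_set, value: [intermediate, high]}
            then: fire
            else: no_fire
          else: no_fire
      - grade: "2B"
        all_of:
          - {atom: {target: age, op: ge, value: 65}}
          - {atom: {target: surgical_risk, op: equals, value: high}}
  - rule_id: echo_heart_failure
    action: echocardiography
    source: ESC
    conditions:
      - grade: "1C"
        all_of:
          - {atom: {target: "2.2.2", op: is_yes}}
          - {atom: {target: surgical_risk, op: in_set, value: [intermediate, high]}}
  - rule_id: pulmonary_function_osa
    action: pulmonary_function
    source: DGAI
    conditions:
      - grade: "2B"
        all_of:
          - {atom: {target: stop_bang, op: ge, value: 3}}
          - {atom: {target: surgical_risk, op: equals, value: high}}
  - rule_id: lab_creatinine_aki
    action: "laboratory:creatinine"
    source: ESAIC
    conditions:
      - grade: "2C"
        atom: {target: aki_factor_count, op: ge, value: 3}
  - rule_id: lab_haemoglobin_high_risk
    action: "laboratory:haemoglobin"
    source: ESAIC
    conditions:
      - grade: "2A"
        atom: {target: surgical_risk, op: equals, value: high}
  - rule_id: cardiology_consult
    action: "other:cardiology_consult"
    source: consensus
    conditions:
      - grade: "2C"
        atom: {target: rcri_clinical_factors, op: ge, value: 4}
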