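# General-surgery acute kidney injury risk index: count of preoperative risk
# factors mapped to five risk classes. Factor list and count->class map ship
# as configurable data (the class map is the canonical I: <=2, II: 3, III: 4,
# IV: 5, V: >=6 grouping).
name: aki_risk_index
factors:
  - {field: age_ge, value: 56, label: Age >= 56 yr}
  - {field: sex_male, label: Male sex}
  - {field: emergency, label: Emergency surgery}
  - {obs: "4.1", label: Intraperitoneal surgery}
  - {obs: "2.2.2", label: Active congestive heart failure}
  - {obs: "4.2", label: Ascites}
  - {obs: "3.1.4", label: Hypertension}
  - {obs: "4.3", label: Mild or moderate renal insufficiency}
  - {obs: "4.4", label: Diabetes mellitus on oral therapy}
  - {obs: "2.2.4", label: Diabetes mellitus on insulin therapy}
classes:
  - {max: 2, label: I}
  - {max: 3, label: II}
  - {max: 4, label: III}
  - {max: 5, label: IV}
  - {max: null, label: V}
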