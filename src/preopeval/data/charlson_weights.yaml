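# Charlson Comorbidity Index weight table (weights 1/2/3/6), transcribed from
# the originally published condition list. Severity pairs are linked with
# `supersedes`: when the severe form is present the milder form's weight is
# not counted again, so 17 independent conditions contribute.
name: charlson
items:
  - {obs: "5.1", label: Myocardial infarction, weight: 1}
  - {obs: "5.2", label: Congestive heart failure, weight: 1}
  - {obs: "5.3", label: Peripheral vascular disease, weight: 1}
  - {obs: "5.4", label: Cerebrovascular disease, weight: 1}
  - {obs: "5.5", label: Dementia, weight: 1}
  - {obs: "5.6", label: Chronic pulmonary disease, weight: 1}
  - {obs: "5.7", label: Connective tissue disease, weight: 1}
  - {obs: "5.8", label: Peptic ulcer disease, weight: 1}
  - {obs: "5.9", label: Mild liver disease, weight: 1}
  - {obs: "5.10", label: Diabetes mellitus, weight: 1}
  - {obs: "5.11", label: Diabetes with end-organ damage, weight: 2, supersedes: "5.10"}
  - {obs: "5.12", label: Hemiplegia, weight: 2}
  - {obs: "5.13", label: Moderate or severe renal disease, weight: 2}
  - {obs: "5.14", label: Any tumour, weight: 2}
  - {obs: "5.15", label: Leukaemia, weight: 2}
  - {obs: "5.16", label: Lymphoma, weight: 2}
  - {obs: "5.17", label: Moderate or severe liver disease, weight: 3, supersedes: "5.9"}
  - {obs: "5.18", label: Metastatic solid tumour, weight: 6, supersedes: "5.14"}
  - {obs: "5.19", label: AIDS, weight: 6}
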