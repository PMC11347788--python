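# SYNTHETIC stand-in for the published POSPOM points table (the original
# table is not redistributed here). The structure is faithful — additive
# integer points from age bands, comorbidity flags, and the procedure risk
# group — but the point values are a demonstrator transcription, NOT the
# published ones. Loaded with checksum verification; scores computed from
# this table must never be compared against published POSPOM values.
name: pospom
age_bands:
  - {min: 0, points: 0}
  - {min: 50, points: 4}
  - {min: 60, points: 8}
  - {min: 70, points: 12}
  - {min: 80, points: 16}
comorbidities:
  - {obs: "5.2", label: Congestive heart failure, points: 4}
  - {obs: "5.1", label: Ischaemic heart disease, points: 3}
  - {obs: "5.4", label: Cerebrovascular disease, points: 3}
  - {obs: "5.13", label: Renal disease, points: 4}
  - {obs: "5.14", label: Cancer, points: 5}
  - {obs: "5.10", label: Diabetes mellitus, points: 2}
  - {obs: "5.6", label: Chronic pulmonary disease, points: 2}
procedure_points:
  low: 2
  intermediate: 5
  high: 9
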