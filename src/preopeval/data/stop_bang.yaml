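# STOP-BANG obstructive sleep apnoea screen: eight yes/no items, one point
# each. Four items come from observations, four are derived from record
# fields (BMI > 35 kg/m2, age > 50 yr, neck circumference flag, male sex).
# Default risk band per the screening literature: >= 3 points is high risk
# (band cutoffs are configurable data).
name: stop_bang
items:
  - {obs: "3.1.1", label: Snoring}
  - {obs: "3.1.2", label: Tiredness}
  - {obs: "3.1.3", label: Observed apnoea}
  - {obs: "3.1.4", label: Pressure (hypertension)}
  - {field: bmi_gt, value: 35, label: BMI > 35 kg/m2}
  - {field: age_gt, value: 50, label: Age > 50 yr}
  - {obs: "3.1.5", label: Neck circumference > 40 cm}
  - {field: sex_male, label: Male sex}
bands:
  - {min: 0, label: low}
  - {min: 3, label: high}
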