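# Activity abstraction hierarchy: low-level label -> abstract label.
# Chains are allowed (resolved transitively); `drop` lists activities to
# eliminate entirely (comorbidity procedures unrelated to the pathway).
mapping:
  Glucose: Lab Test
  Potassium: Lab Test
  Creatinine: Lab Test
  Calcium: Lab Test
  Magnesium: Lab Test
  CT abdomen: CT scan
  CT brain: CT scan
  wrist X-ray: X-ray
  knee X-ray: X-ray
drop:
  - eye lens operation
  - bone excision
  - ovariectomy
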