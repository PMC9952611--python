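# The ten electrolyte disorders screened, each expanded to its pair of
# MedDRA preferred terms: the clinical diagnosis PT and the corresponding
# laboratory-finding PT.  Each PT belongs to exactly one disorder.
hypokalemia:
  - hypokalaemia
  - blood potassium decreased
hyperkalemia:
  - hyperkalaemia
  - blood potassium increased
hyponatremia:
  - hyponatraemia
  - blood sodium decreased
hypernatremia:
  - hypernatraemia
  - blood sodium increased
hypocalcemia:
  - hypocalcaemia
  - blood calcium decreased
hypercalcemia:
  - hypercalcaemia
  - blood calcium increased
hypomagnesemia:
  - hypomagnesaemia
  - blood magnesium decreased
hypermagnesemia:
  - hypermagnesaemia
  - blood magnesium increased
hypophosphatemia:
  - hypophosphataemia
  - blood phosphorus decreased
hyperphosphatemia:
  - hyperphosphataemia
  - blood phosphorus increased
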