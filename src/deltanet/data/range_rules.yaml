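# Clinical out-of-range rules: single direction of risk per biomarker,
# Quest-style cutoffs; thresholds are strict (a value exactly at the
# threshold is in range).  sex_stratified marks biomarkers whose change
# analysis is run separately per sex.
VITD:
  direction: low
  threshold: 30
  units: mg/dL
LDL:
  direction: high
  threshold: 130
  units: mg/dL
CK:
  direction: high
  threshold: 230
  units: U/L
GLU:
  direction: high
  threshold: 100
  units: mg/dL
HDL:
  direction: low
  threshold: 50
  units: mg/dL
CHOL:
  direction: high
  threshold: 200
  units: mg/dL
ALT:
  direction: high
  threshold: {male: 46, female: 29}
  units: U/L
TRIG:
  direction: high
  threshold: 150
  units: mg/dL
CORT:
  direction: high
  threshold: 22
  units: ug/dL
FERR:
  direction: low
  threshold: {male: 20, female: 10}
  units: ng/mL
HSCRP:
  direction: high
  threshold: 3
  units: mg/L
AST:
  direction: high
  threshold: 40
  units: U/L
TESTO:
  direction: low
  threshold: {male: 250, female: 0}
  units: ng/dL
  sex_stratified: true
EOS:
  direction: high
  threshold: 200
  units: cells/uL
MCHC:
  direction: low
  threshold: 32
  units: g/dL
SHBG:
  direction: high
  threshold: 40
  units: nmol/L
FTESTO:
  direction: low
  threshold: {male: 46, female: 0}
  units: pg/mL
  sex_stratified: true
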