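# Default per-biomarker plausibility limits (outer bounds of acceptable
# values).  These are wide physiological bounds written for the bundled
# synthetic presets; for real cohorts derive limits from a population
# reference sample with qc.derive_limits (0.5 / 99.5 percentiles).
LDL: {lower: 30, upper: 300}
HDL: {lower: 15, upper: 150}
CHOL: {lower: 80, upper: 400}
TRIG: {lower: 25, upper: 800}
ALT: {lower: 5, upper: 250}
AST: {lower: 8, upper: 250}
GGT: {lower: 5, upper: 300}
CK: {lower: 20, upper: 2000}
MG: {lower: 1.0, upper: 3.5}
HSCRP: {lower: 0.05, upper: 30}
WBC: {lower: 2.0, upper: 20}
NEUT: {lower: 0.8, upper: 15}
LYMPH: {lower: 0.5, upper: 8}
MONO: {lower: 0.1, upper: 2}
FERR: {lower: 2, upper: 1000}
IRON: {lower: 20, upper: 250}
TIBC: {lower: 150, upper: 550}
TSAT: {lower: 5, upper: 80}
HGB: {lower: 8, upper: 20}
GLU: {lower: 40, upper: 400}
HBA1C: {lower: 3.5, upper: 12}
INS: {lower: 1, upper: 80}
VITD: {lower: 5, upper: 120}
VITB12: {lower: 100, upper: 2000}
FOL: {lower: 2, upper: 40}
TESTO: {lower: 10, upper: 1500}
FTESTO: {lower: 0.5, upper: 60}
SHBG: {lower: 5, upper: 200}
CORT: {lower: 2, upper: 45}
RBC: {lower: 3, upper: 7}
HCT: {lower: 25, upper: 60}
MCV: {lower: 65, upper: 115}
MCHC: {lower: 28, upper: 38}
PLT: {lower: 80, upper: 600}
EOS: {lower: 0.5, upper: 1500}
NA: {lower: 125, upper: 155}
K: {lower: 2.8, upper: 6}
CA: {lower: 7.5, upper: 11.5}
ALB: {lower: 2.5, upper: 6}
CREA: {lower: 0.3, upper: 3}
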