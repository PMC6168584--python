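# Seasonal biomarker designation: which biomarkers get a summer-offset
# adjustment before change testing, which calendar months count as summer,
# and the default planted/adjustment offset in the biomarker's native units.
VITD:
  summer_months: [6, 7, 8, 9]
  offset: 2.5
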