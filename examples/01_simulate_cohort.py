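"""Simulate a cohort with planted structure and peek at what was planted.

The 'paperlike' preset emulates a two-draw blood-test cohort: 40 biomarkers,
7 overlapping panels, block-correlated changes, a +2.5 summer offset on
vitamin D, and interventions that shift specific biomarker deltas.
"""

from deltanet.io import extract_pairs
from deltanet.synthetic import generate_cohort, preset

config = preset("paperlike", seed=1)
table, choices, truth = generate_cohort(config)
pairs = extract_pairs(table, min_gap_days=30)

print(f"participants:        {len(table.participants)}")
print(f"measurements:        {len(table.measurements)}")
print(f"longitudinal pairs:  {len(pairs)} (baseline + follow-up >= 30 days apart)")
print(f"intervention choices: {len(choices)}")
print(f"planted blocks:      {len(truth['r_within'])}")
print(f"seasonal offsets:    {truth['seasonal_offsets']}")
active = {k: v for k, v in truth["intervention_effects"].items() if v["delta_shift"]}
print(f"planted intervention effects: {active}")
# Each 'pair' is one participant's change (delta) on one biomarker; panels
# mean different participants carry different biomarker subsets.
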