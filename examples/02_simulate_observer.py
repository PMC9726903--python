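"""Simulate Bayesian observers and inspect their accuracy.

Each observer encodes intervals on a log scale with asymmetric sensory
noise and compares Kalman-filtered percepts; accuracy is lowest at the
shortest ISI (the second interval is noisiest there) and lower overall
when the variable comparison comes first (group CS).
"""

import numpy as np

from serialtoe import accuracy_table, default_params, simulate_cohort

params, spec = default_params()
for group, seed in (("SC", 1), ("CS", 2)):
    records = simulate_cohort(20, spec, group, params, np.random.default_rng(seed))
    table = accuracy_table(records)
    print(f"group {group}: mean accuracy by ISI")
    print(table.round(3).to_string(index=False))
    by_pos = accuracy_table(records, ("group", "longer_first"))
    print(by_pos.round(3).to_string(index=False))
    print()
print("Accuracy rises with ISI and is higher when the longer interval")
print("comes first - the ordinal position of the longer stimulus matters.")
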