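"""Build one session of the two-interval duration-discrimination design.

The standard lasts 120 ms; comparisons are placed symmetrically at
±20, ±60 and ±100 ms around it; each of four ISI blocks presents every
comparison equally often in random order.
"""

import numpy as np

from serialtoe import DesignSpec, build_design, derive_comparisons, design_to_frame, to_frames

spec = DesignSpec()
comparisons = derive_comparisons(spec.s_duration, spec.deltas)
print("comparison durations (ms):", comparisons)
print("frames at 144 Hz (ceiling):",
      [to_frames(c, 144, "ceiling") for c in comparisons])

trials = build_design(spec, group="SC", rng=np.random.default_rng(7))
df = design_to_frame(trials)
print(f"\nsession: {len(df)} trials, block order "
      f"{df.groupby('block_index')['isi_ms'].first().tolist()} (ISI in ms)")
print(df.head(6).to_string(index=False))
print("\nEach block holds 120 trials, 20 per comparison; the ITI column is")
print("the uniformly drawn 1-3 s gap between trials.")
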