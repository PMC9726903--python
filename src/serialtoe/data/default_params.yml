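# Default observer configuration.
#
# Units: durations in ms; noise SDs in log-duration units; the noise
# "shape" distributions are standardized (the measurement SD multiplies
# the draw).  These defaults reproduce the qualitative Type A
# time-order-error pattern of serial duration discrimination around a
# 120-ms standard: positive constant errors in both stimulus orders,
# larger when the unpredictable comparison comes first (group CS), and
# shrinking as the inter-stimulus interval grows.
observer:
  # process variance of the Kalman prior (log-units^2): a strongly
  # forgetting prior dominated by the most recent measurements
  q: 1.5
  # between-subject base (scalar) noise SD, truncated normal, log units
  sigma_subject: {loc: 0.1, scale: 0.01, lower: 0.07, upper: 0.14}
  # sub-scalar encoding floor for the FIRST interval of a trial: its SD
  # is sigma_subject * (1 + noise_floor_ms / duration), so short
  # first intervals are encoded disproportionately poorly
  noise_floor_ms: 450.0
  # multiplier on the second interval's scalar noise SD, by ISI (ms):
  # less preparation time at short ISIs means a noisier second interval
  isi_noise: {400: 2.6, 800: 1.95, 1600: 1.15, 2000: 1.0}
  # standardized noise of the SECOND interval, selected by the ordinal
  # position of the trial's longer interval; both are shifted low (the
  # second interval tends to be under-measured), more strongly so when
  # the longer interval is the second one
  longer_first_noise: {loc: -0.5, scale: 1.0}
  longer_second_noise: {loc: -0.95, scale: 1.1}
  # standardized noise of a shorter FIRST interval on weak (delta 20 ms)
  # discriminations: positively truncated, i.e. systematic expansion
  weak_level_noise: {loc: 0.25, scale: 0.5, lower: 0.0}
  weak_delta: 20.0
  prior:
    mean0: 4.787491742782046   # ln(120 ms)
    var0: 10.0                 # diffuse start
    carryover: true            # prior persists across ISI blocks
design:
  s_duration: 120.0
  deltas: [20.0, 60.0, 100.0]
  isis: [400.0, 800.0, 1600.0, 2000.0]
  trials_per_block: 120
  iti_range: [1000.0, 3000.0]
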