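# Default dorsal-horn network parameters (version 1).
#
# Produced by the documented calibration procedure (see docs/methods.md):
# (a) the healthy C-window projection response crosses the 25 Hz pain
#     threshold; (b) A-beta (touch) input alone never crosses it;
# (c) delaying spikes on half of the A-beta fibers yields maximal pain
#     inhibition for delays near the start of the C response.
time_constants_ms:
  p: 10.0
  e: 30.0
  i: 6.0
weights:
  ab_to_p: 0.05
  ab_to_e: 0.0
  ab_to_i: 0.6
  c_to_p: 1.7
  c_to_e: 1.0
  e_to_p: 0.6
  i_to_p: 0.3
response_curves:
  p: {max_rate: 60.0, half_drive: 54.0, gain: 0.0755}
  e: {max_rate: 50.0, half_drive: 15.0, gain: 0.2}
  i: {max_rate: 80.0, half_drive: 30.0, gain: 0.07}
nmda:
  baseline: 0.6
  saturation: 2.1
  half_rate_hz: 13.5
  hill: 2.0
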