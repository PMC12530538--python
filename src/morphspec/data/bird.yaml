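# Violet-sensitive (VS) raptor visual system modelled on the common
# buzzard, Buteo buteo. Peak sensitivities are VS-class values from the
# raptor literature; cone abundance ratio 1:2:2:4 and a Weber fraction of
# 0.10 for the LW reference cone; LW curve as the achromatic channel.
name: bird
lambda_max: [405, 450, 504, 567]
eta: [1, 2, 2, 4]
weber_ref: 0.10
channels: [u, s, m, l]
achromatic:
  channel: l
  weber: 0.10
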