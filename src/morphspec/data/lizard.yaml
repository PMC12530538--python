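# Wall-lizard (lacertid) tetrachromat visual system.
# Peak single-cone sensitivities follow microspectrophotometry of
# Podarcis muralis (UVS/SWS/MWS/LWS); cone abundance ratio 1:1:1:4 and a
# Weber fraction of 0.05 for the LW reference cone. The achromatic
# (luminance) channel uses the LW curve, standing in for the double cones.
name: lizard
lambda_max: [367, 456, 497, 562]
eta: [1, 1, 1, 4]
weber_ref: 0.05
channels: [u, s, m, l]
achromatic:
  channel: l
  weber: 0.05
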