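# Colubrid snake visual system modelled on the garter snake,
# Thamnophis sirtalis. The snake literature documents three cone pigments
# (~360, ~482 and ~554 nm); this four-channel configuration adds an
# interpolated blue-sensitive channel at 458 nm so the snake occupies the
# same tetrachromatic colour space as the other observers. Edit this file
# (or drop a channel) to use a literal trichromat instead — all distance
# code handles any channel count. Abundance ratio 1:1:1:4, Weber 0.05.
name: snake
lambda_max: [360, 458, 482, 554]
eta: [1, 1, 1, 4]
weber_ref: 0.05
channels: [u, s, m, l]
achromatic:
  channel: l
  weber: 0.05
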