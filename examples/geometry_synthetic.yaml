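# Example funiculus geometry. These dimensions are synthetic plausibility
# values on the scale of a mid-sized tephritid fly; measure your own
# species (length, width, thickness of the funiculus, mean of ~10
# individuals) and substitute them.
species: synthetic-tephritid
length_mm: 0.6
width_mm: 0.3
thickness_mm: 0.25
positions_norm: [0.0, 0.3333333333333333, 0.6666666666666666, 1.0]
sigma: 10.0
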