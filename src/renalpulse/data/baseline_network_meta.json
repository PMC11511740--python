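{
 "n_vessels": 113,
 "n_outlets": 60,
 "n_renal_per_side": 38,
 "n_segmental_per_side": 5,
 "note": "Reconstructed fixture: published vessel counts (113 vessels, 38 renal per side, 5 segmental per side) and named model values are honoured; the published outlet count (49) is arithmetically incompatible with a strict tree under those counts, so the actual outlet count is recorded here instead."
}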