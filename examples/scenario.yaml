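# Two-process demonstration scenario: dissection (left half) vs infill
# (right half) on a 400x400-pixel modified-random-clusters landscape.
rows: 400
cols: 400
pixel_size: 50
forest_proportion: 0.5
autocorrelation: 0.8
seed: 11
operators:
  - operator: dissection
    intensity: 0.6
    region: [0, 400, 0, 200]
  - operator: infill
    intensity: 0.5
    region: [0, 400, 200, 400]
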