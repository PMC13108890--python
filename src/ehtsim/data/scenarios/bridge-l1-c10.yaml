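# Two immature (C10) graft patches bridge the transmural strip.  The
# premature wave crawls through the freestanding graft (~12 cm/s),
# re-emerges into recovered myocardium on the far side, and a sustained
# figure-of-eight through the two bridges results.
name: bridge-l1-c10
geometry: {extent: [72, 44], resolution: 0.5}
infarct: {shape: strip, x_range: [26, 46]}
eht:
  - {footprint: [40, 16], conductivity_fraction: 0.10, center: [36, 33]}
  - {footprint: [40, 16], conductivity_fraction: 0.10, center: [36, 11]}
pacing: {seeds: [[3, 22]], radius: 1.0}
aip: {dt: 0.1, s2_offsets: [295]}
expected_outcome: sVT
seed: 0
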