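# Laterally placed matured grafts: as with C10, no bridge forms; the
# higher graft conductivity changes nothing at this location.
name: bridge-l2-c90
geometry: {extent: [72, 44], resolution: 0.5}
infarct: {shape: strip, x_range: [26, 46]}
eht:
  - {footprint: [40, 16], conductivity_fraction: 0.90, location: L2, center: [36, 33]}
  - {footprint: [40, 16], conductivity_fraction: 0.90, location: L2, center: [36, 11]}
pacing: {seeds: [[3, 22]], radius: 1.0}
aip: {dt: 0.1, s2_offsets: [295]}
expected_outcome: NR
seed: 0
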