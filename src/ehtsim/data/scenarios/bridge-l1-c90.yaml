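# The same bridges with matured (C90) conductivity: the crossing is ~3x
# faster, the wave re-emerges into still-refractory tissue and reentry
# is abolished.  Electrical maturation as an antiarrhythmic factor.
name: bridge-l1-c90
geometry: {extent: [72, 44], resolution: 0.5}
infarct: {shape: strip, x_range: [26, 46]}
eht:
  - {footprint: [40, 16], conductivity_fraction: 0.90, center: [36, 33]}
  - {footprint: [40, 16], conductivity_fraction: 0.90, center: [36, 11]}
pacing: {seeds: [[3, 22]], radius: 1.0}
aip: {dt: 0.1, s2_offsets: [295]}
expected_outcome: NR
seed: 0
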