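# Uniform healthy sheet: the premature wave expands and dies at the
# boundaries; no substrate, no reentry.
name: healthy-control
geometry: {extent: [40, 30], resolution: 0.5}
pacing: {seeds: [[3, 15]], radius: 1.0}
aip: {dt: 0.1, s2_offsets: [295]}
expected_outcome: NR
seed: 0
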