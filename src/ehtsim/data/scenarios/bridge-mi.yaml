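# Fully transmural scar strip splitting the sheet in two; without a
# graft there is no conductive path across, so the premature beat
# cannot reenter.
name: bridge-mi
geometry: {extent: [72, 44], resolution: 0.5}
infarct: {shape: strip, x_range: [26, 46]}
pacing: {seeds: [[3, 22]], radius: 1.0}
aip: {dt: 0.1, s2_offsets: [295]}
expected_outcome: NR
seed: 0
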