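# Transmural scar wall pierced by a slow border-zone channel at the far
# end of an elongated sheet.  The premature wave reaches the channel
# late enough for it to have recovered, crawls through, re-emerges into
# recovered tissue and re-enters: non-sustained reentrant activity.
name: isthmus-reentry
geometry: {extent: [110, 40], resolution: 0.5}
infarct: {shape: channel_wall, x_range: [86, 98], channel_y: [17, 23]}
pacing: {seeds: [[3, 20]], radius: 1.0}
aip: {dt: 0.1, s2_offsets: [295]}
expected_outcome: nsVT
seed: 0
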