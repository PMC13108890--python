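# The isthmus substrate with a conduction-system tree spanning the
# sheet.  The fast bypass is open at the 600 ms drive but refractory at
# the 295 ms extrastimulus (CS APD 310 ms > coupling interval), so the
# activation sequence of S1 and S2 differ; the CS return limb turns the
# non-sustained channel reentry into sustained VT.
name: cs-enables
geometry: {extent: [110, 40], resolution: 0.5}
infarct: {shape: channel_wall, x_range: [86, 98], channel_y: [17, 23]}
cs: {enabled: true, root: [2, 20], depth: 4, segment_length: 36, length_ratio: 0.75, branch_angle: 25, seed: 2}
pacing: {seeds: [[3, 20]], radius: 1.0}
aip: {dt: 0.1, s2_offsets: [295]}
expected_outcome: sVT
seed: 0
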