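"""Parcellate an LV surface into the AHA 17 segments and localize hypokinesis.

Generates a ventricle whose apical-anterior segments barely move, labels
every vertex with its AHA segment, and prints the per-segment mean wall
displacement — the planted motion deficit shows up in segments 13/15/16.
"""

import numpy as np

from lvshapeflow import LVGenParams, assign_segments, make_lv, segment_aggregate

lv = make_lv(LVGenParams(hypokinesis={13: 0.05, 15: 0.05, 16: 0.05}, seed=2))
segmap = assign_segments(lv.ed_mesh)
motion = np.linalg.norm(lv.displacement, axis=1)
per_segment = segment_aggregate(segmap, motion)

print("seg  vertices  wall motion (mm)")
for seg in range(1, 18):
    flag = "  <- hypokinetic" if seg in (13, 15, 16) else ""
    print(f"{seg:3d}  {segmap.counts()[seg - 1]:8d}  {per_segment[seg - 1]:10.2f}{flag}")
print(f"\nglobal mean wall motion: {motion.mean():.2f} mm")
print("segments 13/15/16 average far below the rest: the parcellation")
print("recovers the regional contraction deficit the generator planted.")
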