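"""Turn a contraction field into volume-curve-following wall motion.

The end-diastolic surface is deformed along its ED→ES displacement field by
a per-step scaling factor λ(t) solved so the cavity volume tracks a
75 bpm volume curve at the requested ejection fraction; differencing λ
gives the grid-velocity boundary condition a flow solver consumes.
"""

import numpy as np

from lvshapeflow import (
    LVGenParams,
    default_normalized_curve,
    enclosed_volume,
    grid_velocity,
    make_lv,
    scale_volume_curve,
    solve_motion_scaling,
)

lv = make_lv(LVGenParams(target_ef=0.25, seed=0))
edv = enclosed_volume(lv.ed_mesh)
curve = scale_volume_curve(default_normalized_curve(), edv, ef=0.25,
                           heart_rate=75.0)
pres = solve_motion_scaling(lv.ed_mesh, lv.displacement, curve, dt=0.002)
vg = grid_velocity(pres, lv.displacement)

err = np.abs(pres.achieved_volumes - pres.target_volumes) / edv
speed = np.linalg.norm(vg, axis=2)
print(f"cycle period            : {curve.period:.3f} s (75 bpm)")
print(f"time steps              : {len(pres.times)} at {pres.time_step * 1e3:.0f} ms")
print(f"EDV / target ESV        : {edv:.1f} / {curve.volumes.min():.1f} ml")
print(f"max volume error / EDV  : {err.max():.2e}")
print(f"achieved EF             : {(edv - pres.achieved_volumes.min()) / edv:.4f}")
print(f"peak wall speed         : {speed.max():.1f} mm/s")
print("lambda stays in [0, 1], returns to 0 at end-cycle, and the deformed")
print("cavity tracks the prescribed volume curve to fractions of a percent.")
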