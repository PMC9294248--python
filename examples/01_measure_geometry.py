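"""Measure the standard geometric markers of one synthetic LV case.

Builds a dilated synthetic ventricle, then reports cavity volumes, stroke
volume, ejection fraction, sphericity and the fitted annulus areas — the
per-case quantities the shape-modeling pipeline consumes.
"""

import numpy as np

from lvshapeflow import (
    LVGenParams,
    ef_sv,
    enclosed_volume,
    fit_annulus,
    make_lv,
    sphericity_index,
)

lv = make_lv(LVGenParams(seed=0))

edv = enclosed_volume(lv.ed_mesh)
esv = enclosed_volume(lv.es_mesh)
sv, ef = ef_sv(edv, esv)
si = sphericity_index(lv.ed_mesh)
av = fit_annulus(lv.ed_mesh.landmark_ring("aortic_annulus"), "ellipse")
mv = fit_annulus(lv.ed_mesh.landmark_ring("mitral_annulus"), "cardioid")

print(f"LVEDV  {edv:7.1f} ml   end-diastolic cavity volume")
print(f"LVESV  {esv:7.1f} ml   end-systolic cavity volume")
print(f"SV     {sv:7.1f} ml   ejected per beat")
print(f"EF     {ef:7.3f}      fraction of EDV ejected (dilated, reduced)")
print(f"SI     {si:7.3f}      sphericity (1 = sphere, lower = elongated)")
print(f"AVAA   {av.area / 100:7.2f} cm²  aortic annulus (ellipse fit)")
print(f"MVAA   {mv.area / 100:7.2f} cm²  mitral annulus (cardioid fit)")
print(f"wall   {np.mean(lv.thickness):7.2f} mm   mean myocardial thickness")
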