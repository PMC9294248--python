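"""Fit a multi-channel statistical shape model to a synthetic cohort.

Generates 40 corresponded cases driven by two orthogonal anatomical modes,
stacks each case into its (coordinates, contraction, thickness, RCA)
feature column, fits the PCA model and shows that two modes explain the
cohort; the mean case is then synthesized back into a surface.
"""

import numpy as np

from lvshapeflow import (
    FeatureMatrix,
    cumulative_variance,
    fit_model,
    make_cohort,
    modes_for_variance,
    synthesize,
)
from lvshapeflow.ssm import ShapeVector, shape_vector_to_geometry
from lvshapeflow.geometry import enclosed_volume

spec = make_cohort(40, mode_sigmas=(4.0, 2.0), noise=0.0, seed=7)
matrix = FeatureMatrix.from_cases(spec.cases)
model = fit_model(matrix)

cum = cumulative_variance(model)
print(f"training cases           : {matrix.n}")
print(f"feature-vector length    : {matrix.M.shape[0]}  (= 7m+3, m = {matrix.m})")
print(f"variance in mode 1       : {100 * cum[0]:.1f} %")
print(f"variance in modes 1-2    : {100 * cum[1]:.1f} %")
print(f"modes for 95 % variance  : {modes_for_variance(model, 0.95)}")

mean_case = shape_vector_to_geometry(ShapeVector.unpack(synthesize(model, [])),
                                     spec.cases[0].ed_mesh.faces,
                                     landmarks=spec.cases[0].ed_mesh.landmarks)
print(f"mean-case EDV            : {enclosed_volume(mean_case.ed_mesh):.1f} ml")
print("two planted modes carry essentially all cohort variance, so the")
print("model compresses 40 anatomies into a mean shape plus two weights.")
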