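"""Undo hemodynamic smoothing with a voxelwise FIR encoding model.

BOLD responses lag neural activity by several seconds. Fitting per-feature
FIR filters (delays of 1-4 TRs) with cross-validated ridge regression,
averaging the filter weights, and multiplying them back onto the feature
timecourses reconstructs activity with the lag removed.
"""

import numpy as np

import voxstate as vs
from voxstate.types import FeatureTimecourse

spec = vs.SyntheticSpec(n_trs=900, n_voxels=80, snr=5.0,
                        drift_amplitude=0, seed=4)
design, bold, truth = vs.generate(spec)

features = FeatureTimecourse(values=design.values,
                             feature_names=design.variable_names,
                             tr_seconds=spec.tr_seconds)
fir = vs.build_fir_design(features, delays_trs=[1, 2, 3, 4])
model = vs.fit_encoding(fir, bold, folds=10, seed=0,
                        feature_names=features.feature_names)
deconv = vs.deconvolve(vs.average_fir_weights(model), features, template=bold)


def median_corr(a):
    cs = []
    for v in range(bold.n_voxels):
        if truth.neural[:, v].std() > 0 and a[:, v].std() > 0:
            cs.append(np.corrcoef(a[:, v], truth.neural[:, v])[0, 1])
    return float(np.median(cs))


print(f"median voxel correlation with the planted neural signal:")
print(f"  raw BOLD:     {median_corr(bold.values):.3f}")
print(f"  deconvolved:  {median_corr(deconv.values):.3f}")
print(f"selected ridge penalties span "
      f"[{model.ridge_penalty.min():.3g}, {model.ridge_penalty.max():.3g}]")

print("\nThe deconvolved timecourses track the pre-convolution signal more")
print("closely than the raw BOLD does, so rapid state switches stay")
print("distinguishable in the state space.")
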