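"""Full reconstruction on one phantom realisation, both estimators.

Pipeline: unwrap each echo phase -> average to the B1+ phase (B0 and
chemical-shift terms cancel) -> bilateral filter (parabolic path only) ->
sliding-kernel conductivity estimation -> per-tube statistics.
"""

import numpy as np

from qcmap import (
    AcquisitionContext,
    LabelMask,
    default_three_tube_phantom,
    reconstruct_pair,
    roi_stats,
    simulate,
)

spec = default_three_tube_phantom(seed=1, grid=64, spacing_mm=1.0)
ctx = AcquisitionContext(spacing_mm=spec.spacing_mm)
s_plus, s_minus, truth = simulate(spec, ctx)
mask = LabelMask(truth.labels)

phi, maps = reconstruct_pair(s_plus, s_minus, labels=mask, ctx=ctx, estimator="both")
print(f"estimated B1+ phase range: [{phi.values.min():.3f}, {phi.values.max():.3f}] rad")

# the periodic forward model fixes the gauge: estimators see sigma - mean(sigma)
gauge = truth.sigma.mean()
for name, cmap in maps.items():
    print(f"\n{name} estimator (values are sigma - {gauge:.3f} S/m volume mean):")
    for stat in roi_stats(cmap, mask):
        true_c = truth.sigma_contrast[truth.labels == stat.label].mean()
        print(f"  tube {stat.label}: {stat.mean:+.3f} +/- {stat.std:.3f} S/m "
              f"over {stat.n_valid} voxels (truth {true_c:+.3f})")
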