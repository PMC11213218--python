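"""Conventional nested model selection on a phantom study.

Fits the three nested tracer-kinetic models to every voxel and picks the
simplest adequate one per voxel with sequential partial F-tests at 95%
confidence, then compares the label map with the simulation ground truth.
"""

import numpy as np

from dcepnms import PhantomSpec, fit_volume, fit_voxel, simulate_study

study = simulate_study(PhantomSpec(shape=(24, 24, 1), tumor_radius=7.0,
                                   core_radius=4.0, noise_sd=0.05, seed=3))

# one voxel from the tumor rim, in detail
ix, iy, iz = np.argwhere(study.labels == 3)[0]
vox = fit_voxel(study.delta_r1[ix, iy, iz], study.aif, study.grid)
print(f"rim voxel ({ix},{iy},{iz}): selected Model {vox.label}")
p3 = vox.fits[2].params
print(f"  Model-3 fit: vp={p3.vp:.4f}  Ktrans={p3.ktrans:.3f}/min  "
      f"kep={p3.kep:.3f}/min  (truth vp={study.vp_true[ix, iy, iz]:.4f}, "
      f"Ktrans={study.ktrans_true[ix, iy, iz]:.3f}, "
      f"kep={study.kep_true[ix, iy, iz]:.3f})")

res = fit_volume(study.delta_r1, study.brain_mask, study.aif, study.grid)
agree = (res.label_map == study.labels).mean()
print(f"whole volume: label agreement with ground truth {100 * agree:.1f}%")
for m in (1, 2, 3):
    n = int((res.label_map == m).sum())
    print(f"  labeled Model {m}: {n} voxels (truth {(study.labels == m).sum()})")
# Disagreements concentrate at region boundaries where the noise hides the
# extra model term; the F-test keeps the simpler model there by design.
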