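# phimo

Physics-informed, self-supervised motion correction for T2* quantification
from multi-echo gradient-echo (GRE) brain MRI.

## The problem

T2*-weighted GRE imaging is highly sensitive to magnetic field (B0)
inhomogeneities. When a subject moves during a scan, the head's position
relative to the field changes, the local field shifts, and the affected
k-space lines carry signal whose echo-wise decay is no longer
mono-exponential — corrupting the voxel-wise T2* fit that quantitative
techniques (e.g. oxygen-metabolism mapping) depend on. The standard remedy
reacquires the k-space center redundantly, which lengthens the scan by
over 40%.

This package implements the alternative: **detect** the motion-corrupted
phase-encode (PE) lines retrospectively, scan-specifically and without any
labels, and **reconstruct** the down-weighted data with a data-consistent
unrolled scheme.

## The method

Per voxel the echo train obeys `s_n = s0 · exp(−TE_n / T2*)`. Motion-induced
B0 changes perturb exactly this structure, so the deviation from it is a
training signal. The physics-informed loss is

    L_phys = 1 − corr(s_rec, s_fit)

— one minus the empirical correlation across echoes between the
reconstructed magnitudes and their own differentiable log-linear
mono-exponential fit, averaged over brain voxels. One continuous exclusion
mask Ω per interleaved slice package ("Even/Odd") is optimized with Adam
through the frozen unrolled reconstruction by minimizing

    L_phys + λ_reg [ (1 − mean Ω) + λ_center (1 − mean Ω_central-10) ],

with λ_reg = 0.005, λ_center = 2, lr = 0.01, 100 epochs, batches of 20
slices drawn from the most inferior eight slices with moderate
susceptibility gradients (< 80 μT/m). The mask multiplies the measured
k-space and the data-consistency weights; the **KeepCenter** rule forces
the 2×2 block around the k-space center to stay on, preserving mean image
intensity even when central lines are excluded. The whole chain — k-space
weighting, unrolled reconstruction, magnitude, fit, correlation — is
differentiated with hand-written vector-Jacobian products in numpy (no
autodiff framework), validated against finite differences in the tests.

Everything runs on a deterministic digital brain phantom with a rigid
motion + B0-perturbation simulator, so the pipeline is testable end to end
on one CPU; ORBA (bootstrap-aggregated reconstruction) and HR/QR
(redundant center reacquisition) baselines and the full line-detection and
map-quality metrics are included.

## Worked example

```python
import numpy as np
from phimo import (
    DetectConfig, ExclusionMask, UnrolledConfig, DecayStack,
    fit_monoexp, mask_metrics, masks_for_all_slices,
    optimize_exclusion_masks, reconstruct_with_masks,
    standard_corruption_scenario,
)

# 92x64, 8-slice, 12-echo phantom with a single 6-mm motion event
# corrupting PE lines 15..26 of both slice packages
ph, scheme, curve, kspace, ref = standard_corruption_scenario(seed=0)

cfg = UnrolledConfig()                       # identity denoiser, 5 DC iterations
mask_even, mask_odd, history = optimize_exclusion_masks(
    kspace, ph.csm, cfg, ph.brain_mask, ph.sg_map, DetectConfig(seed=0))

acc = [mask_metrics(mask_even, ref["odd"])["accuracy"],
       mask_metrics(mask_odd, ref["even"])["accuracy"]]
print("loss", round(history[0], 4), "->", round(history[-1], 4))
print("detection accuracy per package:", acc)

def t2_mae(images):
    maps, _ = fit_monoexp(DecayStack(np.abs(images), ph.te_ms), ph.brain_mask)
    keep = ph.brain_mask & (ph.sg_map < 100)
    return np.mean(np.abs(maps.t2star_ms - ph.t2star_map)[keep])

naive = reconstruct_with_masks(kspace, ExclusionMask(np.ones(ph.pe_size)), ph.csm, cfg)
corrected = reconstruct_with_masks(
    kspace, masks_for_all_slices(mask_even, mask_odd, ph.n_slices), ph.csm, cfg)
print("T2* MAE uncorrected:", round(t2_mae(naive), 2), "ms")
print("T2* MAE corrected:  ", round(t2_mae(corrected), 2), "ms")
```

Output (about 90 s on one CPU):

```
loss 0.088 -> 0.0039
detection accuracy per package: [1.0, 1.0]
T2* MAE uncorrected: 17.69 ms
T2* MAE corrected:   3.44 ms
```

The optimizer pushes the weights of the twelve truly corrupted lines below
the 0.5 threshold while the weights of all clean lines stay at ~1
(accuracy 1.0), and excluding those lines cuts the T2* error of the
reconstruction almost five-fold relative to the uncorrected map.

The same pipeline is scriptable from the shell:

```bash
phimo phantom  --seed 0 --out ph.h5
phimo simulate --input ph.h5 --n-events 1 --amplitude-mm 6 --out sim.h5
phimo detect   --input sim.h5 --out masks.csv
phimo reconstruct --input sim.h5 --masks masks.csv --out rec.h5
phimo fit      --input rec.h5 --out t2star.nii.gz
phimo evaluate --t2star t2star.nii.gz --reference ph.h5 \
               --masks masks.csv --ref-masks sim.refmask.csv --out metrics.json
```

Every command writes a JSON manifest (resolved config, seed, versions,
input hashes) next to its outputs.

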