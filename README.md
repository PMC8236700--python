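# cvrkit

Cerebrovascular reactivity (CVR) mapping from BOLD fMRI acquired during a
step CO2 stimulus, with model-based response-speed estimation and partial
volume correction. It is written for neuroimaging researchers who run
hypercapnia CVR protocols (e.g. sequential-gas-delivery step targeting of
end-tidal CO2) and want tissue-specific, quantitative CVR metrics rather
than mixed-voxel averages.

## What it computes

Per voxel, from a 4-D BOLD series `S(t)` and the end-tidal CO2 trace
`P(t)` (mmHg), three nested models are fit, each with a linear drift
`α·t` and baseline `b`:

- **mCVR** — the slope of `S(t) = mCVR·P(t) + α·t + b + ε`, in
  %BOLD/mmHg: the standard magnitude of reactivity.
- **ssCVR and τ** — `S(t) = ssCVR·{P ⊛ e^(−t/τ)/C}(t) + α·t + b + ε`,
  where the exponential kernel is truncated at `5τ` and `C` normalizes it
  to unit area. τ (grid 2–100 s, step 2 s, chosen by maximal correlation)
  is the speed of the vasodilatory response; ssCVR is the steady-state
  amplitude corrected for that speed.
- **TD** — the convolved regressor is advanced 2 s and then delayed by
  TD ∈ [0, 5] s (step 0.2 s) to the point of maximal correlation,
  approximating blood arrival time.

The standard and convolution models are compared voxel-wise with
`BIC = n·ln(SSE/n) + (p+1)·ln(n)` (p = 2 vs 3). Metric maps are then
resampled to the 1 mm anatomical grid either by nearest neighbor (NN) or
by **partial volume correction (PVC)**: within a 9 mm neighborhood (81
voxels at 3.5 mm), each voxel's value is modeled as
`I_n = g_n·I_g + w_n·I_w + c_n·I_c + ε_n` with tissue fractions from the
anatomical segmentation, solved by least-absolute-deviations regression,
and the tissue-specific solutions are assigned by majority class.
Summaries are reported over GM per vascular territory (CER/ACA/MCA/PCA)
and over WM, after excluding voxels with mCVR > 0.7 %/mmHg (sinovenous)
and, for τ averages, voxels with negative ssCVR (steal physiology).

A digital phantom (`cvrkit.phantom`) generates the whole input set —
tissue probability maps with a realistically thin 2.5 mm cortical
ribbon, territory labels, the PETCO2 trace, and a low-resolution BOLD
series with known per-tissue ground truth — so every stage is testable
without scanner data.

## Worked example

```python
import numpy as np
from cvrkit import (PhantomSpec, generate_geometry, generate_bold,
                    fit_volume, apply_pvc, nn_resample, make_tissue_masks)

spec = PhantomSpec(seed=0)                      # 20x20x12 voxels, 150 frames
geometry = generate_geometry(spec)
phantom = generate_bold(geometry, spec)
fit = fit_volume(phantom.series, phantom.petco2_frames)

masks = make_tissue_masks(geometry.probs, threshold=0.7)
nn = nn_resample(fit["sscvr"], geometry.lowres_grid, geometry.highres_grid)
pvc = apply_pvc(fit["sscvr"], phantom.fractions, phantom.series.brain_mask,
                geometry.lowres_grid, geometry.probs, geometry.highres_grid).highres
for tissue, truth in (("gm", 0.30), ("wm", 0.13)):
    m = masks[tissue]
    print(f"{tissue.upper()} ssCVR  truth {truth:.2f}   "
          f"uncorrected {np.nanmean(nn[m]):.3f}   corrected {np.nanmean(pvc[m]):.3f}")
valid = fit.valid
print(f"mean BIC  standard {np.nanmean(fit['bic_standard'][valid]):.1f}   "
      f"convolution {np.nanmean(fit['bic_convolution'][valid]):.1f}")
```

prints

```
GM ssCVR  truth 0.30   uncorrected 0.203   corrected 0.291
WM ssCVR  truth 0.13   uncorrected 0.156   corrected 0.139
mean BIC  standard 27.5   convolution 16.0
```

Read: mixed 3.5 mm voxels bias GM ssCVR down (0.203 vs true 0.30) and WM
up (0.156 vs 0.13); partial volume correction recovers both to within a
few percent under 1% noise. The lower BIC confirms that modeling the
response speed is worth its extra parameter.

The same pipeline is available from the shell:

```bash
cvrkit simulate --seed 0 --out run/          # phantom inputs
cvrkit fit --bold run/bold.nii.gz --petco2 run/petco2.tsv \
           --mask run/mask.nii.gz --out run/ # mcvr/sscvr/tau/td maps
cvrkit pvc --metric run/sscvr.nii.gz --gm-prob run/gm_prob.nii.gz \
           --wm-prob run/wm_prob.nii.gz --csf-prob run/csf_prob.nii.gz \
           --mask run/mask.nii.gz --radius 9 --out run/sscvr_pvc.nii.gz
cvrkit run --seed 0 --out run/               # everything, plus table.tsv
```

See `docs/methods.md` for the model details, discretization choices and
known limitations.

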