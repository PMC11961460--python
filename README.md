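# pkdvol

Cyst and kidney volumetrics for **atypical (Mayo Class 2) autosomal
dominant polycystic kidney disease (ADPKD)**.

About 5–10 % of ADPKD patients show atypical imaging — unilateral,
lopsided, asymmetric or atrophic cystic involvement — for which the usual
prognostic tool (height-adjusted total kidney volume, htTKV) loses its
predictive value. Characterizing these patients requires separating the
kidney into its cystic and residual-tissue compartments. `pkdvol` is aimed
at imaging researchers and nephrology groups who need exactly that:

* **Automated total-cyst-volume (TCV) segmentation** on T2-weighted MRI
  inside radiologist-drawn kidney masks, using the *progressive weighted
  curve* (PWC) of the kidney gray-level histogram,

      PWC(k) = Σ_{i=0..k} wᵢxᵢ / Σ_{i=0..k} wᵢ,

  where `wᵢ` is the histogram count of gray level `i` and `xᵢ` its gray
  value. Inflection points of the curve are candidate thresholds; each is
  scored from the objects it produces (slice-wise circularity, internal
  intensity SD, mean border gradient) and the best-scoring threshold
  defines the cyst mask.
* **Volumetrics and classification**: TKV, htTKV (mL/m), TCV, residual
  tissue volume RTV = TKV − TCV, the RTV/TCV, RTV/TKV and TCV/TKV ratios,
  nephromegaly (TKV > 750 mL), and the Mayo imaging class (1A–1E from the
  htTKV growth model, 2A/2B from the atypical pattern).
* **Cohort statistics** for a packaged 12-patient atypical-ADPKD cohort:
  descriptive summaries, Class 2A vs 2B contrasts, and eGFR-slope
  progressor analysis.
* **Synthetic phantoms** with known ground truth (ellipsoidal kidneys,
  spherical hyperintense cysts, partial-volume blur, Gaussian/Rician
  noise, atypical spatial patterns), so the segmentation can be validated
  quantitatively without patient data.

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

```python
from pkdvol import (PhantomSpec, generate_phantom, segment_cysts,
                    compute_tkv, derive_volumetrics)

vol, truth = generate_phantom(PhantomSpec(pattern="lopsided", seed=17))
res = segment_cysts(vol, truth.kidney_mask)
tkv, per_kidney = compute_tkv(truth.kidney_mask, vol.spacing)
v = derive_volumetrics(tkv, res.tcv_ml)
print(f"true TCV {truth.true_tcv:.1f} mL, estimated {res.tcv_ml:.1f} mL "
      f"(threshold {res.chosen_level:.1f})")
print(f"TKV {v.tkv:.1f} mL  RTV {v.rtv:.1f} mL  TCV% {v.tcv_percent:.1f}  "
      f"nephromegaly {v.nephromegaly}")
```

prints

```
true TCV 44.7 mL, estimated 41.6 mL (threshold 153.3)
TKV 579.1 mL  RTV 537.5 mL  TCV% 7.2  nephromegaly False
```

The phantom has 44.7 mL of ground-truth cyst volume concentrated in one
kidney; the PWC machinery picks gray level 153 (between the parenchyma
and cyst intensity modes) and recovers the cyst volume to within 7 %.
Subtracting TCV from the 579 mL total kidney volume leaves the residual
(functioning) tissue volume.

The same stages are available from the shell:

```sh
pkdvol simulate --pattern lopsided --seed 17 --out phantom/
pkdvol segment --image phantom/phantom.nii.gz --mask phantom/kidney_mask.nii.gz --out seg/
pkdvol volumetrics --image phantom/phantom.nii.gz --mask phantom/kidney_mask.nii.gz \
       --height 1.70 --age 52 --pattern lopsided
pkdvol cohort-summary --cohort fixture --total-mri 124 --out report.json
pkdvol export-fixture --out cohort.csv
```

`cohort-summary` recomputes the packaged cohort's published statistics:
overall mean htTKV 1893.3 ± 1871.6 mL/m and TCV 1425.9 ± 1632.1 mL/m,
the Class 2A vs 2B contrasts (e.g. htTKV 2232.2 vs 198.5 mL/m,
significant; RTV 528.6 vs 161.0 mL/m, not significant), and the
four-progressor eGFR-slope analysis (median slope −0.89 (−2.03–0.93)
mL/min/1.73 m²/year).

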