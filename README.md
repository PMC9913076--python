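# texagg — robustness of PET texture-feature aggregation methods

Radiomic texture features from ¹⁸F-FDG PET tumor volumes are computed from
grey-level matrices (co-occurrence, run-length, size-zone, distance-zone,
neighbourhood grey-tone difference, neighbourhood dependence) that can be
*aggregated* in several ways: per-slice/per-direction matrices can have their
features averaged, or the count matrices can be merged first, at the 2D,
2.5D or 3D level. For GLCM/GLRLM there are six such methods
(`2D_averaged`, `2D_s_merged`, `2.5D_d_merged`, `2.5D_merged`,
`3D_averaged`, `3D_merged`), for the other four families three
(`2D`, `2.5D`, `3D`). The choice changes feature values, and hence any model
built on them.

`texagg` measures this effect end to end. It provides

- a texture engine: the six matrix families, the full aggregation algebra,
  and the 95 standard features (25 GLCM, 16 GLRLM, 16 GLSZM, 16 GLDZM,
  5 NGTDM, 17 NGLDM), all oracle-tested against independent brute-force
  implementations;
- the PET preprocessing chain: body-weight SUV, tricubic resampling,
  observer-mask intersection / Dice, Van Cittert partial-volume correction
  (Gaussian PSF, FWHM in mm), and fixed-bin-number (FBN) discretization;
- the robustness analysis: pairwise and overall one-way ICC
  `(BMS − WMS)/(BMS + WMS)` with poor/moderate/good/excellent categories at
  0.5/0.75/0.9, category distributions over FBN ∈ {8,…,128} and PVC FWHM ∈
  {1,…,5} sweeps, and absolute Spearman correlation of robust features with
  metabolic tumor volume (MATV);
- a calibrated synthetic phantom cohort (lognormal lesion volumes matched to
  MATV 50.9 ± 86.4 mL, peak uptake matched to SUVmax 15.4 ± 7.77, paired
  observer masks at median Dice 0.87) so the whole study runs without any
  patient data.

It is aimed at radiomics researchers who need to know which features can be
pooled across aggregation conventions and which cannot.

## Worked example

```python
from texagg import fixture_grid, aggregate
from texagg.features import glcm_features

voi, _ = fixture_grid("two-slice-constant")   # slice A all grey 1, slice B all grey 2
avg    = aggregate(voi, "GLCM", "2D_averaged",  glcm_features)["joint_entropy"]
merged = aggregate(voi, "GLCM", "2.5D_merged",  glcm_features)["joint_entropy"]
print(avg, merged)
```

prints `0.0 1.0`: each slice is constant, so averaging per-slice features
sees zero entropy, while the merged matrix holds two equal-mass grey levels
— one bit. That is the aggregation effect in miniature.

At cohort scale (16 phantom patients, FBN 128), the per-pair median ICC of
the 25 GLCM features comes out as

```
2D_averaged-2D_s_merged      0.964
2.5D_d_merged-2.5D_merged    1.000
3D_averaged-3D_merged        0.988
2D_averaged-3D_averaged     -0.443
2D_s_merged-3D_merged       -0.551
```

— changing averaged↔merged *within* a dimension barely matters, changing the
dimension itself destroys agreement. The numbered drivers under `analysis/`
run the full study (128 patients, 10 configurations) and write all tables
under `results/`:

```sh
python analysis/01_simulate_cohort.py     # cohorts + calibration summary
python analysis/02_extract_features.py    # 408 feature-method series / patient / config
python analysis/03_pairwise_icc.py        # 9 GLCM/GLRLM pairs, 3 zone-family pairs
python analysis/04_fbn_pvc_sweep.py       # overall-ICC category percentages
python analysis/05_matv_correlation.py    # |Spearman| of robust features vs MATV
```

The same pipeline is scriptable through the `texagg` CLI
(`simulate` / `extract` / `pairwise` / `sweep` / `matv` / `study`) for
external NIfTI cohorts.

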