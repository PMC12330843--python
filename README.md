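# emct2

Dictionary-based quantitative T2/R2 mapping for 2D multi-echo spin-echo
(MESE) MRI at ultra-high field.

At 7 T, transmit-field (B1+) inhomogeneity makes the MESE echo train a
mixture of spin and stimulated echoes, and sub-millimeter voxels push the
magnitude signal toward the non-central-chi noise floor — both of which bias
naive exponential fits of R2 = 1/T2. `emct2` addresses this with the
echo-modulation-curve (EMC) approach plus explicit noise handling:

1. **Bloch simulation** of the sequence (hard-pulse propagation of an
   isochromat ensemble across the slice profile) builds a dictionary of
   normalized signal curves θ(T2, B1+) at fixed T1.
2. **Noise estimation**: per-slice effective nc-chi parameters
   (n_eff, σ_eff) fitted to background voxels; the SNR map
   max_TE S / (σ_eff √2 Γ(n_eff+½)/Γ(n_eff)) excludes voxels below SNR 5.
3. **Patch-PCA denoising** (3×3 patches × all echoes, fixed rank P = 2) with
   magnitude bias removal
   S_corr = √max(Σ_j w(i,j) Ŝ²(j,t) − 2 n_eff σ_eff², 0).
4. **AFI B1+ mapping** B1 = (100/α_set)·arccos((rν−1)/(ν−r)) with analytic
   error propagation ζ = σ_B1/B1, blended with the smoothed EMC estimate:
   B1_REG = η B1_AFI + (1−η) B1_EMC, η = 1 − min(ζ/ζ_th, 1).
5. **Regularized grid search** per voxel:
   argmin over the dictionary of ‖ŝ − θ̂‖₂ + λ|B1_REG − B1|, yielding R2/T2,
   B1+, S0 = ρ_S/ρ_θ, residual and total-cost maps.

A fully synthetic 24-vial relaxometry phantom (known per-voxel R2, smooth
B1+ field, seeded nc-chi noise) makes every stage testable end-to-end with
no external data. See `docs/methods.md` for the model details, assumptions,
and limitations.

Intended users: quantitative-MRI researchers prototyping or validating
MESE relaxometry pipelines. Inputs are NIfTI volumes with BIDS-style JSON
sidecars (EchoTime in seconds); dictionaries are HDF5.

## Worked example

Render a synthetic phantom study, simulate a reduced dictionary, and run
the full pipeline:

```sh
emct2 phantom --size 64 --slices 3 --snr 15 --seed 1 --out demo/ph
emct2 sim-dict --mode ideal --t2-segments 8:60:0.5,60:120:4,120:240:10 \
               --b1-range 0.5:1.25:0.01 --out demo/dict.h5
emct2 run --mese demo/ph_mese.nii.gz --dict demo/dict.h5 \
          --afi-s1 demo/ph_afi_s1.nii.gz --afi-s2 demo/ph_afi_s2.nii.gz \
          --truth-labels demo/ph_labels.nii.gz --truth-r2 demo/ph_r2.nii.gz \
          --out demo/out
```

which prints

```
wrote demo/ph_* (sigma = 0.02169)
grid: 132 T2 x 76 B1 = 10032 entries
wrote demo/dict.h5 (fingerprint 0b23c666fc1baf49)
done; excluded fraction 0.7783; maps in demo/out
```

The excluded fraction counts mostly air voxels (SNR < 5 by construction).
`demo/out/` holds `r2_map.nii.gz`, `t2_map.nii.gz`, `b1_map.nii.gz`,
`s0_map.nii.gz`, residual/total-cost maps, the exclusion mask, and a
`qc.json` report. Because truth labels were supplied, the QC report scores
per-vial recovery; the first rows at this seed:

```
vial  n   R2_true  R2_est   err%
   1   96    43.53   43.99  +1.0
   2  111    54.01   55.10  +2.0
   3   96    75.49   78.04  +3.4
   4  111    97.49   99.25  +1.8
```

i.e., vial-mean R2 (in 1/s) recovered within a few percent of ground truth
across the phantom (max 4.1% at this seed), including the fast-decaying
vials whose raw (uncorrected) fits would be biased low by 15% and more.

The same stages are importable from Python (`emct2.dictionary`,
`emct2.noise`, `emct2.denoise`, `emct2.b1map`, `emct2.match`,
`emct2.phantom`, `emct2.pipeline`); `emct2.experiments` bundles the two
study-scale experiments used in validation.

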