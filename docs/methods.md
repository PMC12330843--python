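# Methods

`emct2` estimates the transverse relaxation rate R2 = 1/T2 from 2D multi-echo
spin-echo (MESE) magnitude data at ultra-high field, where two effects break
the textbook mono-exponential decay model: transmit-field (B1+)
inhomogeneity turns the refocusing train into a mixture of spin and
stimulated echoes, and the small voxels of high-resolution scans push the
magnitude signal toward the non-central-chi noise floor. The package couples
a Bloch-simulated signal dictionary with noise-bias-corrected inputs and a
B1+-regularized grid search.

## Signal model and simulator

The magnetization state is the augmented 4-vector (Mx, My, Mz, M0); a
sequence is an ordered list of piecewise-constant intervals (hard-pulse
approximation). Each interval applies a rotation about the effective field
— RF at its phase plus the slice-gradient off-resonance γ·Gz·z — followed by
relaxation (transverse decay exp(−Δt·R2), longitudinal recovery toward M0).
This rotate-then-relax splitting is a documented convention; the EPG test
oracle uses the same one, so the two agree to machine precision for
instantaneous pulses. Only slice gradients are modeled: B0 inhomogeneity,
diffusion, eddy currents, magnetization transfer, and in-plane gradients are
out of scope, as is finite-TR saturation (TR is protocol metadata only).

The echo-modulation curve (EMC) is |Σ_k Mxy| over an isochromat ensemble
spanning the slab (default 1000 isochromats over 10 mm for a 0.7 mm slice),
normalized by the ensemble size, read at echo centers TE_k = k·esp.

Two timeline modes exist:

* **shaped** — the production mode: Hann-windowed sinc pulses (time-bandwidth
  2.7; 2.56 ms excitation, 3.0 ms refocusing), discretized into 256 hard
  pulse steps under their slice-select gradients, with 1.35 ms spoiler lobes
  of 55 mT·ms/m straddling each refocusing pulse. Vendor pulse shapes are
  not public; the shapes are configurable inputs and results that depend on
  slice-profile detail will differ from any particular scanner's dictionary
  at the few-percent level. The excitation slice-rephase area is folded into
  the first spoiler lobe (both are z-gradients). This is both physical
  (sequences merge adjacent lobes) and necessary: with the default timing a
  separate rephase lobe would not fit inside esp/2 = 4.5 ms.
* **ideal** — instantaneous pulses, no slice selection, and "exact" crushers
  that dephase the ensemble by whole cycles (isochromat i receives z-phase
  2π·i/N per crusher). With N much larger than the highest populated
  dephasing order, the ensemble sum equals the extended-phase-graph F0
  coherence exactly, which is what makes the EPG oracle a machine-precision
  cross-check and the 180° limit exactly mono-exponential.

Units: ms, 1/ms, mT/m, mm internally; γ/2π = 42.577 MHz/T. CPMG phase
convention: excitation about x, refocusing about y.

## Dictionary

Curves are simulated on a (T2, B1+) lattice at fixed T1 = 1500 ms (T1 >> T2
in brain at 7 T; its residual influence on the echo modulation is small).
The production grid is T2 = 1–60 ms in 0.25 ms steps, 60–120 ms in 2 ms
steps, 120–600 ms in 10 ms steps (inclusive endpoints, deduplicated:
315 values) × B1 = 0.20–1.60 in 0.01 steps (141 values) = 44 415 entries.
Rows are L2-normalized along the echo dimension; the pre-normalization norms
ρ_θ are stored so the matcher can recover the amplitude S0. Storage is one
HDF5 container (float32 curves, float64 grids/norms) with a JSON attribute
block and a protocol+simulator fingerprint that is checked on load. Row
order is T2-major. Desk-scale studies in the tests use reduced grids
(documented in `emct2.experiments`) so a full study runs in tens of seconds
on one CPU.

## Noise model

Root-sum-of-squares combination of n Gaussian-noise channels gives nc-chi
magnitudes; correlations and coil weighting are absorbed into effective real
parameters (n_eff, σ_eff), estimated per slice and treated as stationary
across it. The density is evaluated in the log domain (scaled Bessel
functions); the sampler draws 2n Gaussians and is restricted to integer n.
Estimation pools the echo samples of background voxels found by an iterative
consistency test: start from the lowest quartile of the across-echo mean
image, fit (n_eff, σ_eff) by moments (E[x²] = 2nσ², Var(x²) = 4nσ⁴),
re-threshold at the 4σ upper bound of the signal-free across-echo mean, and
repeat until stable. A user-supplied background mask overrides the search.
A fitted n_eff at the clamp (64) is treated as "no plausible background"
— a constant bright image is formally consistent with a very-high-n nc-chi
law, so the estimator refuses rather than returns nonsense. The SNR map is
max-over-echoes divided by the slice noise-floor mean σ√2·Γ(n+½)/Γ(n);
voxels with SNR strictly below 5 are excluded from fitting (below that line
the magnitude bias is not reliably correctable; the boundary value 5 is
retained).

## Denoising and bias correction

Per slice, all l×l patches (stride 1, l = ⌈√ETL⌉ = 3 for 7 echoes, so
min(l², ETL) = ETL) are filtered by keeping the top P = 2 singular
components after subtracting the per-echo spatial mean. The
Marchenko–Pastur automatic rank cutoff is deliberately not used — it is not
valid for magnitude data. Patch estimates are recombined per voxel with
uniform normalized weights (an inverse-rank alternative sits behind a
config switch); the magnitude offset is then removed on the squared signal,
S_corr = sqrt(max(Σ w·Ŝ² − 2·n_eff·σ_eff², 0)), with clipped voxels flagged.

Two properties of this estimator are worth knowing. The PCA step alone does
not touch the noise *mean* bias — only the subtraction does. And because
the subtraction uses the full-noise term while the filtered values retain
only part of the noise variance, a residual floor of roughly a quarter of
the raw noise-floor mean survives in signal-free regions at the default
patch size (it falls below 20% at l = 5), and constant-signal inputs are
recovered slightly conservatively; at SNR ≥ 5 the corrected mean square is
within 2% of S².

## B1+ mapping and regularization

AFI inverts r = S2/S1 of two interleaved steady-state acquisitions
(TR1/TR2 = 16/160 ms, nominal 60°): B1 = (100/α_set)·arccos((rν−1)/(ν−r)),
ν = TR2/TR1. First-order propagation of the image noise through r with the
exact analytic derivative of the arccos map yields σ_B1 and the relative
error ζ = σ_B1/B1 (validated against finite differences; a printed
closed-form expansion of this propagation is typographically corrupt, so
the derivative form is authoritative). ζ grows as r → 1, i.e., exactly in
low-B1 regions where AFI also underestimates the field, so the regularizer
blends AFI with the dictionary-matching (EMC) B1 estimate:
η = 1 − min(ζ/ζ_th, 1), B1_REG = η·B1_AFI + (1−η)·B1_EMC, with ζ_th = 0.125
(fractional scale — 12.5% relative error; the percent reading of the same
threshold would reject essentially every voxel). B1_EMC comes from a first
matching pass without regularization, Gaussian-smoothed (σ = 5 voxels; B1
varies slowly). ζ is carried per voxel; invalid arccos domains get ζ = ∞
(maximal distrust). S1/S2 correlations and error in ν are neglected.

## Matching

Voxel curves are L2-normalized (norm ρ_S kept); the grid search minimizes
‖ŝ − θ̂‖₂ + λ·|B1_REG − B1_row| per voxel, with the penalty on the B1
fraction (per-voxel scalar reading — the only one compatible with voxel-wise
argmin). λ defaults to 1.0: a 1% B1 deviation costs 0.01, comparable to the
residual term at moderate SNR; λ = 0 is the pure EMC mode used for pass 1,
and λ → ∞ clamps B1 to the nearest grid value. S0 = ρ_S/ρ_θ at the winning
row. Ties resolve deterministically to the smaller T2, then the B1 nearest
the regularizer. Evaluation is batched (configurable batch size; results
are batch-size independent). Excluded voxels carry NaN plus an explicit
mask. R2 maps are in 1/s (= 1000/T2[ms]); B1 maps in percent externally,
fractions internally.

## Synthetic phantom

The generator emulates a cylindrical 24-vial MnCl2 phantom: 12 R2 levels
{4.49 … 97.49} s⁻¹ (the 7 T calibration table, whose concentration–R2 pairs
give a zero-intercept relaxivity of 161.4 mM⁻¹s⁻¹ — kept as a stored-data
integrity check), each level in two diametrically opposite vials. The true
vial geometry is not public; the two-ring layout (8 inner + 16 outer vials)
is this package's own synthetic design. The four highest-R2 (weakest
signal) levels sit on the inner ring where the radial-quadratic B1 field
(default 0.55 at the edge to 1.15 at center) is strongest, so that under the
default noise condition they stay above the SNR-5 exclusion line while still
probing the low-SNR regime. Noise is nc-chi with n = 2 (a plausible
effective multi-channel value), σ chosen so the *median* in-vial SNR equals
the requested level (default 15); renders are bit-reproducible from a seed.
The AFI pair uses the ideal-spoiling ratio model (the same relation the
mapping inverts) — sufficient for round-trip and regularization testing,
not a steady-state simulation. What the phantom does **not** emulate:
Gibbs ringing, reconstruction/GRAPPA correlations, spatially varying n_eff,
B0 effects, multi-compartment decay. Passing phantom tests therefore
validate the pipeline's statistical machinery, not acquisition physics.

Desk-scale study sizes (chosen as this package's own defaults): 64×64×3
phantom, reduced dictionary T2 (8–60 by 0.25, 60–120 by 4, 120–240 by
10) ms × B1 (0.50–1.25 by 0.01), ideal-pulse mode. Vial recovery is scored
on labels eroded by one in-plane voxel, mirroring the practice of placing
ROIs inside vials away from partial-volume edges. Under these conditions
the corrected pipeline recovers every level's vial-mean R2 within 5% at
median SNR 15, while raw fits of a noisier render (median SNR 8, emulating
the finest-voxel scan) underestimate R2 of sub-8-SNR vials by well over 10%
on average.

## Numerical choices and degenerate inputs

Grid segment endpoints are inclusive with deduplication (rounded at 1e−6
ms). All-zero voxel curves are flagged and excluded rather than normalized.
arccos arguments are clamped to [−1, 1] with a validity mask. The B1_EMC
smoother uses normalized convolution so NaNs from excluded voxels neither
spread nor bias the field. Timeline construction fails loudly (naming the
violated gap) when pulses plus spoilers cannot fit the echo spacing.

## Known limitations

* Mono-exponential per-voxel decay only; no multi-compartment T2.
* Maximum-likelihood matching under the nc-chi law is intentionally not
  implemented; noise is handled in preprocessing.
* The low-SNR R2 bias of raw fits measured for mid-range T2 (30–50 ms) at
  SNR 5–7 averages ≈ 8%, below the 10–20% range reported for vial studies
  whose fast-decaying samples dominate the bias; the full phantom study
  reproduces the stronger effect.
* Registration/resampling between AFI and MESE grids is the caller's duty;
  inputs are assumed co-registered.
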