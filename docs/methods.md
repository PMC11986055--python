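# Methods

This note records the scientific and numerical choices behind
`fetalmrsim`, in the spirit of a model-description appendix: what is
modeled, what the tunable parameters mean, what the synthetic data do
and do not establish, and where the design was genuinely open.

## Anatomical model

Input is a high-resolution (≈0.5 mm isotropic) T2w-like volume with an
eight-class integer label map (white matter, intra-axial CSF,
cerebellum, extra-axial CSF, cortical GM, deep GM, brainstem, corpus
callosum; 0 = background). For relaxometry the labels are merged into
three classes. The merge of cerebellum (→ GM) and brainstem / corpus
callosum (→ WM) is not dictated by the three-class model itself; the
defaults were chosen for T2w contrast similarity and are configurable
(`merge_to_three_classes(mapping=...)`) and logged. Gestational age is
accepted in 18–40 weeks with a warning outside the 20.0–34.8-week range
the reference cohorts span.

## White matter partial volumes (GHMRF-EM)

The intensity inside the WM mask is modeled as a three-component
Gaussian mixture whose labels carry a Potts-type smoothness prior over
the 6-connected neighborhood, handled with a mean-field approximation:
the E-step multiplies the Gaussian likelihood by
`exp(beta * sum_{j in N6(i)} q_jk)`. Defaults: `mrf_beta = 0.1`, four
bias-field passes, 20.0 mm FWHM smoothing kernel, at most 100 EM
iterations, relative objective tolerance 1e-5.

* **Initialization** is a deterministic quantile split of the masked
  intensities — no random restarts, so fits are exactly reproducible.
* **Bias field** is multiplicative and estimated in the log domain: the
  masked log-residual between observed and reconstructed intensity is
  Gaussian-smoothed (mask-normalized) and accumulated; the field is
  exponentiated, strictly positive, and mean-normalized so the
  intensity scale is preserved. Non-positive masked intensities are
  clamped to the smallest positive masked value (warned). The four
  passes are interleaved every `ceil(em_max_iter / bias_iterations)`
  iterations; if the EM objective converges before all passes have run,
  the remaining passes are pulled forward rather than skipped, so a
  biased image is never returned uncorrected.
* **Objective**: the reported trace is `sum_i logsumexp_k(log N_ik +
  beta * S_ik)`. For `beta = 0` and no bias interleaving this is the
  exact EM log-likelihood and increases monotonically; with the
  mean-field term (computed from the previous iteration's
  responsibilities) and bias updates it may decrease by up to ~1e-4
  relative per step, which the tests bound explicitly.
* **Class ordering**: components are relabeled by descending mean so
  that "hydrated" is the brightest and "fibers" the darkest T2w class;
  ties within 1e-9 break by input index with a warning.

The acceptance check for this stage is parameter recovery on simulated
spatially coherent mixtures (means within 5 %, mean membership error
≤ 0.1), not agreement with any specific external segmentation tool.

## Maturation model

Reward maps and the sigmoid are evaluated exactly as stated in the
README. Two points were genuinely open:

* **The scalar fed to the sigmoid.** The sigmoid is neutral at 0
  (`f(0) = 1`) while the reward maps are neutral at 1. We pass the
  signed deviation `w = (w+ - 1) - (1 - w-)`, so neutral voxels are
  unmodified and the two maps push T1/T2 in opposite directions. Any
  convention mapping neutral rewards to 0 would differ only by an
  affine reparametrization of `w`.
* **The sigma_WM table.** Normative per-GA WM intensity spreads are not
  shipped; the schedule is built from a user-supplied `(GA, sigma)`
  table (CSV) or, by default, from spreads measured on the package's own
  synthetic phantoms — explicitly labeled non-authoritative. When the
  recursion would drive `alpha <= 0` (sigma ratio ≥ 2) the value is
  clamped to 1e-3 with a warning, keeping `f` well defined and
  near-identity. The PCHIP interpolator covers 20.0–38.0 weeks; values
  outside are clamped to the boundary (warned).

Per-subject relaxometry sampling mimics inclusive integer-uniform draws
(spreadsheet RANDBETWEEN semantics). When the drawn T2 equals its
reference, the T1 perturbation is zero (the rule is stated only for
"smaller"/"larger"). Proton-density fractions are not part of the
published tissue table; the defaults GM 0.86, WM 0.77, CSF 1.00 come
from the simulator lineage and are configurable.

## Acquisition model

* **Signal**: extended phase graph over `etl + 1` configuration states,
  CPMG phase convention (excitation 90° ahead of refocusing). The
  implementation reproduces the CPMG closed form at 180° to 1e-10 and
  brute-force isochromat summation at arbitrary flip angles to better
  than 1e-3. Inter-shot saturation is `1 - exp(-(TR - etl*esp)/T1)`;
  HASTE protocols give no TR and are treated as fully relaxed.
* **Line ordering**: linear, with the k-space center at echo
  `round(TEeff / esp)`. Realized TE is therefore quantized to multiples
  of the echo spacing (e.g. a nominal 101 ms at 10 ms spacing realizes
  as 100 ms); protocol conformance is asserted up to that half-spacing
  quantization. Half-Fourier (HASTE) is limited by the echo-train
  length; SS-FSE uses a 55 % sampling percentage. Acceleration skips
  every `accel`-th row outside the fully sampled reference band.
* **Parallel imaging is idealized**: skipped rows are filled with their
  exact simulated values. A single-coil simulation cannot produce
  GRAPPA residuals; the contrast effect of the shorter train is kept.
  Noise (complex Gaussian, per-channel sd from the protocol) is added
  to acquired samples only.
* **Resampling**: slices are ideal boxcar averages over the slice
  thickness; run 2 is shifted by half a pitch along the slice axis; the
  SS-FSE ±1.6 mm FOV shift alternates sign between runs. In-plane
  sampling is nearest-neighbor onto the acquisition grid. Voxelwise EPG
  is evaluated on (T1, T2) pairs quantized to 10/1 ms — a lookup-table
  speedup whose quantization error is far below the noise floor.
* **Reconstruction**: centered orthonormal FFTs (Parseval exact); the
  phase-oversampled band is cropped in image space, then k-space is
  zero-padded to the square reconstruction matrix and the magnitude
  taken (zero-filling convention, no homodyne). The amplitude is
  rescaled by `sqrt(N_recon / N_acq)` so the intensity scale does not
  depend on the zero-fill factor. Annotations are majority votes over
  the contributing slab with ties resolved to the smallest class code.

## Synthetic phantom

The phantom provides *structure*, not anatomy: concentric ellipsoidal
shells (extra-axial CSF, cortical GM rim, WM bulk) with ventricles, deep
GM, corpus callosum, brainstem and cerebellum, so all eight classes
exist at 32³ and above. WM carries concentric intensity bands indexed by
distance to the ventricles (bright germinal-zone band innermost); the
peak-to-peak band contrast defaults to a linear decay from 0.35 at 21
weeks to 0.05 at 38 weeks, emulating the fading multilayer appearance
across maturation. Class mean intensities are ordered CSF > GM > WM on
an arbitrary T2w-like scale; noise is additive Gaussian with sd =
`noise_sd` × WM mean (0.05 by default — Rician character arises later
from magnitude reconstruction). A ventricle-dilation factor emulates a
ventriculomegaly-like lesion and errors out if the ventricles would
leave the WM.

A green test on phantom data establishes that the pipeline's operators
satisfy their contracts (conservation, bounds, determinism, protocol
cardinalities) — it does not establish anatomical realism, cortical
folding, motion robustness, or segmentation transfer to clinical data.

## Mutual information

Joint histogram of min-max-scaled intensities within the mask, 64
equal-width bins by default, base-2 logarithm. The plug-in estimator has
a positive bias of roughly `(B-1)^2 / (2 N ln 2)` bits for B bins and N
voxels; near-zero independence checks therefore use 16 bins at ~1e4
voxels. Contributions are summed in sorted order and the argument order
is canonicalized internally, making `MI(a, b) == MI(b, a)` bit-exact.

## Known limitations

No fetal or maternal motion, coil sensitivities, B0/B1 inhomogeneity, or
super-resolution reconstruction; acceleration and partial Fourier are
idealized as described; the default alpha schedule is phantom-derived;
the phantom's geometry is deliberately schematic.
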