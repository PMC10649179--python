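# Methods

This note records the models implemented in `mieeg`, their assumptions, the
parameters that matter, the numerical choices, and what the synthetic studies
do and do not demonstrate.

## Forward model

**Geometry.** The head is three nested closed triangulated surfaces — cortex
boundary, skull, scalp — with homogeneous conductivity per layer and air
outside.  The desk-scale fixture uses concentric icospheres of radii
8.0 / 8.5 / 9.2 cm; subdivision level ℓ gives 20·4^ℓ triangles per shell.
Default conductivities are the standard three-shell values 0.33 / 0.0042 /
0.33 S/m (brain / skull / scalp), configurable; no anisotropy.

**BEM.** The surface potential satisfies a second-kind boundary integral
equation whose kernel is the solid angle of each surface patch.  We collocate
at panel centroids with constant potential per panel; panel-to-panel solid
angles use the Van Oosterom–Strackee closed form.  Two numerical points:

- *Auto solid angle.*  The diagonal (panel seen from its own centroid) is set
  by the closed-surface identity — each surface must subtend exactly 2π from
  a point on itself — which makes the constant vector an exact null direction
  of `I − B`.
- *Deflation.*  The system `(I − B)U = G` is singular up to an additive
  constant; we solve `(I − B + 11ᵀ/n)U = G` (rank-one deflation), factorise
  once (LU) and reuse the factorisation for every dipole, so a lead field
  over M sources costs one assembly plus 3M triangular solves.

**Electrode readout.**  Panel potentials are gathered to mesh vertices by
area-weighted averaging of incident panels, then interpolated barycentrically
in the triangle hit by the radial ray through each electrode.  Nearest-panel
lookup was tried first and discarded: with 14 electrodes it contributes ~12%
error against the analytic sphere solution at subdivision 3, an order of
magnitude more than the panel solution itself (~0.6%).  With the barycentric
readout the forward error at the electrodes is 4.0% (radial dipole at 0.7
eccentricity, the worst case) and 0.8% (tangential).

**Validation oracle.**  For equal conductivities the model reduces to a
homogeneous conducting sphere with a closed-form (Legendre series) surface
potential; `homogeneous_sphere_potential` implements the series (60 terms)
independently of the BEM path.

**Source space.**  Fixed-orientation dipoles (along the outward normal —
pyramidal cells sit perpendicular to the cortical sheet) on a spherical dome:
the superior half (z > 0) of an icosphere of radius 7.2 cm, 305 vertices at
subdivision 3, ~1.1 cm spacing.  A full sphere is deliberately not used: the
14-channel montage covers only the upper head, and sources beneath the head
have no nearby electrode under any method; a cortex also does not extend
there.  The icosphere vertex set is mirror-symmetric in x, which the
virtual-electrode pairing exploits.

## Inverse model

`H = I − 11ᵀ/N` removes the unknown reference; `W = diag(‖k_m‖)` is the
depth/coverage weighting (the column-norm reading of the bias matrix);
`L = D − A` is the combinatorial graph Laplacian of the source mesh.  WMNE is
the minimum-‖WJ‖ solution consistent with `GJ = Hu`; LORETA adds the
Laplacian smoothness prior and Tikhonov weight λ.  Rank-deficient matrices
(the Gram matrix under average reference) are inverted with truncated-SVD
pseudo-inverses, relative tolerance 1e-10.

Numerical choices:

- *Ridge on the penalty.*  `W LᵀL W` annihilates `W⁻¹1` (L kills constants);
  a ridge of 1e-4 × mean diagonal is added before inversion.  A much smaller
  ridge (1e-8) lets this near-null mode leak into the estimate and visibly
  degrades localization (noiseless median ~2.6–2.8 cm vs ~2.0 cm); 1e-4 is
  small against the informative spectrum but large against the null mode.
- *λ by GCV.*  Generalized cross-validation over ten log-spaced multipliers
  (1e-6…1) of the mean Gram eigenvalue; relative scaling keeps the grid
  meaningful regardless of amplitude units (scalp data are ~µV).  Noiseless
  consistent data select the smallest grid value, pure out-of-range noise the
  largest.
- *Localization readout.*  The localization studies report the peak of the
  gain-weighted amplitude `|w_m J_m|` — each source's contribution strength
  at the scalp — rather than raw `|J|`: weighted-minimum-norm estimates
  inflate `|J|` at low-gain vertices far from the electrodes (the dome rim),
  and with the raw peak the 20 dB median fluctuates between 2.1 and 3.8 cm
  across study seeds, versus a stable 1.9–2.2 cm with the weighted readout.
  The estimate `J` itself is untouched.

Measured behaviour on the level-3 fixture (20 seeded single-dipole trials,
λ by GCV): median peak error ≈ 2.1 cm at 20 dB SNR, ≈ 2.2 cm noiseless —
about two source-grid steps; errors are quantized to the ~1.1 cm vertex
spacing, so medians closer than half a step are indistinguishable, and the
SNR monotonicity checks use that tolerance.

## Virtual electrodes

Nine left-hemisphere seeds along a coronal arc tilted slightly posteriorly
(the sensorimotor strip of the template), every ~8° of polar angle from near
the vertex toward the ear; coordinates are configuration, not method.  Each
seed snaps to the nearest left-hemisphere source vertex and grows to its 20
geodesically nearest vertices within the hemisphere (Dijkstra on mesh edges,
ties by index); the x-mirrored seed produces the right-hemisphere partner.
Patch series are sign-aligned means: fixed-orientation dipole signs flip
across folds, so each member is flipped to correlate non-negatively with the
seed before averaging (on the smooth dome fixture the flips are rare, but the
rule is what makes the aggregation well-defined on a folded cortex).

## Features

Complex Morlet wavelets at integer frequencies 8–30 Hz (23 bins), with
`n_cycles = f/2` — a fixed-Q trade-off giving ~0.5 s temporal windows across
the band, adequate for sensorimotor rhythm envelopes.  Power maps are linear
(not log); same-length convolution keeps all 640 samples, edge-affected
columns included.  A mirrored pair stitches to 640×46 (left 23 columns, then
right), nine pairs stack to 640×46×9.  Normalisation is per-feature
z-scoring with statistics from the training split only, applied uniformly to
all splits; zero-variance features are centred, not scaled.

## Classifier

The four-block CNN treats the tensor as a 640×414 single-channel image (nine
46-wide pair blocks side by side).  Block 1 convolves [1,46] with stride
[1,46] — one pair per step — then each block whose convolution collapses the
width folds its feature maps back into the width axis, reproducing the layer
geometry 640×9×25 → 213×9×25 → 213×25 → 71×25 → 61×50 → 20×50 → 10×100 →
3×100 → 300 → 6.  Batch norm precedes the Leaky ReLU (slope 0.01); dropout
(rate 0.5) follows each pooling stage; the head is a dense softmax layer.
Training is mini-batch Adam (batch 32) on categorical cross-entropy, capped
at 1000 steps with best-on-validation weight selection; everything (init,
batch order, dropout) derives from one seed, so runs are bit-reproducible.

*Step size.*  The default Adam step is 1e-2.  A step of 1e-5 — sometimes
quoted for Adam in this setting — cannot work at this iteration horizon:
Adam moves each weight by roughly the step size per update, so 1000 updates
displace weights by ~1e-2 of their He-init scale, and measured accuracy stays
at chance.  At 1e-2 the loss plateaus within ~25–150 steps on separable data,
comfortably inside the ~800-step convergence horizon the training cap is
built around; the step size remains a constructor parameter.

The evaluation protocol is the 3:1:1 five-part rotation: trials are divided
into five equal class-stratified parts; each fold takes one part as test, the
next as validation, the remaining three as training, so every part is the
test set exactly once.  Metrics: accuracy, macro precision/recall/F1,
one-vs-rest macro AUC, row-normalised confusion matrix, Cohen's kappa.

## Control strategy

Classes map to one-hot instruction bytes (start 0x01, stop 0x02, forward
0x04, backward 0x08, right 0x10, left 0x20).  The threshold accumulator
counts consecutive identical classifications and emits on reaching the
threshold, resetting both on a class change and after each emission —
threshold 1 passes everything, threshold k emits ⌊n/k⌋ times on n identical
inputs.  A cumulative (non-consecutive) variant was rejected: it contradicts
the two-in-a-row semantics the gating is defined by.  Speed is carried as
mode metadata only; no vehicle is simulated.

## Synthetic data: what it shows and what it does not

Each 8-s trial at 128 Hz carries its class's oscillation during the 0–5 s
imagery window: a sinusoid at the class centre frequency (10/16/22 Hz for
fist/foot/thumb, ±0.2 Hz per-trial jitter) with a 0.25-s cosine ramp,
amplitude 10 nA·m (±10%), on the 20-vertex patch contralateral to the
imagined limb; the mirror patch oscillates at half amplitude (`erd_depth` =
0.5), giving the contralateral-dominance the laterality checks measure.  All
sources additionally carry 8–30 Hz background noise at 1 nA·m.  Sensor noise
is white at a target SNR (default 10 dB; `None` disables it); blinks are
300-ms raised cosines at 10×background RMS on AF3/AF4/F7/F8 (weights
1/1/0.6/0.6), Poisson-timed at 10/min.

These are engineered, not physiological, conditions: classes are separable by
construction (distinct hemisphere × frequency signatures), oscillations are
sustained sinusoids rather than bursty rhythms with event-related
desynchronisation dynamics, the conduction geometry is spherical, and there
is no EMG/ECG, electrode drift, or inter-subject variability.  A perfect
zero-noise score therefore verifies the plumbing end to end — forward
projection, inversion, patch extraction, wavelet features, learning — and
says nothing about accuracy on real recordings.  The permuted-label control
(chance-level accuracy on the same tensors) rules out label leakage through
the pipeline.

## Study sizes

The validation studies run at desk scale by design: BEM accuracy at
subdivision 3 (3840 panels); localization with 20 seeded dipoles per SNR on
the 305-vertex dome; the end-to-end study with 150 trials per class (900
total), evaluating the first fold of the five-part rotation with a 300-step
training cap — the loss plateaus long before that on these conditions.

## Known limitations

- Constant-potential collocation BEM; no linear basis, no isolated-skull
  approach.  With the realistic skull contrast (σ ratio ~80) forward accuracy
  is lower than in the equal-conductivity regime the oracle covers.
- The spherical fixture has no sulci; sign-alignment and mirroring are
  exercised only in their easy regime.
- GCV selects λ per data set; no spatial whitening or noise-covariance
  modelling.
- sLORETA/eLORETA, beamformers and dipole fitting are out of scope, as are
  realistic MRI-derived meshes and MEG.
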