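# Methods

## Signal representation and estimation

The package represents the diffusion-weighted signal by the cumulant
expansion truncated at the kurtosis term. The linear parameterisation used in
the design matrix is `(ln S0, D_ij, MD²·W_ijkl)`: scaling the kurtosis
elements by MD² keeps the model linear in its 22 parameters, and `W` is
recovered after the fit by dividing by the fitted MD². Column bookkeeping
uses the permutation multiplicities of the 6 unique `D` and 15 unique `W`
elements (1/2 and 1/4/6/12), which the tests verify against the naive
81-term contraction.

Fitting is two-pass weighted linear least squares on the log-signal:
an ordinary first pass provides predicted signals, whose squares are the
weights of the second pass. Predicted (not observed) squared signals are the
variance-stabilising choice that stays robust to noisy samples. One-pass and
iterated variants exist in the literature; the two-pass form was chosen as
the standard compromise and is deterministic. No positivity or kurtosis-range
constraints are imposed; implausible voxels keep their values and a validity
flag, and non-positive real-valued signals (possible after phase correction
at low SNR) are excluded per measurement rather than floored so the noise
stays symmetric. Fits are voxelwise and independent; no spatial
regularisation.

With no b=0 image in the protocol, S0 is always an extrapolated fit
parameter; the b=100 s/mm² shell is the reference shell for SNR.

## Scalar metrics

MD and FA come from the eigensystem (eigenvalues sorted descending;
eigenvector signs fixed by making the first component of magnitude >1e-10
positive, which makes the angle maps reproducible). MK is computed as the
orientation average of the apparent kurtosis over a deterministic
Fibonacci-sphere covering (default 10 000 directions) rather than an
analytic closed form: the quadrature is simpler, testably convergent
(5 000 → 10 000 moves the phantom value by <1e-3, well under the 2-decimal
reporting precision), and rotation-invariant to the same quadrature error.
AK is the apparent kurtosis along the principal eigenvector. RK is the mean
apparent kurtosis over m = 256 equally spaced directions in the plane
orthogonal to it — the perpendicular-plane average, not the two-eigenvector
average; for an axially symmetric tensor the two definitions coincide and
the plane average is exact for any fan phase.

## Cardiac wall geometry

Short-axis geometry: the left-ventricular long axis is the slice normal.
Per voxel the frame is radial (outward from the per-slice mask centroid),
circumferential (ẑ × r̂) and longitudinal. The helix angle is the signed
angle of the principal eigenvector's projection onto the circumferential–
longitudinal plane, measured from the circumferential direction, positive
toward the base, after flipping the eigenvector so its circumferential
component is non-negative. E2A is measured inside the cross-myocyte plane
(orthogonal to the primary eigenvector) between the secondary eigenvector
and that plane's wall-tangent direction `e1 × r̂`, folded to (−90°, 90°]
because eigenvectors are sign-ambiguous. These are the standard cardiac-DTI
conventions; since formulas for them are not uniquely fixed in the
literature, the convention is isolated in `geometry.py` and validated by
phantom recovery (exact in the noiseless limit), not against in-vivo values.

## The phantom

The generator emulates the study conditions this package targets: 3
short-axis slices, 2.7 mm in-plane voxels, an annular myocardium (default
radii 15–27 mm, 660 voxels), 5 shells [100, 450, 900, 1200, 1350 s/mm²] with
30 directions × 6 repeats (3 × 12 at b=100), electrostatic-repulsion
direction sets from a fixed seed, and an SNR at b=100 of 40 giving a
measured per-shell ladder of ≈(40, 23, 12, 8, 7).

Ground truth per voxel is one axially symmetric (D, W) pair expressed in the
local myocyte frame and rotated by the transmural helix ramp (+60° endo →
−60° epi, linear in wall depth; the range is a parameter, since only the
qualitative histogram shape is known):

- eigenvalues (λ∥, λ⊥) solved in closed form from the target MD and FA
  (defaults give λ∥ = 2.274×10⁻³, λ⊥ = 1.353×10⁻³ mm²/s);
- `W∥∥ = AK·λ∥²/MD²` (axial kurtosis exact by construction);
- `W⊥⊥` calibrated so the 256-direction perpendicular-fan average — the same
  quadrature the RK metric uses — equals the RK target exactly;
- the parallel–perpendicular cross element root-found (Brent) so the
  orientation-averaged MK equals the MK target; an unattainable MK for the
  given AK/RK raises an error reporting the attainable range.

A small eigenvalue split (`sheet_split = 0.02`) between the two
cross-myocyte eigenvalues makes the secondary eigenvector well defined, with
ground-truth E2A = 0 everywhere (sheetlet tilt is not modelled; E2A recovery
is validated against zero). The split changes FA only in the fourth decimal.
Targets are spatially homogeneous across the wall, since only global means
are available to match.

Complex synthesis multiplies the noise-free signal by `exp(iφ)` with φ a
random 2-D quadratic polynomial per measurement (coefficients sized so the
in-mask phase stays within ±π — smooth motion-induced phase, not a wrap
phantom), then adds independent complex Gaussian noise with σ set from the
in-mask mean b=100 signal and the requested SNR; 256 pure-noise frames are
appended (matching the repetition count used for σ estimation in vivo). All
randomness derives from the spec seed; identical specs are bit-identical.
Outlier injection multiplies whole randomly chosen frames by a dropout
factor inside the mask and returns the corrupted index set for scoring.

What the phantom does not emulate: biophysical tissue compartments (kurtosis
is imposed, not emergent), cardiac/respiratory motion fields and
misregistration (corruption is modelled as whole-frame dropout),
susceptibility distortion, transmural heterogeneity of the scalar targets,
and sheetlet structure. Passing tests therefore demonstrate estimator
correctness under the stated noise model, not robustness to every in-vivo
artefact.

## Preprocessing

Phase removal: the smooth per-measurement phase is estimated and conjugated
off, keeping the real part, so the noise stays zero-mean Gaussian with the
original σ instead of acquiring a Rician floor. The default estimator is a
magnitude²-weighted least-squares fit of a low-order (default quadratic)
2-D polynomial to the voxelwise phase angle, restricted to the myocardial
mask (background voxels carry no phase information) and refined by three
Gauss–Newton re-wrapping iterations for robustness to noisy angles near ±π.
For a polynomial phase this estimator is exact in the noiseless limit, which
makes the pipeline's bias properties testable; a Gaussian low-pass
conjugation (`method="lowpass"`, kernel FWHM 12 mm) is provided as the
assumption-free alternative, accurate away from the wall boundary but not
exact near it.

σ is the per-voxel standard deviation (n−1) of the real part across the
noise-only frames, averaged over the mask. SNR per shell is S/σ with S the
repeat-averaged per-voxel signal, averaged over directions then summarised
over the mask — computed after (no-op) registration and before outlier
rejection, preserving the in-vivo stage ordering so a real registration can
be slotted in.

Outlier rejection replaces the in-vivo semi-automatic procedure with a
deterministic robust-z rule. Each frame is scored by the in-mask mean
log-residual against the per-voxel median of its (shell, direction) repeat
group, weighted by the squared reference signal (the inverse variance of a
log residual) and divided by the group's predicted noise factor so
directions with different signal profiles score on one scale. Within each
shell, frames beyond z = 3 robust standard deviations (1.4826·MAD) are
flagged; a coarse first pass (|z| > 10) removes gross outliers from the
median references before the final pass, since a corrupted repeat would
otherwise bias its siblings' references and cascade false flags. On seeded
corruption (2% of frames at dropout 0.5) this achieves sensitivity 1.0 at a
≈0.9% clean false-positive rate. The per-shell rejection counts of a real
study reflect actual subject motion and are not comparable quantities.

## The synthetic study

`run_full_study` simulates n = 10 subjects with ±3% uniform jitter on the
phantom targets (emulating inter-subject spread and enabling the paired
statistics at the study's n), runs phase correction → σ/SNR → rejection →
DKI WLS → scalar and angle maps per subject, and reports group mean ± SD for
MD/FA/MK/AK/RK, median [IQR] for E2A (median, not mean, as angle
distributions are heavy-tailed), a pooled HA histogram, and the paired
RK−AK contrast with Bland–Altman limits and a Wilcoxon signed-rank p-value.
The Wilcoxon test enumerates the exact null distribution by dynamic
programming over doubled midranks for n ≤ 25 (zeros dropped, midranks for
ties) and falls back to the tie-corrected normal approximation above; note
the smallest attainable two-sided exact p at n = 10 is 2/2¹⁰ ≈ 0.00195.
All seeds derive from one root seed and are logged in the report;
identical configurations produce byte-identical reports.

## Numerical choices and known limitations

- Unit convention: b in s/mm², D in mm²/s everywhere; reporting multiplies
  MD by 10³.
- Degenerate inputs: all-zero tensors give masked FA; non-positive apparent
  diffusivity gives masked (NaN) kurtosis, never silent zeros; rank-deficient
  designs flag the voxel and the pipeline continues.
- Under the study noise the log-linear WLS estimator carries a small
  downward kurtosis bias (≈−0.02 on MK at the b=1350 SNR of ≈7, from the
  curvature of the log transform); the RK−AK contrast is less affected
  because the biases partially cancel.
- DTI fits to kurtosis-bearing signals underestimate MD increasingly with
  bmax — that decline is the phenomenon under study. A side effect of the
  pure-kurtosis forward model with RK > AK is that DTI-estimated FA also
  drifts down slightly with bmax (0.307 at bmax=450 to 0.296 at 1350 on the
  noiseless phantom), because the perpendicular diffusivity is suppressed
  relatively faster; myocardial FA measured in vivo is reported as more
  stable than this, so FA stability across bmax should be read as a
  tissue property the phantom does not reproduce.
- Problem sizes used throughout (3 slices × 660 voxels, 756 measurements,
  10 subjects, 10 000 MK directions) were chosen so the complete study runs
  in about a minute on a single CPU while keeping Monte-Carlo error well
  below the reported precision.
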