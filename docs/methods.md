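# Methods

## Model and assumptions

Half-maps are modeled as u = f + r₁, v = f + r₂: a shared signal plus two
independent, approximately Gaussian noise fields.  Volumes are cubic
(n × n × n, n even), real-valued, with a pixel size p in Å.  Reciprocal
space is indexed by the Fourier-pixel radius k (spatial frequency
s = k/n); the DC term is excluded from every shell, filter and
normalization.  For real volumes, Friedel symmetry makes shell inner
products real, so FSC values are real by construction, not by taking a
real part of something complex.

The statistical machinery assumes (i) approximate normality of the noise —
reasonable for 3D voxels, which average many contributions; (ii) at least
~25 effective samples per shell and correlations below 0.95 for the Fisher
z normal approximation; (iii) independence of the half-maps.  Correlations
introduced upstream (interpolation during reconstruction,
maximum-likelihood orientation weighting) reduce the true degrees of
freedom below the model's estimate; the confidence test is then
anti-conservative to an unquantified degree.  This is a limitation of the
ndf model, not of the mask-robustness property.

## The mFSC and why the mask cannot bias it

Classical FSC masks in real space *before* the Fourier transform.  The
transform of the product is the convolution of the transforms, so the
mask's spectrum is mixed into every coefficient of both half-maps — a
shared component that produces spurious correlation, stronger for tighter
and sharper masks.  The mFSC band-passes each half-map around shell k
first (Gaussian amplitude gain exp(−(r−k)²/2σ_g²), no tail truncation) and
only then computes a Pearson-type correlation over the support of a
*binary* mask.  Dropping voxels from a sum is a projection, not a
convolution: it cannot manufacture correlation between independent inputs.
Soft masks are accepted for the classical FSC (to reproduce the
traditional protocol) but rejected for the mFSC, whose premise requires
support restriction; soft masks are binarized at 0.5.

Within-mask mean subtraction: the correlation formula assumes zero-mean
arguments, and a band-passed volume restricted to a small support
generally has a nonzero local mean (including DC leakage through the
Gaussian tails).  The within-mask mean of each argument is therefore
removed by default; `subtract_mean=False` restores the raw normalized
inner product.

Cost model: one pair of 3D FFTs per shell.  All multi-region analyses
(local map, segments) compute the band-passed volumes once per shell and
share them across regions; results are identical to per-region filtering.

## Degrees of freedom

* Rectangular width-1 shell: ndf = 4πk², the continuum shell surface.
  Exact lattice counts (`shell_voxel_count`) agree within 15% for k ≥ 4
  (15.4% at k = 3); the continuum form is smooth in k and is the default,
  with the lattice count available for comparison.
* Gaussian window: ndf = 4πk² · 3σ_g.  The factor 3σ_g is the window's
  effective thickness, calibrated by a Monte-Carlo PCA experiment: draw
  N(0,1) arrays, multiply by the window, accumulate the covariance, and
  compare its eigenvalues with those of a shuffled (randomization) control;
  the estimate is the highest rank at which the structured eigenvalue still
  exceeds the control.  At 10⁴ iterations the estimate is bit-reproducible
  per seed and varies by ≤ 2 across seeds; the regression of estimates on
  σ_g ∈ {2, 4, 8, 16} through the origin gives a slope of ≈ 3.3.  The
  individual ratios drift from ~4.5·σ_g at σ_g = 2 down to ~3.2·σ_g at
  σ_g = 16 — the linear ndf ≅ 3σ_g rule is an approximation, adopted for
  the closed form because the CI cutoff depends on ndf only through
  (ndf−3)^(−1/2) and is insensitive to factors of this size.
* Binary mask: multiply by the mask fraction |m|/n³.
* Helical: divide by the number of unique disks included in the mask;
  symmetry-equivalent disks contribute voxels but no independent
  information, which keeps the result invariant to the disk count.
* Floor: ndf is floored at 4 (with a warning), since the Fisher variance
  1/(ndf−3) must stay finite; microscopic masks then degrade to an
  uninformative, very wide confidence interval rather than crashing.

Prewhitening — dividing the transform by the per-shell RMS amplitude — is
implied by the shell-wise normalization of both FSC and mFSC, so the
overall real-space ndf is taken as n³ with no explicit step; an explicit
`prewhiten` operation is provided as a diagnostic.

## Resolution rule

Per shell, the curve passes if its value reaches
tanh(arctanh t + q(1−α)·(ndf−3)^(−1/2)) — equivalently, if the one-sided
lower confidence bound of the observed correlation reaches t (tanh is
monotone, so the formulations coincide; the implementation asserts the
cutoff form).  k* is the end of the **initial** contiguous run of passing
shells, so an isolated high-frequency excursion above the cutoff cannot
inflate the resolution; a "global highest passing shell" mode exists for
comparison.  No shell passing yields the sentinel k* = 0 ("no resolvable
signal").  A plain-threshold mode (cutoff ≡ t) reproduces traditional
fixed-threshold readings; because the CI cutoff is strictly above t for
finite ndf, the CI resolution can never be better.  Defaults: t = 0.143,
α = 0.01 one-sided; two-sided mode replaces α by α/2 exactly.

## Synthetic data

The generator is the package's study condition, not a tuning knob:

* Noise is shaped per width-1 shell against the phantom's *measured* shell
  power so the expected FSC at shell k is exactly ssnr/(1+ssnr); within a
  shell the noise is white.  Shells with target SSNR 0 have their shared
  signal removed outright (no finite noise level yields exactly zero
  correlation) and carry noise at the phantom's mean in-band power.
* Phantoms: blob ensembles (12 Gaussian blobs of σ = 0.055·n placed in a
  0.3·n-radius sphere → support ≈ 5–15% of the volume, typical of particle
  boxes), full-support band-limited Gaussian random fields (for spatially
  stationary statistics), and axially periodic filaments.
* `background` adds a shared constant offset (in units of the noise σ) to
  both half-maps, emulating the solvent density level real reconstructions
  sit on.  It lives at DC only, so unmasked curves are unaffected — but it
  is exactly what a tight multiplicative mask imprints on both maps, and
  is therefore switched on (at 1σ) in the mask-artifact demonstrations.
  Without it, strictly zero-mean independent noise would show no masked-FSC
  artifact in expectation.
* `solvent_noise_factor` adds extra white noise outside the support,
  reproducing the elevated solvent noise visible in half-map difference
  volumes.
* Not modeled: CTF, projection geometry, alignment error, inter-half-map
  correlation.  Passing tests therefore validate the estimator's
  statistical behavior under the stated model, not robustness to
  refinement-induced correlations in real maps.

## Numerical choices

* Shell membership: point s belongs to shell k iff k−½ ≤ ‖s‖ < k+½;
  consecutive width-1 shells partition the lattice exactly.
* Curves run to k_max = n/2 − 1 by default; the Nyquist shell is only
  partially sampled.
* Zero-power shells yield a curve value of 0 with a warning (not NaN);
  "zero" is judged relative to the strongest shell (10⁻¹² ratio) to absorb
  FFT rounding residue.
* Degenerate (constant-on-mask) correlations return 0 with a warning.
* Values are clipped to [−1, 1] against float rounding.
* Helical mask height rounds the total n_disks·rise/p (e.g. 8 × 4.14 =
  33.12 → 33 px) rather than rounding per disk; the ndf divisor stays the
  integer disk count.
* The local map evaluates every stride-th voxel whose box fits inside the
  volume and fills the rest of the region by nearest evaluated neighbor;
  stride 2 is the default speed/smoothness trade-off, stride 1 reproduces
  per-voxel evaluation.  Box correlations are computed for all centers at
  once from box means (uniform filters), identical to the per-box masked
  correlation at interior centers.
* Monte-Carlo ndf: window centered mid-array; per-iteration row shuffles;
  accumulation batched as Xᵀ X, algebraically identical to summed outer
  products; eigenvalues rank-matched after descending sort.  Arrays
  shorter than 8σ_g make the window effectively flat — the estimate then
  saturates at the array length and a warning is issued.

## Design decisions that were genuinely open

* SSNR convention fixed as |c|/(1−|c|) (not the half-map-averaging
   2c/(1−c) variant) by the worked values 0.143→0.17, 0.5→1, 0.91→10.
* Fisher variance 1/(ndf−3): the standard result, consistent with the
  ">25 samples" validity range quoted for the method.
* The resolution test is phrased as H₀: ρ ≤ t, rejected when the curve
  exceeds the t-anchored upper cutoff; shown equivalent to the
  lower-confidence-bound reading.
* Box size 15³ (σ_g = 3, α = 1%) for local maps: an 11³ box cuts the ndf
  ~2.5× (3375/1331) and systematically depresses local estimates below the
  global one; 15³ is the smallest box with acceptable dispersion.
* The adaptive local-window-size idea (adjusting the box by target ndf and
  smoothness) is not implemented; the box is a fixed user parameter with
  the defaults above.

## Problem sizes

Validation runs use n = 64 volumes (≤ 32 shells), 20-seed ensembles for
stochastic properties, and length-512 arrays with 10⁴ iterations for the
Monte-Carlo calibration; these sizes give stable statistics for every
property tested while keeping the full suite fast.
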