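# mfscres — mask-robust cryo-EM resolution estimation

`mfscres` estimates the resolution of single-particle cryo-EM
reconstructions from half-maps using the **modified Fourier shell
correlation (mFSC)**, a variant of the FSC that is immune to the real-space
mask, together with a statistically grounded, one-sided confidence-interval
resolution test.  It covers global (whole-map), local (moving-box),
segment-focused, and helical-assembly resolution, and ships a synthetic-data
module so every part of the pipeline can be exercised and validated without
external maps.

## The problem and the method

The classical FSC multiplies both half-maps *u*, *v* by a mask *m*, then
correlates their Fourier transforms shell by shell:

    FSC(k) = Re⟨ û·m, v̂·m ⟩_k / (‖û·m‖_k · ‖v̂·m‖_k)

By the convolution theorem, multiplying by *m* before transforming smears
the mask's transform across every Fourier coefficient: both half-maps
acquire the *shape of the mask* as common signal, and a tight mask makes
even independent noise correlate.  Resolution values read from masked FSC
curves therefore depend on the mask and are routinely overestimated.

The mFSC swaps the order of operations.  For each shell *k*, both half-maps
are band-pass filtered around *k* with a Gaussian gain
G(r) = exp(−(r−k)²/2σ_g²), and the **real-space** correlation coefficient is
then computed only over the voxels where the binary mask is 1.  Restricting
the support removes terms from the sums — it cannot correlate anything — so
the mask, however tight, introduces no artifact.

Correlation maps to spectral signal-to-noise by SSNR = |c|/(1−|c|)
(c = 0.143 ⇒ SSNR ≈ 0.17; c = 0.5 ⇒ 1; c = 0.91 ⇒ 10).

Instead of reading the resolution at the fixed threshold *t*, the package
tests, per shell, whether the observed correlation is *significantly* above
*t*: with the Fisher transform z = arctanh(r), approximately normal with
standard deviation (ndf−3)^(−1/2), the shell passes at one-sided level α iff

    mFSC(k) ≥ tanh( arctanh(t) + q(1−α) · (ndf_m(k) − 3)^(−1/2) )

where the per-shell degrees of freedom are

    ndf_m(k) = 4πk² · 3σ_g · |m|/n³ / n_disks

(shell surface × effective Gaussian window thickness × mask fraction,
divided by the number of symmetry-redundant helical disks, if any).  The
3σ_g window thickness is calibrated by a Monte-Carlo PCA experiment with a
shuffling randomization control (`mc_ndf_gaussian_window`).  The resolution
is the end of the initial contiguous run of passing shells, k*, reported as
n/k* pixels or p·n/k* Å.  Small masks mean small ndf and high cutoffs, so
statistically unsupported claims are suppressed by construction.

## Worked example

```sh
python examples/global_resolution.py
```

builds a 64³ half-map pair whose true per-shell FSC is a logistic falloff
crossing 0.143 near shell 20.5 (pixel 1.34 Å), masks it with a 0.7·n sphere
and prints:

```
threshold: k* = 20 Fourier px -> 4.29 A
       ci: k* = 19 Fourier px -> 4.51 A
```

The plain-threshold reading recovers the generator's crossing shell; the CI
reading at α = 1% is one shell more conservative, as it must be.  The other
examples demonstrate the mask-robustness phenomenon
(`mask_robustness.py`: classical masked FSC ≈ +0.92 on *independent-noise*
half-maps vs mFSC ≈ +0.02 and a correct "no resolvable signal" verdict),
local two-compartment maps, helical disk invariance, and the Monte-Carlo
window calibration.

## Command line

```sh
mfsc fixtures --out data --n 64 --seed 3          # synthetic dataset
mfsc global data/half1.mrc data/half2.mrc --mask data/sphere_mask.mrc
mfsc local  data/half1.mrc data/half2.mrc --region data/sphere_mask.mrc --box 15
mfsc segments HALF1 HALF2 --labels labels.mrc
mfsc helical HALF1 HALF2 --rise 5.13 --radius 37 --disks 8
mfsc mc-ndf --sigma-g 4 --length 512 --iters 10000
```

Defaults: t = 0.143, α = 0.01, σ_g = 1 for global curves and 3 for
local/segment analysis, box 15³.

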