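# Methods

## Model and procedure

The filter treats impulse denoising as detection followed by replacement.

**Detection statistic.** For a round's eight 5×5 kernels `K_i` and the three
color planes `I_j`, the variation response is `V_ij = |K_i ⊛ I_j|`, computed
as an exact int64 correlation under replicate (edge-extension) border
padding, so every pixel — including the two-pixel border frame — receives
the full 24 measurements without the spurious responses zero padding would
create. The per-pixel decision statistic is the minimum `M = min_ij V_ij`
with its (kernel, channel) argmin; ties resolve to the smallest
(kernel id, channel id) pair, kernel-major, which makes the argmin
deterministic and reproducible. A pixel is flagged when `M > T` **and** its
intensity on the argmin channel is exactly 0 or 255. The intensity test
always reads the round's own input image (the original in round one, the
once-cleaned image in round two), matching the data flow of the two-pass
procedure.

Why the minimum: an impulse shows strong variation in *every* direction,
while an edge, ridge, or ramp always has at least one aligned direction with
a quiet response. Because every kernel is zero-sum and point-symmetric, any
affine intensity ramp yields exactly zero response, so smooth gradients can
never be flagged regardless of slope.

**Kernel construction.** The exact integer coefficients are a design
decision of this package, built constructively from three load-bearing
properties: zero sum, directionality at π/8 steps, and (second round)
exclusion of the eight direct neighbors. For each nominal direction θ the
first-round kernel places −1 at the ring-1 and ring-2 lattice cells
angularly nearest θ plus their point mirrors (ties at the π/8-family angles
break toward the cell just below θ, a rotation-invariant choice that keeps
each bank closed under 90° rotation), with center weight +4. Second-round
kernels are the analogous construction restricted to the 16-cell ring at
Chebyshev distance 2: center +2, two −1 on the ring, all direct neighbors 0.
Kernels are integer-valued and unnormalized; the threshold is calibrated to
this scale, and any rescaling of the weights must rescale the threshold
identically. A JSON dump (`mlvmf kernels --dump`) and a SHA-256 bank
checksum embedded in run reports let any coefficient change be diffed.

**Replacement.** Flagged pixels become the vector median of their 3×3
neighborhood: the member vector minimizing the sum of L1 distances to the
other members (L2 available by flag; L1 is integer-exact and matches the
classic vector-median literature). Ties resolve to the earliest vector in
raster order. Replacement is batch per round — all medians are read from the
round's input image before any pixel is written — so results are
independent of scan order; whether the original procedure reused
already-replaced neighbors within a round is unrecorded, and batch was
chosen for its order-independence and hardware-dataflow character.

**Rounds.** Exactly two. More rounds with the same banks would re-examine an
image whose remaining impulses are, by construction, invisible to both
banks.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `threshold` T | 75 | minimum-variation cutoff, absolute response units, both rounds |
| `norm` | L1 | vector-median distance; L2 optional |
| `border` | replicate | convolution border policy |
| `noise mode` | monochrome | one impulse draw per pixel (gray sources); `channelwise` optional |
| `salt_fraction` | 0.5 | share of impulses at 255 |

With center weight 4 (round one) an isolated impulse on a locally flat
region of intensity v responds at `4·|impulse − v|` under every kernel, so
the detection floor is a contrast of T/4 ≈ 19 levels; round two's floor is
T/2 ≈ 38 levels. T = 75 keeps genuine mid-gray scenes detectable while
staying far above the zero response of smooth structure.

## Synthetic data

`make_phantom` generates the study images: `flat` (one mid-gray constant),
`gradient` (an affine ramp, analytically invisible to the banks), `blocks`
(four constant quadrants with every edge-sharing step ≥ 60 levels; the two
closest values sit on a diagonal), and `chest_like` (vertical-gradient
background, two dark elliptical lung fields, bright rib arcs, mild
seed-driven jitter). Clean phantom intensities stay within [45, 210] so
both salt and pepper impulses clear the round-two detection floor of 38
levels — the contrast regime the method targets; phantoms avoid 0/255, so
clean structure can never pass the extreme-intensity test. `add_salt_pepper`
records exact per-channel ground truth; `plant_collision` builds
deterministic 4-/8-connected same-value clusters.

What the phantoms do **not** emulate: photographic texture, fine anatomical
detail, sensor blur, and low-contrast structure near the extremes. Passing
tests therefore demonstrate the detector's selectivity and the two-round
collision behavior on piecewise-smooth content; on real radiographs,
structure with local contrast below T/4 against a 0/255 background — or
genuinely black/white clean regions — can be missed or falsely flagged, as
with any threshold detector of this family.

## Numerical choices

- All detection arithmetic is exact int64; metric arithmetic is float64.
- Argmin and vector-median ties are deterministic (first index wins).
- PSNR of identical images is reported as +inf (a `"inf"` string sentinel in
  CSV/JSON, never a float overflow); NCD of an all-black original raises an
  explicit error rather than returning NaN.
- RGB→YUV uses the analog BT.601 matrix (Y = 0.299R + 0.587G + 0.114B,
  U = 0.492(B−Y), V = 0.877(R−Y)), unquantized, exposed as a module constant
  so alternate conventions can be swapped.
- Coordinates are 0-based (row, column), row-major; channel order is RGB.

## Evaluation protocol and problem sizes

`evaluate` corrupts each clean image at each noise level (one realization
per seed), feeds the same realization to every filter (`mlvmf`, plain `vmf`,
`identity`), and scores PSNR and NCD against the clean image. The acceptance
checks run 256×256 `blocks` and `chest_like` phantoms at 3/5/10/20/30%
monochrome noise with 5 seeds per cell; `scripts/acceptance.py` reports the
same protocol at 3 seeds per cell, a size at which cell means are stable to
well under a dB. Reference comparisons on the standard 256×256 photographic
test images are supported through `mlvmf bench --images DIR` when a user
supplies them; their absolute PSNR/NCD values depend on the particular noise
realization and are not asserted by the test suite.

## Known limitations

- The detector only ever flags exact 0/255 samples; near-extreme impulses
  (e.g. from prior lossy processing) are out of scope.
- Noise models other than salt-and-pepper (Gaussian, Poisson, mixed) and
  bit depths above 8 are out of scope.
- At very high noise densities, impulses embedded in large same-valued
  clusters spanning the full 5×5 support of every kernel remain invisible
  to both rounds; the residual is measured, not hidden, by the collision
  tests.
- The vector median can only return colors present in the window; when a
  window is majority-corrupted the replacement may itself be an impulse
  value. A smarter estimator of the true color is a known extension and
  deliberately not implemented here.
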