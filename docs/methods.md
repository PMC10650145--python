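# Methods

## Problem and model

Subcutaneous blood vessels are hard to see on skin because the visible-range
reflectance of skin is dominated by melanin, which varies strongly across
skin tones. In the NIR optical window (~700–950 nm) skin and fat absorb
weakly while blood absorbs strongly, so vessels appear as dark structures —
but no single spectral band separates vessels reliably for every skin type.

`veinindex` implements a band-math approach: a generalized rational spectral
index over three wavelengths, with small integer coefficients, whose free
parameters are chosen by exhaustive search against an expert-drawn binary
vessel mask. Two families are supported:

* ratio family:
  `R = (k1·I1 + k2·I2 + k3·I3) / (k4·I1 + k5·I2 + k6·I3)`
* product-ratio family:
  `R = (k1·I1 + k2·I2)·(k1·I1 + k3·I3) / (k4·I1 + k5·I2 + k6·I3)`

`I_i` is the brightness in the band whose center is nearest `λ_i`; `k_i`
range over a configured symmetric integer set (default −2…2). In the
product-ratio family `k1` is shared between the two numerator factors — the
form is implemented exactly as written, not with a seventh free coefficient.
The ratio family is invariant to global illumination scaling (degree-0
homogeneous); the product-ratio family scales linearly. The published
optimum member, exposed as `eval_vessel_index`, is the product-ratio formula
at λ = (714, 738, 882) nm with k = (1, −1, −1, 1, 1, 1).

## Objective

A candidate index image is normalized to [0, 1] (percentile clip at the
1st/99th percentiles of the valid pixels, then affine), and scored by the
root-mean-square distance of the *vessel* pixels to the ideal vessel value.
Because the global sign of a formula is arbitrary (sign-symmetric duplicates
are excluded from the search), both polarities are scored — target 0 for
dark vessels, target 1 for bright vessels — and the better one kept.
Background pixels are deliberately not scored; the ranking therefore needs a
second criterion, and among candidates whose RMS ties the best within a
tolerance (default 0.01) the ranking falls back to the mean Michelson
contrast of dark stripes, descending.

Numerical safeguards:

* Pixels whose denominator magnitude falls below 1e-6 of the image-mean
  absolute denominator are flagged invalid and excluded from normalization
  and scoring rather than clamped, so near-division-by-zero never produces
  fake extremes. A candidate with more than half of its vessel pixels
  invalid is rejected outright.
* A candidate whose index image is constant over the valid pixels (zero
  percentile range) is rejected. Any coefficient tuple with numerator
  proportional to the denominator produces such an image; it normalizes to 0
  everywhere, which would score a perfect vessels-dark RMS while carrying no
  information. Rejection, rather than tie-breaking, is the only ranking rule
  that keeps degenerate tuples out of the top of every search.
* Exact RMS ties between polarities report `vessels_dark`.

## Search

The coarse stage enumerates, per family, every coefficient 6-tuple crossed
with every ordered wavelength triple (repeats allowed) on a strided band
grid (default: every 25th band). Sign symmetry is removed by a lexicographic
canonical form: a ratio tuple is emitted only if it precedes its full
negation, a product-ratio tuple only if its denominator half precedes its
negation; all-zero numerators or denominators are degenerate and dropped.
The nominal grid sizes (|set|^6 · n_grid^3, halved for sign symmetry) are
reported alongside the slightly smaller actual enumeration count.

The hot path evaluates one wavelength triple at a time with all coefficient
tuples batched: numerator and denominator rows are shared across candidates,
and percentiles are taken from row-sorted data with the same interpolation
as `numpy.percentile`. The vectorized scorer performs the same floating-
point operations as the public `eval → normalize → masked_rms` composition,
so a brute-force loop over `enumerate_candidates` reproduces its scores
candidate for candidate (this is asserted in the test suite on an 8×8×6
cube).

Refinement takes the top coarse results (default 10) and re-searches at
stride 1 by coordinate descent: each wavelength axis in turn scans every
band within ± one coarse stride of the current position, jointly with the
coarse optimum's one-step coefficient neighborhood, moving only on strict
improvement, up to three sweeps. A full stride-1 grid over the ±25-band
cube of all three wavelengths would cost ~10⁵ triples per coarse result —
times ten coarse results and thousands of pixels per evaluation, far beyond
a single-CPU desk run — while coordinate descent reaches the same
neighborhood optimum in a few hundred triple evaluations whenever the
objective is locally coordinate-monotone, which holds for the smooth
single-dip structure the search targets. The coarse point is always a
candidate, so refined RMS never exceeds coarse RMS.

The two-wavelength baseline searches all normalized-difference pairs
`(I_a − I_b)/(I_a + I_b)` on the same grid with the same objective. ND pairs
are degenerate members of the three-wavelength ratio family, so the
three-wavelength optimum can never be worse in RMS; the contrast margin of
the three-wavelength winner over the ND winner is the package's stand-in for
the reported up-to-25% contrast improvement, which was measured on human
images that are not publicly available.

## Contrast metric

Vessels cross a vertical profile (one image column) as dark fringes. Fringes
are detected with `scipy.signal.find_peaks` on the negated profile, with a
prominence floor (default 5% of the image dynamic range, resolved once per
image) and a width window (default 3 px to 25% of the profile length);
invalid pixels split the profile into independently scanned segments. Per
fringe, `i_min` is the minimum inside it and `i_max` the larger flanking
shoulder, giving the Michelson contrast `(i_max − i_min)/(i_max + i_min)`.
The image figure of merit is the mean over all fringes in all columns; the
accompanying absolute-error figure is the sample standard deviation of the
per-stripe contrasts (an explicit estimator choice — the source procedure
reports an error without defining one). Contrast is computed on normalized,
dark-oriented images in the ranking so thresholds are scale-stable; the
metric itself is scale-invariant and strictly decreases under a constant
pedestal.

## Synthetic data

No real forearm hyperspectral data are distributable, so the generator
provides phantoms with the statistical structure the method assumes, not
radiative-transfer fidelity:

* **Baseline skin spectrum** — a logistic ramp rising from the visible into
  the NIR, times a melanin attenuation `exp(−1.2·m·(λ/400)⁻³)`; the melanin
  scale `m` maps from six skin-tone grades (fair 0.05 … dark 1.0). Darker
  skin is uniformly darker with the gap closing toward 1000 nm.
* **Vessels** — 3 smooth sinusoidal paths (width 3–6 px, depth 0.5–2 mm) by
  default. Vessel spectra multiply the baseline by Gaussian absorption dips
  at 740 nm (depth 0.45, σ 28 nm) and 970 nm (depth 0.30, σ 45 nm), chosen
  so the NIR window carries the vessel signal: 738 nm sits inside a dip and
  714/882 nm on its shoulders, making the published optimum region a
  plausible one on synthetic data. Dips attenuate with depth
  (`exp(−depth/1.5 mm)`) and the vessel footprint is blurred with a
  depth-dependent Gaussian (σ = 0.5 + 0.6·depth).
* **Noise** — additive zero-mean Gaussian, default sd 0.01 on a unit-scale
  reflectance, clipped at 0.

Default sample size is 64×64 pixels × 250 bands (400–1000 nm), matching the
band count and range of the target acquisition at a desk-scale spatial crop.
The ground-truth mask is the exact unblurred vessel footprint. A single
seeded generator drives all randomness; identical configs are bit-identical.

What passing tests on these phantoms shows: the search machinery recovers
planted spectral structure through noise, prefers three-wavelength indices
over two-wavelength ones, and is deterministic and oracle-consistent. What
it does not show: performance on real skin (specular glints, hair, tattoos,
depth-varying scattering, camera noise statistics), and the phantom contrast
values are not comparable to the published per-participant contrast tables.

## Problem sizes and defaults

* Coarse search defaults: stride 25, coefficient set −2…2; on 250 bands this
  is the published reduction 0.5·5⁶·10³ ≈ 7.81×10⁶ per family. Tests and the
  acceptance script run the reduced set {−1, 0, 1} (0.5·3⁶·10³ ≈ 3.6×10⁵ per
  family before degeneracy removal, ~676 000 actual candidates over both
  families), which keeps a full coarse+refine cycle around half a minute on
  one CPU while preserving every structural property of the search.
* Tie tolerance 0.01 on normalized RMS; contrast tie-break limited to the
  top 500 tied candidates.
* Percentile clip (1, 99); denominator validity threshold 1e-6 (relative).

## Known limitations

* The generator's optics are phenomenological; melanin/hemoglobin curves are
  stylized, and there is no specular or volumetric scattering model.
* Eq-style contrast aggregation treats every detected fringe equally; wide,
  shallow vessels and narrow, deep ones weigh the same.
* Refinement is a local coordinate descent around coarse optima; a coarse
  optimum in the wrong basin refines to the wrong local minimum (mitigated
  by refining the top 10 coarse results rather than one).
* ENVI support covers BSQ/BIL reading and BSQ writing with wavelengths in
  the header — the subset the pipeline itself produces and consumes.
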