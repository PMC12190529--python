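# Methods

`nbisim` reconstructs a 380–780 nm reflectance hypercube from a white-light
endoscopic (WLI) sRGB image and synthesizes a simulated narrow-band imaging
(NBI) view from it. This note records the model, its assumptions, the
numerical choices, what the synthetic world does and does not emulate, and
the known limitations.

## Pipeline model

**1. Colorimetric calibration.** The anchor is a 24-patch colour target with
paired measurements: the camera's sRGB value of each patch and its
spectrometer reflectance spectrum. Camera values are linearized with the
IEC 61966-2-1 inverse transfer and mapped to "camera XYZ" with the standard
sRGB→XYZ(D65) matrix. The spectrometer spectra are integrated against the
CIE 1931 2° observer to give target tristimulus `XYZ_spec` (reference white
Y = 100). A polynomial feature vector `V(XYZ_cam)` — by default the 14-term
degree-3 basis {1, X, Y, Z, XY, XZ, YZ, X², Y², Z², XYZ, X³, Y³, Z³},
evaluated on XYZ/100 to keep monomials O(1) — is regressed onto the targets:

    C = XYZ_spec · pinv(V),     XYZ_corr = C · V(XYZ_cam)

with the minimum-norm SVD pseudo-inverse (relative cutoff 1e-10). Fourteen
terms against 24 patches keeps the fit overdetermined. The per-patch colour
error before/after correction is reported as CIEDE2000 (kL = kC = kH = 1) by
default, CIE76 ΔE*ab on request.

**2. Spectral reconstruction.** The 24 patch reflectances are decomposed by
mean-centred PCA. Six components are retained by default: for smooth natural
reflectances (and for the synthetic generator below) they carry ≥ 99.6% of
the variance. A second minimum-norm regression maps colour features of the
*corrected* XYZ to PC scores:

    M = Score · pinv(V_color),   s(λ) = mean(λ) + EV · M · V_color(XYZ_corr)

Applied per pixel this turns an image into an (H, W, 401) hypercube.
Reconstructed reflectance is clamped to [0, 1.2]: mild overshoot is
legitimate extrapolation, 1.2 bounds nonphysical blow-up; clamp counts are
logged. Because colour is 3-dimensional and the spectral space is
6-dimensional, reconstruction is exact only for spectra whose variation the
colour features can index (metamerism is the fundamental limit); on the
synthetic training patches the mean RMSE is ~0.03–0.05 reflectance units.

**3. NBI synthesis.** Each illumination band is a Cauchy–Lorentz line
`A·(1/π)·γ/((λ−λ0)²+γ²)`. Defaults: primary bands at 415 nm (γ = 15 nm) and
540 nm (γ = 10 nm) — the blue band that images deep submucosal vessels and
the green band for superficial capillaries — plus weak bands at 600/700/780
nm (γ = 5 nm) emulating commercial post-processing tints. A band's response
to a reflectance spectrum is the luminance-weighted integral
`A·Σ r·f₁·ȳ / Σ f₁·ȳ` (f₁ the unit-amplitude profile), so a perfect
reflector responds exactly A and amplitudes trade off linearly against the
3×n_bands display mixing matrix. Default mix follows the standard NBI
pseudo-colour convention: the 415 nm band drives display G and B, the
540 nm band drives R; the long-wave bands enter every channel at 0.05.
Mixed linear RGB is clipped to [0, 1] and sRGB-encoded.

**4. Band optimization.** Band centres, widths and amplitudes (and
optionally the mix) are tuned by dual annealing — generalized simulated
annealing with local search — against target patch colours, minimizing the
mean CIEDE2000 over the patches. Bounds: centres ±10 nm of nominal,
γ ∈ [1, 40] nm, A ∈ [0, 2], mix ∈ [0, 1.5]; budget 2000 objective
evaluations; the seed is a mandatory argument. After annealing, a bounded
Nelder–Mead polish is run from the best point: the annealer's
gradient-based local search can stall in the curved, ill-conditioned
valleys of the CIEDE2000 objective, where a derivative-free simplex still
makes progress. The returned objective never exceeds the starting value
(the start is kept if the search fails to improve it).

Identifiability caveat: with all five bands free, a primary-band centre is
not identifiable to ~1 nm — the weak auxiliary bands and free widths can
compensate a small shift almost exactly. Centre-recovery claims are
therefore only meaningful for the two-band configuration, and are verified
there.

**5. Quality metrics.** SSIM uses the standard 11×11 Gaussian window
(σ = 1.5, K1 = 0.01, K2 = 0.03, sample covariance off) on the BT.601 luma
of the sRGB-encoded image. PSNR is 10·log10(range²/MSE); identical images
are flagged as infinite rather than reported as a number. Entropy is
Shannon entropy of the 256-bin grayscale histogram (0–8 bits); the percent
difference is normalized by the reference image's entropy.

## Colour-science choices

* **Observer.** CIE 1931 2° colour-matching functions evaluated from the
  published multi-lobe piecewise-Gaussian analytic fit (Wyman, Sloan &
  Shirley, JCGT 2013), clipped at zero. The fit deviates from the official
  tabulation by well under 1% of peak, and the same observer is used on the
  synthesis and the analysis side, so the pipeline is internally consistent.
* **Illuminant / white.** D65 by default (embedded 10 nm CIE tabulation,
  linearly interpolated); any illuminant can be supplied as a spectrum.
  Tristimulus scale: reference white Y = 100. Patch colours of composed NBI
  images are compared under the sRGB (D65) white.
* **Resampling.** Linear interpolation, zero outside tabulated support.
* **Grid.** 380–780 nm at 1 nm (401 bands) by default, configurable.

## The synthetic world

No measurement data ships with the package; `nbisim.synth` generates every
fixture with known ground truth.

* **Reflectances** are logistic-squashed sums of at most 4 Gaussian bumps
  with widths ≥ 40 nm (defaults: 3 bumps, widths 50–90 nm, amplitudes
  ±1.6). This makes them smooth, bounded in (0, 1), and of low intrinsic
  dimension — the regime in which six principal components suffice, chosen
  to mirror measured colour-target spectra. A separate generator produces
  spectra lying *exactly* in a low-dimensional affine span (scaled into
  mid-gray ± 0.35 so renders stay inside the sRGB gamut) for
  exact-recovery tests.
* **The camera** is colorimetric: its three sensitivities are nonnegative
  near-identity mixtures of the CMFs (so its raw response is a linear map
  of scene XYZ), with exposure 0.85 and an optional quadratic nonlinearity
  in XYZ. The nonlinearity is *declared* as the polynomial map g from
  camera XYZ back to scene XYZ; the render applies g⁻¹ by damped Newton
  iteration. Declaring the recovery direction makes the noiseless world
  exactly invertible by a polynomial feature expansion of matching degree,
  which is what anchors the < 1e-8 exact-recovery tests. Quadratic
  coefficients are drawn in ±0.03 (on XYZ/100), keeping the map safely
  monotone. Optional Gaussian sensor noise is added per pixel in linear
  RGB and requires an explicit seed.
* **Scenes** are 4×6 grids of 32×32 px constant patches (192×128 images).
* **The oracle NBI renderer** integrates the *true* reflectances against
  the band profiles with its own inline implementation — it never touches
  the reconstruction path — and returns the reference image plus per-patch
  Lab targets.

What the world does **not** emulate: anatomically realistic endoscopy
(vessels, specular highlights, lesions), spatial lens effects, demosaicing,
or continuous-tone histograms. Consequences: passing tests demonstrate the
correctness and self-consistency of the algorithmic pipeline and its
behaviour under a realistic measurement geometry; they do not demonstrate
clinical image quality. In particular, histogram-entropy comparisons on a
24-patch chart are intrinsically jumpy — the histogram is ~24 spikes, and
entropy moves only when two near-coincident patch luma values merge into or
split out of one bin, so single-scene entropy differences fluctuate in
~2% steps depending on the draw, whereas natural images with dense
histograms vary smoothly.

## Standard problem sizes

The reference study (`nbisim.workflow.run_synthetic_study`) uses the
24-patch world, the 192×128 scene, k = 6 components, the degree-3
expansion, and 2000-evaluation optimizer budgets for both the full
band-and-mix and the lighting-only runs; the whole study completes in well
under a minute on one CPU. Seeds for the camera and the two optimizer runs
are derived from the base seed as +1, +2, +3.

## Known limitations

* Metamerism bounds reconstruction fidelity: distinct spectra with equal
  corrected XYZ reconstruct identically. Only the colour-indexable
  component of spectral variation is recovered.
* The correction and mapping are least-squares fits to 24 training patches;
  generalization to colours far outside the target gamut is extrapolation
  of a degree-3 polynomial and is clamped, not trusted.
* The Lorentzian has heavy tails: at γ = 5 nm only ~90% of the full-line
  power lies within ±32 nm of the centre, so "narrow" bands still leak
  across the spectrum; band responses always use the truncated grid.
* Out-of-sRGB-gamut scene colours are clipped by the synthetic camera;
  exactness guarantees hold only for in-gamut worlds.
* No chromatic adaptation, 10° observer, or vendor-exact replication of
  commercial NBI processing.
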