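# nbisim

Narrow-band imaging (NBI) simulation from white-light endoscopy, via
RGB→hyperspectral reflectance reconstruction.

NBI endoscopes illuminate tissue with two narrow bands — 415 nm blue light
that reveals deep submucosal vessels and 540 nm green light that picks out
superficial capillaries — and this contrast helps endoscopists spot early
neoplastic change that ordinary white-light imaging (WLI) misses. Many
endoscopy systems lack NBI hardware. `nbisim` implements the software
alternative: calibrate the camera against a 24-patch colour target,
reconstruct a full 380–780 nm reflectance spectrum at every pixel of a WLI
frame, then relight that hypercube with narrow Lorentzian bands to produce
a simulated NBI view. It is aimed at researchers in biomedical imaging who
want a transparent, testable reference implementation of this pipeline.

## Method

With a colour target providing paired camera sRGB values and spectrometer
reflectance spectra for 24 patches:

1. **Calibration** — linearize sRGB, map to camera XYZ, expand into a
   degree-3 polynomial feature vector V, and regress onto the
   spectrum-derived tristimulus: `C = XYZ_spec · pinv(V)`,
   `XYZ_corr = C · V`.
2. **Spectral reconstruction** — mean-centred PCA of the patch spectra
   (k = 6 components), then `M = Score · pinv(V_color)` mapping colour
   features of corrected XYZ to PC scores, so each pixel's spectrum is
   `s(λ) = mean(λ) + EV·M·V_color`.
3. **NBI synthesis** — integrate the hypercube against Cauchy–Lorentz bands
   `f(λ; λ0, γ) = A γ/π / ((λ−λ0)² + γ²)` at 415/540 nm (plus weak
   600/700/780 nm bands), mix band images into display RGB, and optionally
   tune all band parameters by dual annealing against target patch colours
   (objective: mean CIEDE2000).
4. **Evaluation** — SSIM, PSNR, histogram entropy difference and CIEDE2000
   summaries against a reference render.

A synthetic-world module (`nbisim.synth`) generates smooth patch
reflectances, a configurable colorimetric camera with known polynomial
nonlinearity, patch-grid scenes, and an independent oracle NBI renderer, so
the whole pipeline is testable with known ground truth and no external
data. See `docs/methods.md` for model details and assumptions.

## Worked example

Generate a synthetic fixture, fit the models, convert the WLI render and
score it against the oracle NBI render:

```sh
nbisim simulate --out demo --seed 1
nbisim calibrate --rgb demo/patch_rgb.csv --spectra demo/patch_spectra.csv \
                 --out demo/model.json --report demo/report.csv
# post_mean_de00 0.000000
nbisim fit-spectral --rgb demo/patch_rgb.csv --spectra demo/patch_spectra.csv \
                    --model demo/model.json --out demo/spectral.json
# cumulative_explained_variance_percent 99.9708
nbisim convert --image demo/wli.png --model demo/model.json \
               --spectral demo/spectral.json --out demo/nbi.png
nbisim evaluate --test demo/nbi.png --reference demo/oracle_nbi.png
# ssim                  0.999834
# psnr_db               53.4819
# entropy_ref_bits      4.3350
# entropy_test_bits     4.5016
# entropy_diff_percent  3.8447
```

Reading the numbers: the calibration drives the mean training colour error
(CIEDE2000) to ~0 on this noiseless synthetic camera; six principal
components explain 99.97% of the patch-spectra variance; and the simulated
NBI image agrees with the independent ground-truth render at SSIM 0.9998
and PSNR 53 dB. The entropy difference is the most volatile statistic on a
24-patch chart — its histogram is a couple of dozen spikes, so a tiny
colour shift that merges two spikes into one 8-bit bin steps the entropy by
a few percent (see `docs/methods.md`).

The same study is available as a library call:

```python
from nbisim.workflow import run_synthetic_study
stats = run_synthetic_study(seed=1)
print(stats["reconstruction_mean_rmse"])   # 0.0352902...
print(stats["nbi_full_opt_mean_de00"])     # 0.101972...
```

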