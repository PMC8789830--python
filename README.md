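# octarec — accelerated OCT angiography reconstruction

OCT angiography (OCTA) images blood flow without contrast agents by
repeating B-scans at each slow-axis location and measuring how the
signal decorrelates: flowing blood decorrelates, static tissue does
not.  High-quality angiograms need dense raster sampling and ~8
repeats per location, which makes volumetric OCTA slow (17.8 s for a
fully-sampled 400×400, 8-repeat scan under the timing model used
here).  Undersampling the enface plane by a ratio r on both axes and
acquiring only 2 repeats cuts acquisition time by r²·(8/2) — 16× at
r = 2 (≈ 1.1 s), 64× at r = 4 (0.28 s), 256× at r = 8 (0.07 s) — at
the price of resolution and quality.

`octarec` recovers that loss with a two-stage convolutional generator:
a **super-resolution module** (9×9 low-level convolution, a *Deep
layer* of 3×3 PReLU convolution blocks wired densely or residually,
element-wise merge, pixel-shuffle upsampling) maps the undersampled
low-quality angiogram to full resolution, and a **quality-enhancement
module** (same design, shape-preserving) compensates for the missing
repeats.  Training minimizes a composite perceptual loss

    L = L_MAE + 0.8 · L_MS-SSIM + 7e-5 · L_FMAE

(mean absolute error, multiscale structural similarity, and the MAE
between 2-D Fourier magnitudes, which targets undersampling artifacts
in frequency space), optionally followed by an adversarial stage
(`L + 5e-3 · (−log D(G(X)))` against a batch-normalized leaky-ReLU
discriminator).  The package is written for researchers working on
fast OCTA protocols: it includes a synthetic vascular-phantom
generator (so the whole pipeline runs without any data download),
interpolation baselines (nearest/bicubic/Lanczos, plus a bilateral
filter), an evaluation suite (SSIM, MS-SSIM, PSNR, RMS contrast,
skeleton-based vessel connectivity), and a CLI.  The networks run on a
small numpy autodiff engine — no GPU or deep-learning framework is
required.

## Worked example

Generate phantoms, train the small dense-variant generator at ratio 2,
and compare against bicubic interpolation on held-out pairs:

```python
from octarec.experiments import generate_phantom_pairs, reconstruction_benchmark

pairs = generate_phantom_pairs(230, seed=0)   # 48x48 enface slices, r=2
result = reconstruction_benchmark(seed=0, connection="dense", pairs=pairs)
print(f"generator SSIM {result.gen_ssim:.4f}  "
      f"bicubic SSIM {result.bicubic_ssim:.4f}  margin {result.margin:.4f}")
```

prints (about two minutes on one CPU core):

```
generator SSIM 0.6003  bicubic SSIM 0.4581  margin 0.1421
```

Held-out structural similarity against the 8-repeat fully-sampled
ground truth: the trained generator (0.60) reconstructs vessel
structure that bicubic upsampling of the noisy 2-repeat input (0.46)
cannot, because interpolation can neither denoise nor restore the
repeat-count quality gap.

The same pipeline from the shell:

```bash
octarec simulate --grid 64 64 32 --repeats 8 --seed 0 --out runs/sim
octarec pair --volume runs/sim/series.tif --mask runs/sim/vessel_mask.tif \
             --ratio 2 --seed 0 --out runs/pairs
octarec train --manifest runs/pairs/manifest.csv --connection dense \
              --blocks 2 --channels 12 --epochs 15 --seed 0 --out runs/model
octarec evaluate --manifest runs/pairs/manifest.csv \
                 --checkpoint runs/model/generator.npz --out runs/eval
octarec speedup --ratio 2 --repeats 2
```

The last command prints the acquisition model for that protocol:

```
speed-up: 16x
acquisition time: 1.1 s
equivalent step size: 20 um
```

Every command writes its fully resolved configuration as
`config.yaml` next to its outputs, so a run is reproducible from that
file alone.  See `docs/methods.md` for the model, the phantom's
statistical design, and all numerical conventions.

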