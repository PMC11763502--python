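# flimupscale

Edge-preserving upscaling of fluorescence lifetime (FLIM) images.

Accumulating enough photons for a per-pixel lifetime fit makes
high-pixel FLIM slow: a 512×512 acquisition takes minutes, long enough
for living cells to move, bleach, or fragment their mitochondria.
`flimupscale` takes the opposite route — acquire fast at 256×256 or
128×128, then reconstruct a high-pixel image computationally. It is
aimed at FLIM users (confocal/TCSPC) who export an intensity image and a
fitted lifetime matrix (picoseconds, SPCImage-style ASCII) and want
2× or 4× more pixels without longer scans.

## What it computes

The intensity image and the lifetime matrix are interpolated
*separately*, then recombined as a pseudo-color image (lifetime → hue,
intensity → brightness). Two interpolators are provided:

**Bicubic (baseline).** Separable cubic convolution over the 4×4
neighborhood, f(i+s, j+t) = A·B·C, with the standard kernel

    R(x) = 1 − 2x² + x³        0 ≤ x < 1
         = 4 − 8x + 5x² − x³   1 ≤ x < 2
         = 0                   x ≥ 2

**Edge-preserving interpolation (EPIM).** A three-step 2× scheme:
source pixels are copied through bit-exactly; the in-between pixels are
filled by measuring, in a local window, the summed absolute variation
along four candidate directions (horizontal, vertical, two diagonals)
and interpolating *along the least-varying direction* — the edge — with
4-point cubic weights (−1/16, 9/16, 9/16, −1/16). Pixels whose photon
count was too low for a lifetime fit are excluded from every window and
stencil, with surviving weights renormalized, so no lifetime is ever
invented from unfitted background — the failure mode that gives plain
bicubic its halo of spurious lifetimes around bright structures. The
interpolated intensity image can additionally be sharpened by
gradient-guided wavelet detail gain with soft-threshold denoising.
Factor 4 applies the 2× pipeline twice. See `docs/methods.md` for the
full model.

## Worked example

Simulate a microsphere phantom (256×256 ground truth, decimated 2× to a
128×128 input), reconstruct with both methods, and compare:

```sh
flimupscale simulate --scene microspheres --size 256 --factor 2 --seed 7 --out demo
flimupscale reconstruct --prefix demo/lr --method epim+enhance --factor 2 --out demo/epim
flimupscale reconstruct --prefix demo/lr --method bicubic     --factor 2 --out demo/bicubic
flimupscale evaluate --gt demo/gt --candidate epim demo/epim \
                     --candidate bicubic demo/bicubic --out demo/report.json
```

which prints (abridged):

```json
{
  "bicubic": {
    "intensity_psnr_db": 30.371146776851987,
    "lifetime_mae_ps": 53.615800603280334,
    "histogram_l1": 0.12327521796747609,
    "n_valid_joint": 15913
  },
  "epim": {
    "intensity_psnr_db": 30.69199519799053,
    "lifetime_mae_ps": 43.93278390096769,
    "histogram_l1": 0.177852670508877,
    "n_valid_joint": 15914
  }
}
```

Reading the numbers: over the ~16k pixels where both the ground truth
and the reconstruction carry a fitted lifetime, the edge-preserving
method's lifetime error (43.9 ps mean absolute) is about 10 ps lower
than bicubic's (53.6 ps) — the gap concentrates at sphere boundaries,
where bicubic mixes unfitted background into its stencil — and its
intensity PSNR is ~0.3 dB higher. `histogram_l1` is the L1 distance
between normalized lifetime histograms (10 ps bins, 700–1400 ps);
`demo/epim_pseudocolor.png` is the rendered overlay (red = short
lifetime, blue = long, black = no fit).

The same pipeline is available as a library:

```python
from flimupscale import PhantomSpec, make_fixture_pair, compare
from flimupscale.pipeline import reconstruct_frame

lr, gt = make_fixture_pair(PhantomSpec(scene="microspheres", image_size=256, seed=7), 2)
rec = reconstruct_frame(lr, factor=2, method="epim+enhance")
print(compare(gt, {"epim": rec})["epim"].lifetime_mae_ps)
```

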