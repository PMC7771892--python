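# fpmsda

Background correction and denoising for Fourier Ptychographic Microscopy
(FPM) by **structure-dependent amplification (SdA)**, together with
everything needed to study it end to end on synthetic data: a coherent FPM
forward simulator with a realistic camera-noise model, a sequential
Gauss–Newton phase-retrieval reconstructor, the conventional background
corrections it is compared against, and an image-quality metric suite.

## The problem

FPM fuses many low-resolution images captured under oblique LED
illumination into one high-resolution complex image. Frames whose
illumination NA exceeds the objective NA (darkfield, typically 80–95% of
the dataset) carry only scattered light on top of a noisy camera
background b (stray light + dark current, read noise σ, shot noise). Any
uncorrected background in a darkfield frame is stamped into the recovered
spectrum at that frame's illumination wavevector; summed over hundreds of
frames these errors produce a high-frequency "orange-peel" artefact.
Subtracting a global estimate faces a hard trade-off:

* `mean` — subtract mean(background): too low a threshold, residual noise
  survives and artefacts dominate;
* `mean + 3σ` — subtract mean + 3·std: removes ~99.7% of a Gaussian
  background but also clips the weak darkfield signal, blurring away high
  spatial frequencies.

## The SdA method

SdA escapes the trade-off by using real-space redundancy across the stack
to classify pixels before thresholding. With all statistics taken over a
structure-free mask `M` (complement of the Otsu-binarized, disc-dilated
on-axis brightfield image):

1. `S2 = max(S1 − mean[S1(M)], 0)` per darkfield frame;
2. `I_BF`: binarized reciprocal of the brightfield sum, dilated — a
   conservative object map;
3. `I_DF = max(Σ_DF S2 − mean[Σ_DF S2 (M)], 0)` — per-pixel amplification
   weights from the darkfield sum;
4. `A = S2 · (I_DF·I_BF + I_BF^C)` boosts object pixels only, so that
5. `S2' = max(A·I_BF − (mean[A(M)] + 3·std[A(M)]), 0)` can threshold the
   background away without touching amplified signal;
6. `S3`: pixels with `S2' > 0` restored to their original `S2` values;
7. `S4`: equals `S3` for frames with signal-to-background ratio
   SBR = mean[S2(I_BF)]/mean[S2(M)] > 1; low-SBR frames instead carry
   `S2'` rescaled to the frame's `S2` maximum.

The reconstructor then uses `S4` for iterations 1…N−1 and `S3` for the
final iteration, removing background artefacts while keeping the
high-frequency content of noisy darkfield frames. An optional local
median filter cleans residual rim artefacts on the reconstructed
amplitude without touching any other pixel.

## Worked example

`examples/03_compare_background_methods.py` degrades a simulated
acquisition (constant offset 300 counts, shot noise, Gaussian σ = 1000)
and reconstructs it after each correction:

```
method      SSIM    MSE      SNR(dB)  contrast
mean        0.501   1331.0    16.66     0.847
mean3sigma  0.432   2403.5    35.46     0.433
sda         0.552   1113.3    33.13     0.824
```

Read it as the method's design goal in numbers: `mean` keeps bar contrast
(0.847) but its noisy background wrecks the reconstruction SNR (16.7 dB);
`mean + 3σ` has a clean background (35.5 dB) but halves the contrast
(0.433); SdA delivers both at once (33.1 dB, 0.824) and the lowest MSE
against the noise-free reference. The other examples show the forward
model and round-trip reconstruction (`01`), the SdA stage-by-stage
diagnostics (`02`), and the metric suite (`04`); each prints a short
explanation with its numbers.

A thin CLI mirrors the pipeline for shell use:

```bash
fpm-sda make-fixture --kind bars --shape 192 --pixel-size 0.27 --out obj.tif
fpm-sda simulate --object obj.tif --lr-shape 64 --offset 300 --sigma 1000 --gain 1 --out raw.tif
fpm-sda correct --stack raw.tif --method sda --s1 6 --s2 3 --out-s3 s3.tif --out-s4 s4.tif
fpm-sda reconstruct --stack s3.tif --stack-first s4.tif --hr-shape 192 --pixel-size 0.27 --out recon.tif
```

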