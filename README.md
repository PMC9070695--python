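# streakless

Two-stage, fully automatic sinogram-domain denoising of volumetric
tomography data.

Streak noise in raw projections — the precursor of ring artifacts in
reconstructed tomograms — is modeled as additive stationary noise with very
long range correlation (constant along the acquisition angle) and removed by
a coarse-to-fine multiscale procedure built around a PSD-aware volumetric
collaborative filter (stage 1).  The remaining Poissonian noise is then
attenuated through a data-driven variance-stabilizing transform, multiscale
3-D filtering with a streak-notched flat PSD, and an exact-unbiased inverse
(stage 2).  Both stages self-calibrate their filtering strength from the
data; no tuning input is required.

## Layout

| module | contents |
|---|---|
| `streakless.normalization` | bright/dark-field normalization, log transform |
| `streakless.noise_model` | correlation-kernel / PSD duality, streak component kernels per scale, binning-residual transfer, Poisson-stage PSDs |
| `streakless.noise_estimation` | MAD-based std probes (db3 / Gaussian separable kernels), non-negative least-squares unmixing into streak components |
| `streakless.binning` | exact summation binning/debinning along displacement (2-D), angle (1-D) and all axes (3-D) |
| `streakless.collab_filter` | volumetric collaborative filter: whitened block matching, 3-D DCT + Haar group transform, PSD-derived subband variances, hard-threshold + Wiener stages |
| `streakless.streak_pipeline` | extreme-streak pre-attenuation, multiscale streak removal with per-segment adaptive PSDs |
| `streakless.poisson_pipeline` | field correction, polynomial-variance VST with exact-unbiased inverse, multiscale Poisson denoising |
| `streakless.synthetic` | procedural phantom, streak/Poisson corruption model, SNR metric |
| `streakless.io` / `streakless.cli` | TIFF/HDF5 stack I/O and the command line |

Internal axis order is always `(angle, horizontal, vertical)`.

## CLI

```sh
# generate a synthetic fixture (Z noisy, Y streak-free, lnA clean)
streakless simulate --seed 1 --std 0.02 --peak 2560 --out fixtures/

# stage 1 only: multiscale streak removal of a log-domain stack
streakless streaks fixtures/Z.tiff --output Yhat.tiff [--scales K] \
    [--angular-target 32] [--segment 256] [--extreme-tau 4.0]

# stage 2 only: Poisson denoising (use --no-streak-notch on data that
# did not pass through the streak stage)
streakless poisson Yhat.tiff --bright B.tiff --dark D.tiff \
    --output Dhat.tiff [--kpoi 1] [--vst-degree 2] [--no-streak-notch]

# end to end: normalize -> log -> extreme streaks -> multiscale streaks
# -> Poisson stage; writes the streak-free intermediate too
streakless full P_raw.tiff --bright B.tiff --dark D.tiff \
    --output Dhat.tiff --intermediate Yhat.tiff
```

Inputs may be multi-page TIFF (one page per angle) or HDF5; the on-disk
axis order is declared with `--axis-order`.  Every run writes its resolved
configuration as a `.run.yaml` next to the output.

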