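# fanpat

Photoacoustic tomography (PAT) toolkit for a rotating arc-array breast
scanner with a fan-shaped diffuse illuminator.

PAT maps optical absorption by detecting the ultrasound that pulsed light
generates in tissue: the initial pressure is p₀(r) ∝ Ψ(r)·μₐ(r), fluence
times absorption. In the scanner modeled here, a 384-element transducer arc
(11.5 cm long, on a dome of 12 cm radius) rotates through 200 poses at 1.8°,
and a thin fan-shaped beam (90° × 0.24° divergence) rides along with it,
shining through an optical window in the dome. Because the light diverges
strongly and moves with the detector, the fluence inside the sample is
non-uniform *and different at every pose* — so recovering μₐ(r) requires
dividing each pose's reconstructed pressure by a per-pose fluence model
before the poses can be combined.

The toolkit implements the full chain:

- **simulate** — voxelized wire phantoms, a linear forward model
  (time-of-flight delays, 1/r spreading, Gaussian element directivity,
  per-pose fan fluence) and structured cross-channel band noise with
  per-pulse energy jitter;
- **preprocess** — fifth-order Butterworth low-pass at 14.5 MHz, truncated-SVD
  subtraction of the leading k = 10 singular components (the band noise), and
  pulse-energy normalization;
- **reconstruct** — universal back-projection: per voxel, the ramp-filtered
  record b(t) = p(t) − t·∂p/∂t evaluated at t = |r−r_D|/v_s, weighted by the
  element's solid angle dΩ₀ and the separable Gaussian directivity
  S₀(θ_L, θ_E) = exp(−θ_L²/2σ_L²)·exp(−θ_E²/2σ_E²) (σ_L = 18.5°, σ_E = 6.2°),
  normalized by the summed weights; then per-pose fluence compensation with
  the diffusion-approximation fan integral
  Ψ(r) = ∬_B exp(−μ_eff r)/(4πDr) dθ dφ;
- **evaluate** — SNR and FWHM from amplitude profiles, RMSE, SSIM, the
  relative image error ‖A−M‖₂/‖M‖₂ against the phantom model, and its
  depth-resolved version over 50 spherical shells from the detector surface.

See `docs/methods.md` for the model details and numerical choices.

## Worked example

`examples/03_reconstruct_and_evaluate.py` places two point absorbers with a
true 2:1 absorption ratio at equal depth — one in the fan plane, one
displaced elevationally where the thin fan delivers far less light —
simulates an acquisition, and reconstructs with and without fluence
compensation:

```
fluence ratio at the two absorbers: 16.3
true absorption ratio:        2.0
compensated peak ratio:       2.22
uncompensated peak ratio:     36.25
```

The uncompensated contrast is the absorption ratio times the fluence ratio
(≈ 2 × 16.3); dividing each pose by its modeled fluence recovers the true
2:1 within ~10 %. The other examples print the derived optical coefficients
(breast tissue: D = 0.0327 cm, μ_eff = 2.47 cm⁻¹) and demonstrate the
denoising chain.

## Command line

```sh
fanpat fixture three_wire            # write a ready-to-run config
fanpat run --config three_wire.yaml --outdir out/
fanpat reconstruct --in out/clean.h5 --config three_wire.yaml \
       --directivity on --fluence-comp on --out recon.nii.gz
```

RF scans are HDF5 (one channels × time dataset per pose), volumes NIfTI,
reports JSON; every artifact embeds the config hash.

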