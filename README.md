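# gpqpi

Simulation and single-shot reconstruction for **geometric-phase quantitative
phase imaging** — a common-path interference microscope in which the sample
and reference waves are polarization-coded (left/right circular), deflected
into opposite diffraction orders by a geometric-phase grating, and recombined
into an off-axis hologram whose carrier fringe period is *independent of
wavelength*. Because the carrier is achromatic, a single camera frame taken
under broadband, spatially incoherent illumination is enough to restore the
phase retardance quantitatively.

The package is aimed at people building or analyzing such instruments: it
provides a physics simulator with known ground truth (a piezo-stepped mirror,
a programmable SLM pixel grid, a polarization-directed flat lens, live-cell
dry-mass phantoms), the full reconstruction pipeline, and the quantification
layers used to characterize the method's precision and applications.

## Model

For spectral weights `w_λ` the recorded intensity is the incoherent sum of
two-beam interference patterns sharing one carrier `ν_c`:

```
I(x, y) = Σ_λ w_λ [ |s_λ|² + |r_λ|²
          + 2|s_λ||r_λ| cos(2π ν_c·(x, y) + Φ_s − Φ_r + 2π·OPD/λ) ]
```

The retardance `ΔΦ = Φ_s − Φ_r` is restored by Fourier sideband demodulation
and 2-D unwrapping, then converted to physical quantities:

- surface height (reflective double pass): `δz = λ ΔΦ / 4π`
- dry-mass surface density (Davies relation): `ρ = λ ΔΦ / (2π α · passes)`
  with `α = 0.18 µm³/pg`
- geometric-phase lens: `ΔΦ = 2φ`, `φ(x, y) = −π r²/(λ₀ f)`; the focused
  field is examined by band-limited angular-spectrum propagation, and at
  Fresnel number `N_F = a²/(λf) ≈ 1` the axial intensity follows
  `I(z) = (f/z)² sinc²(u/2π)`, `u = (π a²/λ)(1/z − 1/f)`, with its maximum
  shifted toward the lens.

Broadband coherence gating (coherence length `λ²/Δλ` = 7.2 µm for the
600/50 nm band), per-frame piston drift, detector read noise, shot noise at
a photon budget, and SLM inter-pixel crosstalk are all part of the forward
model.

## Worked example

```python
from gpqpi import scenes, hologram, reconstruct, quantify

scene = scenes.mirror_scene((256, 256), pitch_um=0.5, dz_nm=140.0)
spectrum = scenes.make_spectrum(600.0, 50.0, 21)          # 600/50 nm band
holo = hologram.form_hologram(scene, spectrum, carrier=(0.125, 0.0),
                              noise=hologram.NoiseSpec(photon_budget=1e4),
                              seed=0)
print(f"fringe contrast: {hologram.fringe_contrast(holo):.3f}")
pm = reconstruct.unwrap(reconstruct.wrapped_phase(reconstruct.demodulate(holo)))
hm = quantify.phase_to_height(pm, wavelength_nm=600.0)
interior = reconstruct.border_mask(hm.height_nm.shape)
print(f"reconstructed height: {hm.height_nm[interior].mean():.2f} nm")
print(f"spatial std: {hm.height_nm[interior].std():.3f} nm")
```

prints

```
fringe contrast: 0.996
reconstructed height: 140.14 nm
spatial std: 0.045 nm
```

— the 140 nm mirror displacement is recovered to 0.1 % from a single
broadband hologram, with a sub-0.05 nm shot-noise floor at this photon
budget. The same pipeline characterizes a polarization-directed lens:

```python
from gpqpi import experiments
lens = experiments.run_lens(seed=1)
print(f"fitted focal length: {lens['fitted_focal_length_mm']:.2f} mm")
print(f"max phase deviation: {lens['max_abs_error_rad']:.3f} rad")
```

```
fitted focal length: 100.01 mm
max phase deviation: 0.064 rad
```

A command-line runner wraps the experiment protocols:

```
gpqpi run stability --frames 300 --drift-nm 0.83 --seed 1
gpqpi run lens
gpqpi make-fixtures --outdir fixtures --seed 0
```

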