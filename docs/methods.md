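# Methods

## Forward model

The instrument is modeled in the fully incoherent, ideal-point-imaging
limit: the recorded hologram is an incoherent sum of monochromatic two-beam
interference patterns, one per sampled spectral line, all sharing a single
achromatic carrier frequency. This is exactly the regime in which the
retardance restoration is lossless, and it is the regime the downstream
pipeline needs; the full partially coherent transfer (finite source size,
finite NA) is outside scope, with an optional Gaussian PSF blur available as
a crude finite-NA stand-in. The carrier is imposed directly as a parameter
rather than derived from the grating/Fourier-lens geometry: achromaticity is
a design property of the optical train, and only the property matters to
reconstruction.

Scene phase is split into an **achromatic** part (geometric phase of the
lens, programmed liquid-crystal retardance — both wavelength independent by
physics) and an **optical-path** part in nanometres (mirror topography,
cellular dry mass), contributing `2π·OPD/λ` per line. This split is what
makes coherence gating emerge naturally: a 20 µm inter-arm path offset
collapses the fringe contrast of the 600/50 nm band (coherence length
`λ²/Δλ = 7.2 µm`) below 0.1 while a balanced interferometer stays above
0.99.

Jones calculus uses the circular basis `(e_L, e_R)` with LHCP = `(x̂+iŷ)/√2`
from the receiver's viewpoint; all handedness statements in tests are
relative to this convention. The grating operator swaps handedness and
imprints `±2φ`; `grating_deflection` takes the spatial period of one 2π
*phase* ramp explicitly, because the relation between the axis-rotation
period and the phase period is a property of the element the caller must
decide (a 9 µm phase period at 600 nm gives the 8° mutual angle between the
±1 orders).

## Noise model and calibration

Three noise sources, all driven by one seed per frame:

- **Piston drift** — per-frame Gaussian height-equivalent offset
  (default σ = 0.83 nm), the dominant temporal instability of a common-path
  interferometer. It enters as `4π·p/λ` per spectral line.
- **Shot noise** — Poisson at a photon budget (default 10⁴ per pixel).
- **Read noise** — additive Gaussian, expressed as a fraction of the mean
  noiseless intensity. When the injected amplitude is large, a stray-light
  pedestal (4× the read fraction) keeps the signal inside the detector's
  nonnegative range: without it, zero-clipping at fringe troughs rectifies
  the noise into a phase bias. The read-noise σ references the pre-pedestal
  mean so the response stays linear in the knob.

The blank-area height noise of the full chain is the calibrated quantity:
pilot reconstructions of blank holograms solve
`read² = target² − shot²` for the read amplitude and refine it over a few
fixed-point iterations (the chain is mildly nonlinear at large amplitudes).
The calibration is a property of the acquisition geometry — grid, pitch,
carrier, demodulation band — and is recomputed per experiment; pilot seeds
are disjoint from measurement seeds. The default target, 2.95 nm, makes the
simulated chain's spatial background noise match the instrument-class value
the protocols are designed around.

## Reconstruction

Demodulation multiplies the hologram by the conjugate carrier wave and
applies a circular low-pass at baseband — algebraically identical to
selecting the +1 sideband and shifting it to the origin, and exact for
carriers that do not fall on an FFT bin. Default bandwidth is half the
carrier magnitude. Two refinements matter in practice:

- **Zero-order removal.** A Gaussian low-pass estimate of the
  non-interference intensity (σ = 1.2/f_c, opaque at the carrier) is
  subtracted first; otherwise the apodization window leaks the strong DC
  term into the pass band, leaving a ~2 nm phase-ripple floor even on
  noiseless holograms.
- **Apodization.** A Tukey window with a 32-pixel taper per edge. A real
  window cannot bias the phase where it is positive; a wide taper only
  trades edge amplitude for strongly suppressed spectral leakage of the
  conjugate sideband. Quantitative comparisons exclude at least a 16-pixel
  border; protocols whose statistic is a field-wide maximum exclude the
  full 32-pixel apodized margin, where window attenuation amplifies phase
  noise.

Unwrapping uses reliability-sorted region growing
(`skimage.restoration.unwrap_phase`), which is exact up to a global 2π
offset on smooth wrapped inputs and degrades gracefully under noise; the
residue count of the wrapped input is reported as a quality diagnostic.
Polynomial background removal (default order 1, piston + tilt) uses
iterative MAD-based sigma-clipping so compact foreground objects — cells, a
programmed SLM block — do not drag the fit; an unclipped fit absorbs part of
the object signal into the estimated piston and visibly deflates dry-mass
totals.

For smooth calibrated objects (the parabolic lens) an optional denoising
step fits a second-order 2-D polynomial, Gaussian-smooths the residual
(σ = 10 µm, far below the 100 µm signal scale), and re-adds the trend. This
is exactly unbiased on polynomial profiles including at the borders, unlike
direct smoothing, and unlike a narrowed demodulation band it does not smear
the field-edge discontinuity into the interior (a 0.03 cycles/µm band was
tried and rejected for that reason: its edge ringing alone reached
0.11–0.15 rad).

## Experiment protocols and problem sizes

- **Temporal stability (σ_T)** — 300 flat-mirror frames, 256² at 0.5 µm
  pitch, 7 spectral lines; ROI-mean heights in nine diffraction-spot disks
  (radius 0.61λ/NA = 1.22 µm at NA 0.3) on a 3×3 lattice; σ per ROI over
  time, summarized mean ± spread.
- **Spatial noise (σ_Z)** — nine 20×20 µm² blank areas; per-ROI stds pooled
  over six independently regenerated holograms to tighten the estimator
  (the per-ROI estimate has few effective degrees of freedom because the
  demodulation band correlates neighboring pixels).
- **Piezo accuracy** — 0–1 µm staircase in 100 nm steps, five repeats. A
  single flat frame only defines phase modulo 2π, so, as in the physical
  experiment where the mirror moves gradually, the per-step field-mean
  wrapped phases (circular mean) are unwrapped *temporally* along the
  staircase (each step is 2.09 rad < π) and referenced to step zero.
  Per-step mean error and RMSE are reported. Converting with the central
  wavelength leaves a small real bias (`≈ dz·σ_λ²/λ₀²`, ≤ 1.3 nm at 1 µm)
  from the curvature of `1/λ` across the band.
- **SLM retardance** — two adjacent 20 µm pixels programmed at 3.09 and
  2.85 rad on a zero background, plus a non-addressed background frame
  reconstructed under the same noise and subtracted with wrapped
  arithmetic. Imaging 20 µm plateaus needs a pass band resolving ~5 µm, so
  this experiment runs at carrier 0.25 cycles/µm (band 0.125), not the
  metrology default of 0.125/0.0625. Pixel statistics use the central 50 %
  of each pixel's area and circular means reported on the SLM's [0, 2π)
  stroke range (the programmed strokes sit near the ±π wrap boundary).
- **Lens** — f = 100 mm, design wavelength 600 nm, 0.5×0.5 mm² field on a
  384² grid; full-band demodulation, unwrapping, detrended denoising;
  the reconstruction is aligned to the theoretical `2φ` up to piston + tilt
  (fitted on the difference) and the maximum absolute deviation is taken
  over the field minus the apodized margin. The focal length is fitted by
  least squares to `φ = −π r²/(λf) + piston + tilt`.
- **Axial intensity** — band-limited angular-spectrum propagation
  (Matsushima-style anti-aliasing limit, padding ×2) of `exp(iφ)` inside a
  circular aperture of half-width a = 0.25 mm, z ∈ [30, 300] mm in 0.5 mm
  steps. The closed-form Fresnel axial intensity is validated against a
  direct Fresnel quadrature (an independent brute-force oracle) to 2×10⁻⁴
  before the FFT propagator is compared with it. The analytic formula
  assumes a circular aperture; comparisons therefore mask the square field
  to the inscribed circle. At N_F ≈ 1 both routes put the global intensity
  maximum near z = 61 mm — far inside the paraxial focus — with coincident
  zero positions.
- **Cells** — phantoms are smooth non-overlapping Gaussian dry-mass blobs
  (σ 6–9 µm, i.e. 20–35 µm footprints typical of spread adherent cells;
  150–400 pg total mass; peak densities ~1–2 pg/µm²), placed with 3σ plus
  the apodized-margin clearance from the field edge, with per-frame area
  growth at constant mass for time-lapse series. Phase follows the inverse
  Davies relation with the double-pass factor. Cells are imaged at the
  higher carrier (their phase chirp reaches ~0.1 cycles/µm), segmented by
  marker-based watershed (Gaussian smoothing 1 µm; foreground threshold
  Otsu by default, overridden to 1.5 % of the map maximum for phantom
  recovery so Gaussian tails retain their mass; h-maxima markers at 10 % of
  the dynamic range; regions under 20 µm² dropped), measured per label, and
  tracked by greedy maximum-overlap matching (min overlap 0.3).

These sizes keep any single protocol in the seconds-to-tens-of-seconds
range while estimating each statistic with the same pipeline a larger run
would use.

## What the synthetic data does and does not show

The generators reproduce the *calibration physics* of the instrument class:
achromatic carrier formation, coherence gating, double-pass height
conversion, per-pixel programmable retardance, conjugate geometric-phase
imprinting, Davies mass–phase proportionality, and the stated noise
statistics. They do not attempt textured cells, refractive-index/thickness
decoupling, instrument drift beyond piston, detector MTF, or aberrations —
so passing tests demonstrate that the reconstruction and quantification
chain is correct and meets the stated precision under the modeled
conditions, not that it would meet them on any particular real microscope.

## Numerical choices and degenerate inputs

- Wrapped phase lives in (−π, π]; zero-amplitude pixels get phase 0 and a
  zero quality flag.
- Lossless Jones operators are unitary to 1e-12; the analyzer is an
  idempotent projector.
- The focal-length fit fails loudly on flat phase; `propagate` raises a
  sampling error (with the required pad factor) when the anti-aliasing band
  limit would pass fewer than two frequency samples.
- Spectra are sampled on ±2σ of the Gaussian band; a single sample or zero
  bandwidth degenerates to a monochromatic line.
- Hologram stacks quantize to uint16 with the scale stored in the JSON
  sidecar and reused on re-write, so write → read → write is
  byte-identical.

## Known limitations

Fresnel-kernel-free angular-spectrum propagation treats the scalar field
exactly, but the comparison target (the sinc² axial formula) is itself a
Fresnel-approximation result for a circular aperture, so agreement is
checked on maxima/zero positions and profile correlation rather than
pointwise. The piston-drift-only temporal model makes per-ROI σ_T nearly
identical across ROIs (the real instrument's ±0.23 nm spread across ROIs
has additional spatial structure the model does not include). SLM pixel
pitch is not a measured quantity here; 20 µm is a typical value for the
device class and is a free parameter.
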