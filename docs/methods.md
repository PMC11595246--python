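# Methods

## Signal model

The sample's vibrational response after impulsive excitation at delay
τ = 0 is modelled as a sum of damped sinusoids in the refractive index,

δn(τ) = Σᵢ Aᵢ · exp(−τ/T₂ᵢ) · sin(2π νᵢ τ + φᵢ),   τ ≥ 0,

with νᵢ = 100·c·Ωᵢ the optical frequency of a mode at Raman shift Ωᵢ
(cm⁻¹), T₂ᵢ its dephasing time and Aᵢ a dimensionless modulation depth.
Spectral-shift detection reads the probe's frequency shift, which is
proportional to the **first time-derivative** of δn; the simulator
evaluates that derivative analytically.  The pump-probe temporal overlap
adds a strong artifact near τ = 0, modelled as a Gaussian whose full
width at half maximum defaults to the 170 fs excitation pulse duration
(pulse durations are FWHM by the usual ultrafast-optics convention) and
whose amplitude defaults to 10× the largest per-line derivative
amplitude, so it dominates the raw record as on the instrument.

Detection is modelled at demodulated baseband: the AOM modulation and
lock-in demodulation appear only through their bandwidth consequences
(the delay-sampling step and the electronic filter limit), not as an RF
waveform.

## Acquisition geometry and timing

One `AcquisitionConfig` carries the scan geometry (Nx macro-pixels, Ny
lines, field of view) and the delay-line timing.  Two timing constants
are deliberately **independent**: the per-window delay span (4.5 ps per
25 μs window, giving the 16.67 fs per-sample step used for every delay
axis) and the delay scaling α_t = 161 fs/μs (used only for the
optical-to-electronic frequency conversions).  The instrument
calibration quotes both, and they are not numerically consistent with
each other; each is therefore used exactly in its own role rather than
derived from the other.

Delay axes are left-aligned and half-open: sample k of window w sits at
w·(mechanical step) + k·Δτ, so the trigger marks the scan start.
Consecutive windows stepped by 3 ps overlap by 1.5 ps of the 4.5 ps
span; registration concatenates windows along the delay axis in
acquisition order.

## Raw-record synthesis

Each scan line is a row of Nx·N_window segments.  A segment holds a
trigger pulse at its start followed by Nτ data samples of
envelope × transmission-map × trace (Raman channel) and
envelope × transmission-map (transmission channel).  The per-window
envelope is a raised-cosine-edged (Tukey) window with a configurable
edge fraction (default 0.2 of the window per ramp), matching the smooth
rise and fall of the delay line's diffraction efficiency; its endpoints
are exactly zero, which is what makes transmission normalization
non-trivial.  Per-line clock jitter — the mirror flyback is not a
multiple of the DAQ sample — is a uniform integer **circular** shift of
the whole row in [0, jitter_max]; a truncated acquisition zeroes the
tail of the final line.  All randomness flows from one seed; identical
inputs give bit-identical records.

What the generator does **not** emulate: pump-bandwidth roll-off of the
excitation efficiency (modes are excited with their configured
amplitude regardless of shift), detector nonlinearity, 1/f drift,
shot-noise scaling with transmitted power, spatial blur across
macro-pixel boundaries (each macro-pixel is a pure species), and RF
demodulation artifacts.  Passing tests therefore demonstrate the
correctness of the registration/processing algebra and the bandwidth
bookkeeping, not robustness to every systematic error of a real
instrument.

## Registration

Rising edges of the trigger channel (threshold: 50% of the per-line
dynamic range above the minimum, debounced at half a window) locate
every segment.  Rows are indexed circularly when extracting the Nτ
samples after each edge, which undoes the circular jitter exactly —
cubes are bit-identical for any jitter below Nτ/2.  A line with fewer
edges than expected is accepted as a truncated prefix: its missing
windows, and its last detected (possibly cut) window, are zero-filled
and masked; any other edge pattern raises a structured error naming the
line, since silently reinterpreting a malformed trigger train would be
worse than failing.  The samples-per-window period is the median
inter-edge spacing; a disagreement with the configured value is recorded
as a warning, and a single-window-per-line record (one edge per line)
falls back to the configured segment length.

## Spectral chain

Per pixel, in order:

1. **Transmission normalization** — elementwise division where the
   transmission exceeds a floor (default 10% of its per-trace maximum);
   below-floor samples (the envelope edges, and any noise-negative
   values) are marked invalid rather than divided, so no non-finite
   value can enter the chain.
2. **Window stitching** — the junction between windows n and n+1 is the
   delay where the falling envelope of n crosses the rising envelope of
   n+1 (their raised-cosine symmetry puts it mid-overlap).  Outside a
   guard band of ±3 samples around the junction each window contributes
   its own side; inside it both windows' valid samples are nodes
   (coincident delays averaged), and a modified-Akima piecewise cubic —
   slopes from secant-weighted averaging, continuous in value and first
   derivative, well-suited to decaying sinusoids — is fitted through all
   retained nodes and resampled onto a uniform axis at the window sample
   spacing.  Blending both windows in the overlap, rather than bridging
   a one-sided gap, keeps the stitch error negligible against the
   signal.
3. **Overlap masking** — samples before the cut delay (default 300 fs,
   ≈ 3.5 σ of the default overlap spike) are zeroed; the retained region
   is mean-subtracted (the derivative signal is zero-mean, and residual
   DC would leak into the 10–150 cm⁻¹ band) and apodized with a Tukey
   window of shape parameter 0.1 — a steep taper that sacrifices <10% of
   the trace.
4. **FFT** — the trace is zero-padded to 8× the next power of two (an
   explicit FFT length fixed from the full cube delay length gives every
   pixel one shared wavenumber axis) and transformed; the axis is
   rfftfreq converted to cm⁻¹ via the delay step.

**Spectral convention.**  `compute_spectrum` returns the intensity
(power, |F|²) spectrum by default, with |F| available via
`mode="magnitude"`.  Vibrational spectra are conventionally reported as
intensities, and the width bookkeeping follows from the choice: the
FWHM of a T-long rectangular-windowed line is 0.886/T in the intensity
spectrum versus 1.207/T in the amplitude spectrum.  With the intensity
convention a single 4.5 ps window resolves ≈ 8 cm⁻¹ and a stitched
five-window ~16.5 ps trace resolves just under 2 cm⁻¹, matching the
instrument's quoted single- and multi-window resolutions; the amplitude
convention cannot reach 2 cm⁻¹ at that span (its floor is 2.5 cm⁻¹).
Peak *positions* are identical in both modes.

Peak width is measured by `peak_stats` as the full width at half
maximum via linear interpolation of the half-maximum crossings around
the band-restricted argmax; a peak on the band edge is flagged.

## Chemical images and ROIs

Frequency slices take the nearest wavenumber bin (or a stated band
mean), optionally smoothed with a 2×2-support Gaussian kernel
(σ = 0.8 px sampled at offsets {0,1}²; an even-sized "Gaussian of size
2×2" has no centred form, so the kernel is corner-anchored) and
normalized either to the image maximum or to the brightest voxel of the
whole cube.  ROI spectra are per-bin means over the valid pixels of a
mask.

## Phantoms and study conditions

Two presets mirror the instrument's demonstration samples: a uniform
calibration crystal with a single narrow phonon at 90 cm⁻¹ (bismuth
germanate; T₂ default 10 ps) and a two-species sample of acetaminophen
(56 cm⁻¹) and anthracene (37 cm⁻¹) crystals plus a void region
(T₂ default 5 ps), laid out in thirds across the field of view.

Problem sizes used by the tests and the acceptance script: registration
round trips at the instrument frame geometry (64 macro-pixels × 63–64
lines × 270 samples); calibration-crystal recovery on a 16×16 grid and
two-species imaging on the full 64×64 grid (the per-pixel chain is
identical at any grid size); resolution figures from single-pixel
acquisitions with 1 and 5 windows.

Noise defaults are zero (the processing chain is deterministic and the
headline quantities are properties of the algebra, not the noise);
where a statement is only well-posed above a noise floor — "an empty
region's spectrum is flat", meaning no feature rises above 3× the
band median — the generator adds Gaussian noise of σ = 10⁻³ on both
signal channels, about 10% of the largest derivative amplitude,
a plausible single-sweep lock-in noise floor.

## Numerical choices and degenerate inputs

Trigger threshold 0.5 of dynamic range; debounce gap Nτ/2; stitch guard
±3 samples; transmission floor 0.1; overlap cut 300 fs; Tukey α 0.1;
pad factor 8 — all configurable, all recorded in spectrum/cube metadata
and CLI manifests.  Flat trigger rows error (except a flat final line,
treated as fully truncated); an all-below-floor transmission errors
naming the pixel; per-pixel failures inside cube processing flag the
pixel and abort only if every pixel fails; empty ROIs and out-of-range
slices are rejected.

## Known limitations

* Integer-sample registration only; no sub-sample edge interpolation.
* No lineshape fitting, baseline correction beyond mean subtraction, or
  denoising beyond the 2×2 slice filter.
* The pump-bandwidth excitation roll-off above ~160 cm⁻¹ is not
  modelled; simulated lines near the Nyquist/filter limits are excited
  at full strength.
* Real-time (streaming) operation is out of scope; the CLI is batch.
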