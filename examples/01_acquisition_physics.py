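"""Acquisition-physics calculators: what the delay-line timing implies.

The acousto-optic delay line advances 161 fs of pump-probe delay per
microsecond of laboratory time, so THz molecular vibrations appear as
MHz electronic signals at the lock-in amplifier.  This example prints
the bandwidth limits that follow.
"""

import timewrap as tw

cfg = tw.AcquisitionConfig()  # instrument defaults: 4.5 ps / 25 us, 270 samples

print(f"delay sampling step: {cfg.delay_step_fs:.2f} fs")
print(f"Nyquist-limited Raman shift: {tw.nyquist_max_shift(cfg.delay_step_fs):.0f} cm^-1")
print(f"29 THz vibration = {tw.wavenumber_from_frequency(29.0):.0f} cm^-1")
print(
    "a 160 cm^-1 vibration appears at "
    f"{tw.electronic_frequency(160.0, cfg.delay_scaling):.2f} MHz"
)
print(
    f"a {cfg.detection_filter:.0f} MHz detection filter passes shifts up to "
    f"{tw.max_shift_for_filter(cfg.detection_filter, cfg.delay_scaling):.0f} cm^-1"
)
print(
    "macro-pixel length over a 500 um FOV with 64 pixels: "
    f"{tw.macro_pixel_length(500.0, 64):.1f} um"
)

# Expected output: a 967 cm^-1 Nyquist ceiling, the 160 cm^-1 -> 0.77 MHz
# mapping, a 207 cm^-1 filter limit and ~7.8 um macro-pixels — the numbers
# that size the instrument's usable low-frequency Raman band.
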