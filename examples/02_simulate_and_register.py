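"""Simulate a time-wrapped raw acquisition and register it into cubes.

A calibration-crystal phantom (one phonon at 90 cm^-1) is rendered into
the three raw 2D channel records, with per-line clock jitter; trigger
rising edges then remap the records to (Ny, Nx, Ntau) cubes, removing
the jitter exactly.
"""

import numpy as np

import timewrap as tw

cfg = tw.AcquisitionConfig(n_macro_x=16, n_lines_y=8)
phantom = tw.bgo_phantom(cfg)
noise = tw.NoiseModel(raman_sigma=1e-3, jitter_max=15, seed=0)

raw = tw.simulate_acquisition(phantom, cfg, noise)
print(f"raw records: {raw.raman.shape[0]} lines x {raw.raman.shape[1]} samples")
print(f"aspect ratio per macro-pixel: {cfg.n_delay_samples} (time-wrapped)")

report = tw.validate_sync(raw)
print(f"sync: {report.edge_counts.sum()} trigger edges, period {report.period} samples")

cubes = tw.reshape_to_cubes(raw)
print(f"cube shape: {cubes.raman_cube.shape}  (Ny, Nx, Ntau)")
residual = np.max(
    np.abs(cubes.raman_cube - raw.ground_truth.raman_cube)
)
print(f"max |registered - ground truth|: {residual:.2e}  (additive noise only)")

# The registered cube differs from the clean ground truth only by the
# injected Gaussian noise: the per-line jitter (up to 15 samples) has been
# removed exactly by the trigger-edge registration.
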