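"""Multi-window stitching: five 4.5 ps windows into a ~16.5 ps trace.

The mechanical delay line steps the fast 4.5 ps scan by 3 ps between
windows; adjacent windows overlap by 1.5 ps and are joined where their
transmission envelopes cross, with a modified-Akima interpolant across
each seam.  The longer trace sharpens the spectral resolution.
"""

import numpy as np

import timewrap as tw

line = tw.VibrationalLine(center=90.0, amplitude=1.0, dephasing_time=100.0)
phantom = tw.Phantom(np.zeros((1, 1), dtype=int), {0: [line]})

for n_windows in (1, 5):
    cfg = tw.AcquisitionConfig(n_macro_x=1, n_lines_y=1, n_windows=n_windows)
    raw = tw.simulate_acquisition(phantom, cfg)
    hcube = tw.process_acquisition(raw)
    spec = tw.roi_spectrum(hcube, np.ones((1, 1), dtype=bool))
    stats = tw.peak_stats(spec, band=(10.0, 150.0))
    span_ps = (cfg.delay_span + (n_windows - 1) * cfg.mechanical_step)
    print(
        f"{n_windows} window(s), ~{span_ps:.1f} ps trace: "
        f"peak {stats.position:.2f} cm^-1, FWHM {stats.fwhm:.2f} cm^-1"
    )

# Stitching five windows shrinks the linewidth from ~8 cm^-1 to below
# 2 cm^-1 — the window-limited resolution scales inversely with the total
# delay span, at the cost of a slower acquisition.
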