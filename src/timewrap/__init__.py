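"""timewrap: time-wrapped hyperspectral acquisition and spectral processing
for time-domain coherent Raman point-scanning microscopy.

A fast acousto-optic delay line sweeps several picoseconds of pump-probe
delay during the slow X motion of a galvo scanner, wrapping the delay
dimension into the X axis of ordinary 2D frames.  This package simulates
those raw records, registers them into hyperspectral cubes using the
trigger channel, and processes them (transmission normalization,
multi-window stitching, overlap masking, zero-padded FFT) into
vibrational spectra and chemical images.
"""

from .physics import (
    AcquisitionConfig,
    DelayAxis,
    build_delay_axis,
    electronic_frequency,
    frequency_from_wavenumber,
    macro_pixel_length,
    max_shift_for_filter,
    nyquist_max_shift,
    psf_aspect_ratio,
    wavenumber_from_frequency,
)
from .register import (
    CubePair,
    EdgeTable,
    RegistrationError,
    SyncReport,
    build_edge_table,
    detect_rising_edges,
    infer_window_period,
    reshape_to_cubes,
    validate_sync,
)
from .simulate import (
    NoiseModel,
    Phantom,
    RawAcquisition,
    VibrationalLine,
    bgo_phantom,
    read_fixture,
    simulate_acquisition,
    transient_trace,
    transmission_envelope,
    two_species_phantom,
    two_species_rois,
    write_fixture,
)
from .spectral import (
    HyperCube,
    PeakStats,
    ProcessingParams,
    Spectrum,
    StitchedTrace,
    compute_spectrum,
    frequency_slice,
    mask_overlap,
    normalize_by_transmission,
    peak_stats,
    process_cube,
    roi_spectrum,
    stitch_windows,
)

__version__ = "0.1.0"


def process_acquisition(raw, params=None):
    """Convenience end-to-end chain: trigger registration then per-pixel
    spectral processing; returns the :class:`HyperCube`."""
    cubes = reshape_to_cubes(raw)
    return process_cube(cubes, params=params or ProcessingParams())
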