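"""Synthetic raw-acquisition generator.

Emulates the "time-wrapped" raster of a point-scanning microscope whose
fast acousto-optic delay line sweeps the pump-probe delay once per
macro-pixel: each scan line is a long row of (Nx * N_window) segments of
N_tau DAQ samples, recorded simultaneously on three analog channels
(Raman / lock-in, trigger, transmission).  The simulated physics:

* impulsively excited molecular vibrations produce a decaying oscillatory
  refractive-index modulation; spectral-shift detection reads out its
  first time-derivative;
* a strong pump-probe temporal-overlap spike near zero delay;
* the delay line's per-window transmission envelope with smooth
  falling/rising edges;
* one trigger pulse at the start of every delay scan;
* per-line clock jitter (the flyback time is not a multiple of the DAQ
  sample), modelled as an integer circular shift of the whole row;
* optionally a truncated final line.

Everything is deterministic under a fixed seed so the registration and
spectral stages can be tested bit-exactly against stored ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal.windows import tukey

from .physics import (
    AcquisitionConfig,
    DelayAxis,
    build_delay_axis,
    frequency_from_wavenumber,
)

__all__ = [
    "VibrationalLine",
    "Phantom",
    "NoiseModel",
    "GroundTruth",
    "RawAcquisition",
    "refractive_index_transient",
    "transient_trace",
    "transmission_envelope",
    "simulate_acquisition",
    "write_fixture",
    "read_fixture",
    "bgo_phantom",
    "two_species_phantom",
]

#: Default FWHM of the pump-probe overlap spike, fs (the excitation laser
#: pulse duration, quoted as usual as a full width at half maximum).
DEFAULT_OVERLAP_WIDTH = 170.0


@dataclass(frozen=True)
class VibrationalLine:
    """One Raman-active vibrational mode.

    center : Raman shift, cm^-1; amplitude : dimensionless modulation
    depth of the refractive-index transient; dephasing_time : exponential
    decay constant T2, ps; phase : initial phase, rad.
    """

    center: float
    amplitude: float = 1.0
    dephasing_time: float = 10.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.center < 0:
            raise ValueError("center must be >= 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.dephasing_time <= 0:
            raise ValueError("dephasing_time must be > 0")

    @property
    def cycles_per_fs(self) -> float:
        """Optical frequency of the mode in cycles per fs."""
        return frequency_from_wavenumber(self.center) * 1e-3  # THz -> 1/fs


@dataclass
class Phantom:
    """Spatial map of vibrational species over the macro-pixel grid.

    label_map : (Ny, Nx) integer species identifiers; species_table maps
    each identifier to its vibrational lines (an empty list is a
    Raman-silent region); transmission_map : (Ny, Nx) static transmission
    in (0, 1].
    """

    label_map: np.ndarray
    species_table: dict[int, list[VibrationalLine]]
    transmission_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map)
        if self.transmission_map is None:
            self.transmission_map = np.ones(self.label_map.shape)
        self.transmission_map = np.asarray(self.transmission_map, dtype=float)
        if self.transmission_map.shape != self.label_map.shape:
            raise ValueError("transmission_map shape must match label_map")
        if np.any(self.transmission_map <= 0) or np.any(self.transmission_map > 1):
            raise ValueError("transmission_map values must lie in (0, 1]")
        missing = set(np.unique(self.label_map)) - set(self.species_table)
        if missing:
            raise ValueError(f"labels without species_table entry: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_map.shape


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise and per-line trigger jitter."""

    raman_sigma: float = 0.0
    transmission_sigma: float = 0.0
    jitter_max: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.raman_sigma < 0 or self.transmission_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.jitter_max < 0 or int(self.jitter_max) != self.jitter_max:
            raise ValueError("jitter_max must be a non-negative integer")


@dataclass
class GroundTruth:
    """Clean per-pixel signals the pipeline should recover.

    raman_cube / transmission_cube : (Ny, Nx, N_window*N_tau) exactly what
    trigger registration yields under zero noise and jitter;
    transient : same shape, the pure detected transient without envelope
    or static transmission (what normalization + stitching recovers).
    """

    raman_cube: np.ndarray
    transmission_cube: np.ndarray
    transient: np.ndarray


@dataclass
class RawAcquisition:
    """Three co-registered 2D channel records plus their configuration."""

    raman: np.ndarray
    trigger: np.ndarray
    transmission: np.ndarray
    config: AcquisitionConfig
    ground_truth: GroundTruth | None = None
    truncated_samples: int = 0

    def __post_init__(self) -> None:
        if not (self.raman.shape == self.trigger.shape == self.transmission.shape):
            raise ValueError("the three channels must share one shape")


def refractive_index_transient(
    lines: list[VibrationalLine], tau_fs: np.ndarray
) -> np.ndarray:
    """Underlying refractive-index modulation (not its derivative).

    Sum over modes of A*exp(-tau/T2)*sin(2*pi*f*tau + phi) for tau >= 0,
    zero before the pump arrives.
    """
    tau = np.asarray(tau_fs, dtype=float)
    out = np.zeros_like(tau)
    pos = tau >= 0
    for ln in lines:
        t2_fs = ln.dephasing_time * 1e3
        out[pos] += (
            ln.amplitude
            * np.exp(-tau[pos] / t2_fs)
            * np.sin(2 * np.pi * ln.cycles_per_fs * tau[pos] + ln.phase)
        )
    return out


def transient_trace(
    lines: list[VibrationalLine],
    axis: DelayAxis,
    overlap_width: float = DEFAULT_OVERLAP_WIDTH,
    overlap_amplitude: float = 0.0,
) -> np.ndarray:
    """Detected trace: analytic d/dtau of the refractive-index transient
    plus a Gaussian pump-probe overlap spike centred at tau = 0.

    Spectral-shift detection reads the probe's red/blue shift, which is
    proportional to the first time-derivative of the index modulation.
    ``overlap_width`` is the Gaussian full width at half maximum in fs.
    An empty line list yields the pure spike.
    """
    tau = axis.values
    out = np.zeros_like(tau)
    pos = tau >= 0
    for ln in lines:
        t2_fs = ln.dephasing_time * 1e3
        w = 2 * np.pi * ln.cycles_per_fs
        arg = w * tau[pos] + ln.phase
        out[pos] += (
            ln.amplitude
            * np.exp(-tau[pos] / t2_fs)
            * (w * np.cos(arg) - np.sin(arg) / t2_fs)
        )
    if overlap_amplitude != 0.0:
        sigma = overlap_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        out = out + overlap_amplitude * np.exp(-(tau**2) / (2.0 * sigma**2))
    return out


def transmission_envelope(n_samples: int, edge_fraction: float = 0.2) -> np.ndarray:
    """Per-window delay-line diffraction-efficiency envelope in [0, 1].

    Raised-cosine rise over ``edge_fraction`` of the window, flat top at
    1, symmetric raised-cosine fall (a Tukey window of shape parameter
    2*edge_fraction); first and last sample are exactly 0.
    """
    if not 0 < edge_fraction < 0.5:
        raise ValueError("edge_fraction must lie strictly in (0, 0.5)")
    return tukey(n_samples, alpha=2 * edge_fraction)


def _peak_derivative_amplitude(phantom: Phantom) -> float:
    amps = [
        2 * np.pi * ln.cycles_per_fs * ln.amplitude
        for lines in phantom.species_table.values()
        for ln in lines
    ]
    return max(amps) if amps else 1.0


def simulate_acquisition(
    phantom: Phantom,
    config: AcquisitionConfig,
    noise: NoiseModel = NoiseModel(),
    edge_fraction: float = 0.2,
    overlap_width: float = DEFAULT_OVERLAP_WIDTH,
    overlap_amplitude: float | None = None,
    truncate_last: int = 0,
) -> RawAcquisition:
    """Render a phantom into the raw time-wrapped 2D records.

    For each line y, macro-pixel x and window w (in acquisition order) a
    trigger pulse is written, then N_tau samples of
    envelope * transmission_map * transient into the Raman channel and
    envelope * transmission_map into the transmission channel.  One
    uniform integer circular shift in [0, jitter_max] is applied per line,
    and the final line may be truncated by ``truncate_last`` samples.

    ``overlap_amplitude`` defaults to 10x the largest per-line derivative
    amplitude, so the overlap spike dominates the raw record as it does
    on the instrument.
    """
    ny, nx = phantom.shape
    if (ny, nx) != (config.n_lines_y, config.n_macro_x):
        raise ValueError(
            f"phantom shape {phantom.shape} does not match config "
            f"({config.n_lines_y}, {config.n_macro_x})"
        )
    ntau = config.n_delay_samples
    if noise.jitter_max >= ntau / 2:
        raise ValueError("jitter_max >= n_delay_samples/2 would defeat registration")
    if overlap_amplitude is None:
        overlap_amplitude = 10.0 * _peak_derivative_amplitude(phantom)

    nw = config.n_windows
    seg = config.samples_per_segment
    lead = config.trigger_lead
    envelope = transmission_envelope(ntau, edge_fraction)

    # one clean trace per (species, window); phase-locked excitation makes
    # every pixel of a species identical up to its static transmission
    axes = [build_delay_axis(config, w) for w in range(nw)]
    species_traces = {
        s: np.concatenate(
            [
                transient_trace(lines, ax, overlap_width, overlap_amplitude)
                for ax in axes
            ]
        )
        for s, lines in phantom.species_table.items()
    }

    transient = np.zeros((ny, nx, nw * ntau))
    for s, tr in species_traces.items():
        transient[phantom.label_map == s] = tr
    tmap = phantom.transmission_map[..., None]
    env_full = np.tile(envelope, nw)
    clean_raman = env_full * tmap * transient
    clean_trans = env_full * tmap * np.ones_like(transient)

    # lay segments out along each row: [trigger_lead pad | N_tau data] each
    raman = np.zeros((ny, nx, nw, seg))
    trans = np.zeros((ny, nx, nw, seg))
    raman[..., lead:] = clean_raman.reshape(ny, nx, nw, ntau)
    trans[..., lead:] = clean_trans.reshape(ny, nx, nw, ntau)
    raman = raman.reshape(ny, nx * nw * seg)
    trans = trans.reshape(ny, nx * nw * seg)

    trig = np.zeros((ny, nx, nw, seg))
    pulse_width = max(2, ntau // 20)
    trig[..., :pulse_width] = 1.0
    trig = trig.reshape(ny, nx * nw * seg)

    rng = np.random.default_rng(noise.seed)
    jitter = (
        rng.integers(0, noise.jitter_max + 1, size=ny)
        if noise.jitter_max > 0
        else np.zeros(ny, dtype=int)
    )
    if noise.raman_sigma > 0:
        raman = raman + rng.normal(0.0, noise.raman_sigma, raman.shape)
    if noise.transmission_sigma > 0:
        trans = trans + rng.normal(0.0, noise.transmission_sigma, trans.shape)

    for y in range(ny):
        if jitter[y]:
            raman[y] = np.roll(raman[y], jitter[y])
            trig[y] = np.roll(trig[y], jitter[y])
            trans[y] = np.roll(trans[y], jitter[y])

    if truncate_last > 0:
        if truncate_last >= raman.shape[1]:
            raise ValueError("truncate_last must be smaller than the row length")
        raman[-1, -truncate_last:] = 0.0
        trig[-1, -truncate_last:] = 0.0
        trans[-1, -truncate_last:] = 0.0

    gt = GroundTruth(
        raman_cube=clean_raman,
        transmission_cube=clean_trans,
        transient=transient,
    )
    return RawAcquisition(
        raman=raman,
        trigger=trig,
        transmission=trans,
        config=config,
        ground_truth=gt,
        truncated_samples=truncate_last,
    )


def write_fixture(raw: RawAcquisition, path: str | Path) -> None:
    """Persist an acquisition (channels, config, ground truth) losslessly."""
    from . import io

    io.write_fixture(raw, path)


def read_fixture(path: str | Path) -> RawAcquisition:
    """Load an acquisition written by :func:`write_fixture`."""
    from . import io

    return io.read_fixture(path)


# --------------------------------------------------------------------------
# phantom presets

#: Low-frequency phonon of the BGO (bismuth germanate) calibration crystal.
BGO_SHIFT_CM = 90.0
#: Strongest low-frequency lattice modes of the two-species test sample.
ACETAMINOPHEN_SHIFT_CM = 56.0
ANTHRACENE_SHIFT_CM = 37.0


def bgo_phantom(
    config: AcquisitionConfig, dephasing_time: float = 10.0
) -> Phantom:
    """Uniform calibration-crystal phantom: one narrow phonon at 90 cm^-1."""
    label = np.zeros((config.n_lines_y, config.n_macro_x), dtype=int)
    table = {0: [VibrationalLine(BGO_SHIFT_CM, 1.0, dephasing_time)]}
    return Phantom(label_map=label, species_table=table)


def two_species_phantom(
    config: AcquisitionConfig, dephasing_time: float = 5.0
) -> Phantom:
    """Two crystal species plus a void region over the field of view.

    Left third: acetaminophen (56 cm^-1); middle third: anthracene
    (37 cm^-1); right third: void (no Raman-active mode, transmission
    only).  Region masks are available via :func:`two_species_rois`.
    """
    ny, nx = config.n_lines_y, config.n_macro_x
    label = np.full((ny, nx), 2, dtype=int)
    label[:, : nx // 3] = 0
    label[:, nx // 3 : 2 * nx // 3] = 1
    table = {
        0: [VibrationalLine(ACETAMINOPHEN_SHIFT_CM, 1.0, dephasing_time)],
        1: [VibrationalLine(ANTHRACENE_SHIFT_CM, 1.0, dephasing_time)],
        2: [],
    }
    return Phantom(label_map=label, species_table=table)


def two_species_rois(phantom: Phantom) -> dict[str, np.ndarray]:
    """Boolean ROI masks for the two-species phantom's three regions."""
    return {
        "acetaminophen": phantom.label_map == 0,
        "anthracene": phantom.label_map == 1,
        "void": phantom.label_map == 2,
    }
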