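"""Acquisition timing/geometry model and unit conversions.

The acousto-optic programmable dispersive filter (AOPDF, "Dazzler") sweeps
several picoseconds of pump-probe optical delay within tens of microseconds
of laboratory time.  The ratio of the two, the delay scaling ``alpha_t``
(fs of optical delay per us of lab time), maps molecular vibration
frequencies (THz) down to electronic frequencies (MHz) at the detector.
This module holds that mapping, the Nyquist/filter bandwidth limits it
implies, and the scan geometry of the "macro-pixel" raster.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.constants import c as _C  # speed of light, m/s

__all__ = [
    "AcquisitionConfig",
    "DelayAxis",
    "wavenumber_from_frequency",
    "frequency_from_wavenumber",
    "electronic_frequency",
    "max_shift_for_filter",
    "nyquist_max_shift",
    "macro_pixel_length",
    "psf_aspect_ratio",
    "build_delay_axis",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Scan geometry and delay-line timing of one hyperspectral acquisition.

    Defaults are the instrument settings of the reference acquisition:
    a 4.5 ps delay span swept in 25 us per macro-pixel, sampled with 270
    points, 161 fs/us delay scaling, 64 macro-pixels over a 64 um field
    of view.

    Parameters
    ----------
    n_macro_x : int
        Number of macro-pixels Nx along the slow-scanned X axis.
    n_lines_y : int
        Number of scan lines Ny.
    n_delay_samples : int
        DAQ samples per delay window (N_tau).
    window_duration : float
        Laboratory time of one delay scan, us; equals the macro-pixel
        dwell time.
    delay_span : float
        Optical delay covered by one window, ps.
    delay_scaling : float
        alpha_t, fs of optical delay per us of laboratory time.
    fov : float
        Field of view along X, um.
    n_windows : int
        Number of delay windows recorded per macro-pixel.
    mechanical_step : float
        Mechanical delay increment between consecutive windows, ps.
    mod_freq : float
        AOM modulation frequency, MHz.
    lia_integration : float
        Lock-in integration time, ns.
    detection_filter : float
        Electronic low-pass bandwidth, MHz.
    trigger_lead : int
        Samples by which the trigger rising edge precedes data validity.
    """

    n_macro_x: int = 64
    n_lines_y: int = 64
    n_delay_samples: int = 270
    window_duration: float = 25.0
    delay_span: float = 4.5
    delay_scaling: float = 161.0
    fov: float = 64.0
    n_windows: int = 1
    mechanical_step: float = 3.0
    mod_freq: float = 12.0
    lia_integration: float = 100.0
    detection_filter: float = 1.0
    trigger_lead: int = 0

    def __post_init__(self) -> None:
        for name in ("n_macro_x", "n_lines_y", "n_delay_samples", "n_windows"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in (
            "window_duration",
            "delay_span",
            "delay_scaling",
            "fov",
            "mechanical_step",
            "mod_freq",
            "lia_integration",
            "detection_filter",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.trigger_lead < 0:
            raise ValueError("trigger_lead must be >= 0")

    @property
    def delay_step_fs(self) -> float:
        """Optical delay between consecutive samples, fs."""
        return self.delay_span * 1e3 / self.n_delay_samples

    @property
    def samples_per_segment(self) -> int:
        """Raw samples allocated per (macro-pixel, window) segment."""
        return self.trigger_lead + self.n_delay_samples

    @property
    def row_length(self) -> int:
        """Raw samples per scan line."""
        return self.n_macro_x * self.n_windows * self.samples_per_segment

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "AcquisitionConfig":
        """Load from a YAML or JSON document with exactly these field names."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data)


@dataclass(frozen=True)
class DelayAxis:
    """Ordered optical delays, fs, for one window's retained samples."""

    values: np.ndarray
    origin: float = 0.0  # delay of pump-probe overlap, fs

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.size == 0:
            raise ValueError("DelayAxis must hold at least one sample")
        if v.size > 1 and not np.all(np.diff(v) > 0):
            raise ValueError("DelayAxis values must be strictly increasing")

    @property
    def step(self) -> float:
        """Sample spacing, fs (uniform within a window)."""
        if self.values.size < 2:
            raise ValueError("step undefined for a single-sample axis")
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.values.size


def wavenumber_from_frequency(f_thz: float) -> float:
    """Convert a vibration frequency (THz) to a Raman shift (cm^-1)."""
    if f_thz < 0:
        raise ValueError("frequency must be >= 0")
    return f_thz * 1e12 / (100.0 * _C)


def frequency_from_wavenumber(shift_cm: float) -> float:
    """Convert a Raman shift (cm^-1) to a vibration frequency (THz); exact inverse."""
    if shift_cm < 0:
        raise ValueError("Raman shift must be >= 0")
    return shift_cm * 100.0 * _C / 1e12


def electronic_frequency(shift_cm: float, scaling: float) -> float:
    """Electronic (lock-in) frequency, MHz, at which a Raman shift appears.

    The delay line advances ``scaling`` fs of optical delay per us of lab
    time, a dimensionless ratio scaling*1e-9; the vibration's optical
    frequency (shift*100*c Hz) is slowed by that ratio.
    """
    if shift_cm < 0:
        raise ValueError("Raman shift must be >= 0")
    if scaling <= 0:
        raise ValueError("delay scaling must be > 0")
    f_opt_hz = shift_cm * 100.0 * _C
    return f_opt_hz * (scaling * 1e-9) / 1e6


def max_shift_for_filter(filter_bw_mhz: float, scaling: float) -> float:
    """Largest Raman shift (cm^-1) passed by an electronic low-pass filter.

    Exact inverse of :func:`electronic_frequency` evaluated at the filter
    edge.
    """
    if filter_bw_mhz <= 0:
        raise ValueError("filter bandwidth must be > 0")
    if scaling <= 0:
        raise ValueError("delay scaling must be > 0")
    f_opt_hz = filter_bw_mhz * 1e6 / (scaling * 1e-9)
    return f_opt_hz / (100.0 * _C)


def nyquist_max_shift(delay_step_fs: float) -> float:
    """Largest resolvable Raman shift (cm^-1) for a delay sampling step (fs)."""
    if delay_step_fs <= 0:
        raise ValueError("delay step must be > 0")
    f_max_thz = 1.0 / (2.0 * delay_step_fs * 1e-15) / 1e12
    return wavenumber_from_frequency(f_max_thz)


def macro_pixel_length(fov: float, n_macro_x: int) -> float:
    """Macro-pixel extent along X, um: the distance the mirror sweeps
    during one delay scan, FOV / Nx."""
    if n_macro_x < 1:
        raise ValueError("n_macro_x must be >= 1")
    if fov <= 0:
        raise ValueError("fov must be > 0")
    return fov / n_macro_x


def psf_aspect_ratio(fov: float, n_macro_x: int, y_resolution: float) -> float:
    """X/Y aspect ratio of the elongated macro-pixel point-spread function."""
    if y_resolution <= 0:
        raise ValueError("y_resolution must be > 0")
    return macro_pixel_length(fov, n_macro_x) / y_resolution


def build_delay_axis(config: AcquisitionConfig, window_index: int = 0) -> DelayAxis:
    """Uniform delay axis of one window, offset by the mechanical step.

    Sample k of window w sits at ``w*mechanical_step*1e3 + k*delay_step_fs``
    fs (left-aligned, half-open: the last sample is one step short of the
    nominal span end).
    """
    if not 0 <= window_index < config.n_windows:
        raise ValueError(
            f"window_index {window_index} out of range [0, {config.n_windows})"
        )
    offset = window_index * config.mechanical_step * 1e3
    values = offset + np.arange(config.n_delay_samples) * config.delay_step_fs
    return DelayAxis(values=values, origin=0.0)
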