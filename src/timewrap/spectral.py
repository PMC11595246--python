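"""From registered cubes to vibrational spectra and chemical images.

Per-pixel chain: divide the Raman trace by the delay-line transmission
(which also marks the attenuated window edges invalid), stitch the
mechanically stepped delay windows into one long time trace with a
modified-Akima interpolant across each junction, excise the pump-probe
overlap spike with a tapered-cosine (Tukey) gate, and Fourier-transform
the zero-padded trace to a spectrum on a wavenumber axis.  Frequency
slices of the resulting hypercube are the chemical images; ROI averages
of it are the per-compound spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.constants import c as _C
from scipy.interpolate import Akima1DInterpolator
from scipy.signal.windows import tukey

from .physics import AcquisitionConfig, DelayAxis, build_delay_axis
from .register import CubePair

__all__ = [
    "ProcessingParams",
    "StitchedTrace",
    "Spectrum",
    "HyperCube",
    "PeakStats",
    "normalize_by_transmission",
    "stitch_windows",
    "mask_overlap",
    "compute_spectrum",
    "process_cube",
    "frequency_slice",
    "roi_spectrum",
    "peak_stats",
]


@dataclass(frozen=True)
class ProcessingParams:
    """Tunables of the per-pixel spectral chain.

    floor_fraction : transmission validity floor as a fraction of the
    per-trace maximum; guard : valid samples dropped on each side of a
    stitch junction before the modified-Akima refit; cut_delay : fs,
    delay below which the overlap spike is gated out; tukey_alpha :
    shape of the tapered-cosine apodization (0 = rectangular gate);
    pad_factor : zero-padding multiple of the next power of two;
    mode : "power" (intensity, the default spectral convention) or
    "magnitude".
    """

    floor_fraction: float = 0.1
    guard: int = 3
    cut_delay: float = 300.0
    tukey_alpha: float = 0.1
    pad_factor: int = 8
    mode: str = "power"


@dataclass
class StitchedTrace:
    """A single uniform time trace assembled from one or more windows."""

    delays: np.ndarray  # fs, strictly increasing, uniform
    values: np.ndarray
    junctions: np.ndarray = field(default_factory=lambda: np.asarray([], dtype=int))
    window_labels: np.ndarray | None = None  # source window per sample

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.delays.shape != self.values.shape:
            raise ValueError("delays and values must share one shape")
        if self.delays.size > 1 and not np.all(np.diff(self.delays) > 0):
            raise ValueError("delays must be strictly increasing")

    @property
    def step(self) -> float:
        return float(self.delays[1] - self.delays[0])

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.delays.size


@dataclass
class Spectrum:
    """Wavenumber axis (cm^-1, uniform, starting at 0) and spectral values."""

    wavenumbers: np.ndarray
    magnitude: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def bin_width(self) -> float:
        return float(self.wavenumbers[1] - self.wavenumbers[0])


@dataclass
class HyperCube:
    """(Ny, Nx, Nfreq) spectral magnitudes on one shared wavenumber axis."""

    data: np.ndarray
    wavenumbers: np.ndarray
    pixel_valid: np.ndarray
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PeakStats:
    position: float  # cm^-1
    fwhm: float  # cm^-1
    height: float
    on_edge: bool = False


def normalize_by_transmission(
    raman: np.ndarray,
    transmission: np.ndarray,
    floor_fraction: float = 0.1,
    pixel: tuple | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Divide the Raman trace by the delay-line transmission.

    Samples where the transmission falls below ``floor_fraction`` of its
    maximum (the attenuated window edges) are marked invalid and left
    untouched rather than divided, so no infinities can appear.

    Returns (normalized trace, boolean validity mask).
    """
    raman = np.asarray(raman, dtype=float)
    transmission = np.asarray(transmission, dtype=float)
    if raman.shape != transmission.shape:
        raise ValueError("raman and transmission traces must share one shape")
    floor = floor_fraction * transmission.max()
    # noise can push edge samples slightly negative; the floor excludes them
    valid = transmission >= floor if floor > 0 else np.zeros(raman.shape, dtype=bool)
    if not valid.any():
        where = f" at pixel {pixel}" if pixel is not None else ""
        raise ValueError(f"transmission entirely below floor{where}")
    out = np.zeros_like(raman)
    out[valid] = raman[valid] / transmission[valid]
    return out, valid


def _trim_to_valid(trace: np.ndarray, axis: DelayAxis, valid: np.ndarray):
    """Restrict to the contiguous valid span of a single window."""
    idx = np.flatnonzero(valid)
    first, last = idx[0], idx[-1]
    return trace[first : last + 1], axis.values[first : last + 1]


def _envelope_crossing(
    ax_fall: np.ndarray, env_fall: np.ndarray, ax_rise: np.ndarray, env_rise: np.ndarray
) -> float:
    """Delay at which window n's falling envelope meets window n+1's rising one."""
    lo = max(ax_fall[0], ax_rise[0])
    hi = min(ax_fall[-1], ax_rise[-1])
    if hi <= lo:
        raise ValueError("adjacent windows do not overlap in delay")
    grid = np.linspace(lo, hi, 512)
    diff = np.interp(grid, ax_fall, env_fall) - np.interp(grid, ax_rise, env_rise)
    sign_change = np.flatnonzero(np.diff(np.signbit(diff)))
    if sign_change.size == 0:
        raise ValueError("no envelope crossing found between adjacent windows")
    i = sign_change[0]
    # linear interpolation of the zero of diff
    frac = diff[i] / (diff[i] - diff[i + 1])
    return float(grid[i] + frac * (grid[i + 1] - grid[i]))


def stitch_windows(
    traces: list[np.ndarray],
    axes: list[DelayAxis],
    envelopes: list[np.ndarray],
    masks: list[np.ndarray] | None = None,
    guard: int = 3,
    floor_fraction: float = 0.1,
) -> StitchedTrace:
    """Recombine mechanically stepped delay windows into one time trace.

    For each adjacent pair the junction is placed where the falling
    transmission envelope of window n crosses the rising envelope of
    window n+1; window-n samples before the crossing and window-(n+1)
    samples after it are kept.  Within ``guard`` samples of each junction
    both windows' valid data contribute (coincident delays averaged), and
    a modified-Akima ("makima") piecewise cubic — continuous in value and
    first derivative, appropriate for sums of decaying sinusoids — is
    fitted through the retained points and resampled onto a uniform axis
    at the per-window sample spacing.

    A single window is returned unchanged on its own (trimmed) axis.
    """
    if not traces:
        raise ValueError("no windows to stitch")
    if not (len(traces) == len(axes) == len(envelopes)):
        raise ValueError("traces, axes and envelopes must have equal lengths")
    if masks is None:
        masks = [e >= floor_fraction * np.max(e) for e in envelopes]

    if len(traces) == 1:
        vals, dels = _trim_to_valid(traces[0], axes[0], masks[0])
        return StitchedTrace(
            delays=dels,
            values=vals,
            junctions=np.asarray([], dtype=int),
            window_labels=np.zeros(len(vals), dtype=int),
        )

    starts = [ax.values[0] for ax in axes]
    if not np.all(np.diff(starts) > 0):
        raise ValueError("windows must be ordered by increasing delay offset")

    crossings = [
        _envelope_crossing(
            axes[n].values, envelopes[n], axes[n + 1].values, envelopes[n + 1]
        )
        for n in range(len(traces) - 1)
    ]

    # assign each window the delay interval between its flanking junctions;
    # inside a guard band around each junction both windows overlap and
    # both contribute, so the interpolant blends them across the seam
    step = axes[0].step
    bounds = [-np.inf] + crossings + [np.inf]
    pts_delay, pts_value, pts_window = [], [], []
    for n, (tr, ax, m) in enumerate(zip(traces, axes, masks)):
        primary = (ax.values >= bounds[n]) & (ax.values < bounds[n + 1])
        blend = np.zeros(ax.values.size, dtype=bool)
        for x in crossings:
            blend |= np.abs(ax.values - x) <= guard * step
        sel = m & (primary | blend)
        pts_delay.append(ax.values[sel])
        pts_value.append(tr[sel])
        pts_window.append(np.full(sel.sum(), n))
    delay = np.concatenate(pts_delay)
    value = np.concatenate(pts_value)
    window = np.concatenate(pts_window)
    order = np.argsort(delay, kind="stable")
    delay, value, window = delay[order], value[order], window[order]

    # merge samples the two windows recorded at (numerically) equal delays
    tol = 1e-6 * step
    uniq = np.flatnonzero(np.concatenate([[True], np.diff(delay) > tol]))
    groups = np.append(uniq, delay.size)
    delay_u = delay[uniq]
    value_u = np.asarray(
        [value[a:b].mean() for a, b in zip(groups[:-1], groups[1:])]
    )
    if delay_u.size < 4:
        raise ValueError("too few samples retained to fit the stitch interpolant")
    interp = Akima1DInterpolator(delay_u, value_u, method="makima")

    t0, t1 = delay_u[0], delay_u[-1]
    n_out = int(np.floor((t1 - t0) / step)) + 1
    uniform = t0 + np.arange(n_out) * step
    values = interp(uniform)
    labels = window[np.searchsorted(delay, uniform).clip(0, delay.size - 1)]
    junctions = np.asarray(
        [int(np.searchsorted(uniform, x)) for x in crossings], dtype=int
    )
    return StitchedTrace(
        delays=uniform, values=values, junctions=junctions, window_labels=labels
    )


def mask_overlap(
    trace: StitchedTrace, cut_delay: float = 300.0, tukey_alpha: float = 0.1
) -> StitchedTrace:
    """Gate out the pump-probe temporal-overlap spike.

    Samples before ``cut_delay`` (fs) are zeroed; the retained region is
    mean-subtracted (the derivative signal is zero-mean in theory, and a
    residual DC offset would leak into the low-wavenumber bins) and
    apodized with a Tukey window whose rising taper begins at the cut.
    ``tukey_alpha`` = 0 degenerates to a rectangular gate.
    """
    if cut_delay >= trace.delays[-1]:
        raise ValueError("cut_delay lies beyond the end of the trace")
    out = np.zeros_like(trace.values)
    kept = trace.delays >= cut_delay
    region = trace.values[kept]
    if np.any(region):
        region = region - region.mean()
    out[kept] = region * tukey(int(kept.sum()), alpha=tukey_alpha)
    return StitchedTrace(
        delays=trace.delays.copy(),
        values=out,
        junctions=trace.junctions,
        window_labels=trace.window_labels,
    )


def _next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def compute_spectrum(
    trace: StitchedTrace,
    pad_factor: int = 8,
    mode: str = "power",
    n_fft: int | None = None,
) -> Spectrum:
    """Zero-padded FFT of a uniform time trace, on a wavenumber axis.

    The trace is zero-padded to ``pad_factor`` times the next power of
    two of its length (or to an explicit ``n_fft``, e.g. to give every
    pixel of a cube the same axis).  ``mode`` selects the intensity
    ("power", |F|^2, the default) or amplitude ("magnitude", |F|)
    spectrum; peak positions are identical in both, the full width at
    half maximum is not.
    """
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    if mode not in ("power", "magnitude"):
        raise ValueError("mode must be 'power' or 'magnitude'")
    d = np.diff(trace.delays)
    if trace.delays.size < 2 or not np.allclose(d, d[0], rtol=1e-9, atol=1e-9):
        raise ValueError("trace axis must be uniform; resample first")
    n = n_fft if n_fft is not None else pad_factor * _next_pow2(len(trace))
    if n < len(trace):
        raise ValueError("n_fft smaller than the trace")
    spec = np.abs(np.fft.rfft(trace.values, n))
    if mode == "power":
        spec = spec**2
    wavenumbers = np.fft.rfftfreq(n, d=trace.step * 1e-15) / (100.0 * _C)
    return Spectrum(
        wavenumbers=wavenumbers,
        magnitude=spec,
        metadata={
            "pad_factor": pad_factor,
            "n_fft": n,
            "mode": mode,
            "trace_length": len(trace),
        },
    )


def process_cube(
    cubes: CubePair,
    config: AcquisitionConfig | None = None,
    params: ProcessingParams = ProcessingParams(),
) -> HyperCube:
    """Run normalize -> stitch -> mask -> FFT for every spatial pixel.

    All pixels share one wavenumber axis (the FFT length is fixed from
    the full cube delay length).  Pixels with truncated windows or a
    failed normalization are flagged invalid and zero-filled; processing
    aborts only if every pixel fails.
    """
    cfg = config or cubes.config
    ny, nx = cfg.n_lines_y, cfg.n_macro_x
    nw, ntau = cfg.n_windows, cfg.n_delay_samples
    axes = [build_delay_axis(cfg, w) for w in range(nw)]
    n_fft = params.pad_factor * _next_pow2(nw * ntau)

    data = None
    wavenumbers = None
    valid = np.zeros((ny, nx), dtype=bool)
    n_failed = 0
    for y in range(ny):
        for x in range(nx):
            if not cubes.window_valid[y, x].all():
                n_failed += 1
                continue
            raman_w = cubes.raman_cube[y, x].reshape(nw, ntau)
            trans_w = cubes.transmission_cube[y, x].reshape(nw, ntau)
            try:
                norm, masks = [], []
                for w in range(nw):
                    t, m = normalize_by_transmission(
                        raman_w[w], trans_w[w], params.floor_fraction, pixel=(y, x)
                    )
                    norm.append(t)
                    masks.append(m)
                stitched = stitch_windows(
                    norm, axes, list(trans_w), masks, guard=params.guard
                )
                masked = mask_overlap(stitched, params.cut_delay, params.tukey_alpha)
                spec = compute_spectrum(
                    masked, params.pad_factor, params.mode, n_fft=n_fft
                )
            except ValueError:
                n_failed += 1
                continue
            if data is None:
                wavenumbers = spec.wavenumbers
                data = np.zeros((ny, nx, wavenumbers.size))
            data[y, x] = spec.magnitude
            valid[y, x] = True
    if data is None:
        raise ValueError("every pixel failed spectral processing")
    return HyperCube(
        data=data,
        wavenumbers=wavenumbers,
        pixel_valid=valid,
        metadata={
            "params": params,
            "n_failed_pixels": n_failed,
            "n_windows": nw,
        },
    )


def _gaussian_2x2_kernel(sigma: float = 0.8) -> np.ndarray:
    """Gaussian sampled on the 2x2 offset grid {0,1}^2, normalized."""
    a = np.arange(2)
    k = np.exp(-(a[:, None] ** 2 + a[None, :] ** 2) / (2 * sigma**2))
    return k / k.sum()


def frequency_slice(
    hcube: HyperCube,
    shift: float,
    smooth: bool = True,
    normalize: str = "none",
    band: float | None = None,
) -> np.ndarray:
    """Chemical image at one Raman shift.

    Nearest-bin slice by default, or the mean over ``band`` cm^-1 around
    the shift.  Optional 2x2 Gaussian spatial smoothing (sigma 0.8 px)
    and normalization to the brightest pixel of the image
    ("image-max") or of the whole cube ("cube-max").
    """
    wn = hcube.wavenumbers
    if not wn[0] <= shift <= wn[-1]:
        raise ValueError(
            f"shift {shift} cm^-1 outside axis range [{wn[0]:.2f}, {wn[-1]:.2f}]"
        )
    if normalize not in ("none", "image-max", "cube-max"):
        raise ValueError("normalize must be one of none, image-max, cube-max")
    if band is None:
        img = hcube.data[:, :, int(np.argmin(np.abs(wn - shift)))].copy()
    else:
        sel = np.abs(wn - shift) <= band / 2
        img = hcube.data[:, :, sel].mean(axis=2)
    if smooth:
        img = ndimage.correlate(img, _gaussian_2x2_kernel(), mode="nearest")
    if normalize == "image-max" and img.max() > 0:
        img = img / img.max()
    elif normalize == "cube-max" and hcube.data.max() > 0:
        img = img / hcube.data.max()
    return img


def roi_spectrum(hcube: HyperCube, roi_mask: np.ndarray) -> Spectrum:
    """Per-bin mean spectrum over a region of interest (valid pixels only)."""
    roi = np.asarray(roi_mask, dtype=bool) & hcube.pixel_valid
    if not roi.any():
        raise ValueError("ROI contains no valid pixels")
    return Spectrum(
        wavenumbers=hcube.wavenumbers.copy(),
        magnitude=hcube.data[roi].mean(axis=0),
        metadata={"roi_pixels": int(roi.sum())},
    )


def peak_stats(
    spectrum: Spectrum, band: tuple[float, float] | None = None
) -> PeakStats:
    """Peak position, interpolated FWHM and height of the strongest line.

    The peak is the argmax within ``band`` (cm^-1); the width comes from
    linear interpolation of the half-maximum crossings on either side.
    A peak sitting on the band edge is flagged rather than trusted.
    """
    wn, mag = spectrum.wavenumbers, spectrum.magnitude
    if band is not None:
        lo, hi = band
        if lo < wn[0] or hi > wn[-1] or lo >= hi:
            raise ValueError("band must lie within the wavenumber axis")
        sel = (wn >= lo) & (wn <= hi)
        idx = np.flatnonzero(sel)
    else:
        idx = np.arange(wn.size)
    i_peak = idx[np.argmax(mag[idx])]
    height = mag[i_peak]
    on_edge = i_peak == idx[0] or i_peak == idx[-1]
    half = height / 2.0

    def _cross(direction: int) -> float:
        i = i_peak
        while 0 < i < wn.size - 1:
            j = i + direction
            if mag[j] <= half:
                frac = (mag[i] - half) / (mag[i] - mag[j])
                return wn[i] + frac * (wn[j] - wn[i])
            i = j
        return wn[i]  # ran off the axis

    left = _cross(-1)
    right = _cross(+1)
    return PeakStats(
        position=float(wn[i_peak]),
        fwhm=float(right - left),
        height=float(height),
        on_edge=bool(on_edge),
    )
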