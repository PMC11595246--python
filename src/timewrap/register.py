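"""Trigger-edge registration of raw time-wrapped records into data cubes.

The DAQ clock and the delay-line trigger are not phase-locked across
scan lines (the mirror flyback is not a multiple of the DAQ sample), so
each raw row carries an unknown integer offset.  The trigger channel
records one pulse per delay scan; its rising edges give the exact start
of every (macro-pixel, window) segment, letting the 2D records be
remapped to (Ny, Nx, N_tau) cubes independently of the per-line jitter.
Rows are treated circularly, so a jittered row loses no samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .physics import AcquisitionConfig
from .simulate import RawAcquisition

__all__ = [
    "RegistrationError",
    "EdgeTable",
    "CubePair",
    "SyncReport",
    "detect_rising_edges",
    "build_edge_table",
    "infer_window_period",
    "reshape_to_cubes",
    "validate_sync",
]


class RegistrationError(RuntimeError):
    """Raised when the trigger structure of a line cannot be interpreted."""


@dataclass
class EdgeTable:
    """Per-line trigger rising-edge positions and derived timing."""

    edges: list[np.ndarray]
    period: int | None = None  # inferred samples per window segment
    offsets: np.ndarray | None = None  # per-line estimate of the jitter shift
    warnings: list[str] = field(default_factory=list)


@dataclass
class CubePair:
    """Co-registered Raman and transmission cubes, (Ny, Nx, N_window*N_tau).

    ``window_valid`` is (Ny, Nx, N_window); a False entry marks a
    zero-filled window from a truncated line.  ``line_truncated`` flags
    the affected lines.
    """

    raman_cube: np.ndarray
    transmission_cube: np.ndarray
    window_valid: np.ndarray
    line_truncated: np.ndarray
    config: AcquisitionConfig

    @property
    def pixel_valid(self) -> np.ndarray:
        """(Ny, Nx) pixels whose every window was fully acquired."""
        return self.window_valid.all(axis=2)

    @property
    def n_accepted_lines(self) -> int:
        return int((~self.line_truncated).sum())


@dataclass
class SyncReport:
    """Diagnostic summary of trigger/DAQ synchronization for one record."""

    edge_counts: np.ndarray
    expected_edges: int
    period: int | None
    expected_period: int
    truncated_lines: list[int]
    fatal: bool = False
    messages: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal and not self.truncated_lines


def detect_rising_edges(
    trigger_row: np.ndarray,
    threshold_fraction: float = 0.5,
    min_gap: int | None = None,
    line_index: int | None = None,
) -> np.ndarray:
    """Indices where the trigger crosses its threshold upward.

    The threshold is ``threshold_fraction`` of the row's dynamic range
    above its minimum, robust to baseline drift.  The row is treated
    circularly (the previous sample of index 0 is the last sample).
    Edges closer than ``min_gap`` samples to the previous accepted edge
    are debounced.
    """
    row = np.asarray(trigger_row, dtype=float)
    if row.size == 0:
        raise ValueError("trigger row is empty")
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must lie strictly in (0, 1)")
    lo, hi = row.min(), row.max()
    if hi == lo:
        where = f" on line {line_index}" if line_index is not None else ""
        raise RegistrationError(f"flat trigger row{where}: no edges detectable")
    theta = lo + threshold_fraction * (hi - lo)
    high = row >= theta
    prev_high = np.roll(high, 1)
    edges = np.flatnonzero(high & ~prev_high)
    if min_gap is not None and edges.size > 1:
        kept = [edges[0]]
        for e in edges[1:]:
            if e - kept[-1] >= min_gap:
                kept.append(e)
        edges = np.asarray(kept)
    return edges


def build_edge_table(
    trigger: np.ndarray,
    config: AcquisitionConfig | None = None,
    threshold_fraction: float = 0.5,
    allow_flat_last_line: bool = True,
) -> EdgeTable:
    """Detect edges on every line of a trigger record.

    A completely flat *final* line (acquisition aborted before its first
    trigger) yields an empty edge list rather than an error.
    """
    min_gap = config.n_delay_samples // 2 if config is not None else None
    edges: list[np.ndarray] = []
    table_warnings: list[str] = []
    n_lines = trigger.shape[0]
    for y in range(n_lines):
        try:
            edges.append(
                detect_rising_edges(trigger[y], threshold_fraction, min_gap, y)
            )
        except RegistrationError:
            if allow_flat_last_line and y == n_lines - 1:
                edges.append(np.asarray([], dtype=int))
                table_warnings.append(f"line {y}: flat trigger, treated as truncated")
            else:
                raise
    table = EdgeTable(edges=edges, warnings=table_warnings)
    table.period = infer_window_period(table, config)
    table.offsets = np.asarray(
        [int(e[0]) % table.period if e.size else 0 for e in edges]
    )
    return table


def infer_window_period(
    edge_table: EdgeTable, config: AcquisitionConfig | None = None
) -> int:
    """Samples per window segment: the median inter-edge spacing.

    If a configuration is given and disagrees, a warning is recorded (the
    configured value may simply be stale) but the measured period wins.
    """
    spacings = np.concatenate(
        [np.diff(e) for e in edge_table.edges if e.size >= 2] or [np.asarray([])]
    )
    if spacings.size == 0:
        if config is not None:
            # a one-window-per-line record has a single edge per line;
            # only the configured segment length can supply the period
            return config.samples_per_segment
        raise RegistrationError("need at least two edges on some line to infer period")
    period = int(round(float(np.median(spacings))))
    if config is not None and period != config.samples_per_segment:
        msg = (
            f"inferred window period {period} != configured "
            f"{config.samples_per_segment} samples"
        )
        edge_table.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)
    return period


def reshape_to_cubes(
    raw: RawAcquisition, threshold_fraction: float = 0.5
) -> CubePair:
    """Remap the 2D records to (Ny, Nx, N_window*N_tau) cubes.

    For each line, the N_tau samples following each trigger edge (plus
    the configured trigger lead) are assigned to consecutive
    macro-pixel/window slots in acquisition order, with circular row
    indexing so per-line jitter is removed exactly.  A line with fewer
    edges than expected is accepted as a truncated prefix: its missing
    windows (and its last detected, possibly cut, window) are zero-filled
    and masked.  Any other edge pattern is a structured error.
    """
    cfg = raw.config
    ny, nx, nw, ntau = (
        cfg.n_lines_y,
        cfg.n_macro_x,
        cfg.n_windows,
        cfg.n_delay_samples,
    )
    lead = cfg.trigger_lead
    expected = nx * nw
    table = build_edge_table(raw.trigger, cfg, threshold_fraction)

    raman = np.zeros((ny, nx * nw, ntau))
    trans = np.zeros((ny, nx * nw, ntau))
    valid = np.zeros((ny, nx * nw), dtype=bool)
    truncated = np.zeros(ny, dtype=bool)
    row_len = raw.raman.shape[1]
    rel = np.arange(ntau)

    for y in range(ny):
        edges = table.edges[y]
        k = edges.size
        if k == expected:
            n_full = k
        elif k < expected:
            # truncated prefix: every inter-edge gap must match the period
            if k >= 2 and not np.all(np.abs(np.diff(edges) - table.period) <= 1):
                raise RegistrationError(
                    f"line {y}: {k} edges with irregular spacing "
                    f"(expected {expected} edges of period {table.period})"
                )
            truncated[y] = True
            n_full = max(k - 1, 0)  # last detected window may itself be cut
        else:
            raise RegistrationError(
                f"line {y}: {k} trigger edges, expected {expected} "
                "or a truncated prefix"
            )
        for i in range(n_full):
            idx = (edges[i] + lead + rel) % row_len
            raman[y, i] = raw.raman[y, idx]
            trans[y, i] = raw.transmission[y, idx]
            valid[y, i] = True

    raman = raman.reshape(ny, nx, nw, ntau).reshape(ny, nx, nw * ntau)
    trans = trans.reshape(ny, nx, nw, ntau).reshape(ny, nx, nw * ntau)
    window_valid = valid.reshape(ny, nx, nw)
    return CubePair(
        raman_cube=raman,
        transmission_cube=trans,
        window_valid=window_valid,
        line_truncated=truncated,
        config=cfg,
    )


def validate_sync(
    raw: RawAcquisition, threshold_fraction: float = 0.5
) -> SyncReport:
    """Purely diagnostic synchronization report; never raises."""
    cfg = raw.config
    expected = cfg.n_macro_x * cfg.n_windows
    expected_period = cfg.samples_per_segment
    if raw.trigger is None or raw.trigger.size == 0 or np.ptp(raw.trigger) == 0:
        return SyncReport(
            edge_counts=np.zeros(cfg.n_lines_y, dtype=int),
            expected_edges=expected,
            period=None,
            expected_period=expected_period,
            truncated_lines=[],
            fatal=True,
            messages=["trigger channel missing or flat: cannot register"],
        )
    try:
        table = build_edge_table(raw.trigger, cfg, threshold_fraction)
    except RegistrationError as exc:
        return SyncReport(
            edge_counts=np.zeros(cfg.n_lines_y, dtype=int),
            expected_edges=expected,
            period=None,
            expected_period=expected_period,
            truncated_lines=[],
            fatal=True,
            messages=[str(exc)],
        )
    counts = np.asarray([e.size for e in table.edges])
    truncated = [int(y) for y in np.flatnonzero(counts < expected)]
    messages = list(table.warnings)
    fatal = bool(np.any(counts > expected))
    if fatal:
        messages.append("some lines show more edges than configured windows")
    return SyncReport(
        edge_counts=counts,
        expected_edges=expected,
        period=table.period,
        expected_period=expected_period,
        truncated_lines=truncated,
        fatal=fatal,
        messages=messages,
    )
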