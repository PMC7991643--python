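"""Spatiotemporal fluctuation analysis of time-lapse predictions.

Quantifies the stochastic dynamics of marker expression in live cells
imaged every few minutes over many hours: per-cell total-expression
traces; the contrast between *overall* marker-marker correlation
(across cells at one time point) and *fluctuation* correlation (across
time within one cell); the trace autocorrelation function and the
correlation time of its exponential head; kymograph-style intracellular
expression maps (vertical-axis projection per frame, position x time);
and their 2-D Fourier magnitude spectra with physical frequency axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import detrend as _lin_detrend

from virtustain.errors import (
    FitFailureError,
    ShapeError,
    UndefinedStatisticError,
    ValidationError,
)

__all__ = [
    "TimelapseTrace",
    "ACFResult",
    "SpatioTemporalMap",
    "trace_expression",
    "overall_correlation",
    "fluctuation_correlation",
    "autocorrelation",
    "fit_correlation_time",
    "project_intracellular",
    "fft2_map",
]


@dataclass
class TimelapseTrace:
    """Total expression of one cell for one marker over uniform frames."""

    cell_id: str
    marker: str
    values: np.ndarray
    frame_interval: float  # minutes

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValidationError("trace needs >= 2 frames")
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be > 0")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.frame_interval


@dataclass
class ACFResult:
    """Autocorrelation of a trace; acf[0] = 1 by construction."""

    lags: np.ndarray  # minutes
    acf: np.ndarray
    frame_interval: float
    correlation_time: float | None = None
    fit_range: tuple[int, int] | None = None  # [start, stop) lag indices


@dataclass
class SpatioTemporalMap:
    """Position x time expression matrix for one cell and marker."""

    matrix: np.ndarray  # positions x frames
    pixel_pitch: float  # micrometres per resampled position bin
    frame_interval: float  # minutes
    occupancy: np.ndarray | None = None  # pixels per position bin, same shape

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ShapeError("map matrix must be positions x frames")


#: resampled intracellular profile length (position bins per cell)
PROFILE_LENGTH = 100


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a * a).sum() * (b * b).sum())
    if den == 0:
        raise UndefinedStatisticError("correlation undefined for constant series")
    return float(np.clip((a * b).sum() / den, -1.0, 1.0))


def trace_expression(stack, masks, cell_id="", marker="",
                     frame_interval: float = 2.0) -> TimelapseTrace:
    """Total in-mask intensity per frame.

    ``stack`` is (frames, H, W) or a list of frames; ``masks`` one
    boolean mask per frame (a single mask is broadcast to all frames).
    """
    frames = [np.asarray(f, dtype=np.float64) for f in stack]
    if len(frames) < 2:
        raise ValidationError("need >= 2 frames")
    m = np.asarray(masks)
    if m.ndim == 2:
        mask_list = [m.astype(bool)] * len(frames)
    else:
        mask_list = [np.asarray(mm, dtype=bool) for mm in masks]
    if len(mask_list) != len(frames):
        raise ValidationError(
            f"{len(frames)} frames but {len(mask_list)} masks"
        )
    vals = []
    for f, mm in zip(frames, mask_list):
        if f.shape != mm.shape:
            raise ShapeError("frame/mask shape mismatch")
        if not mm.any():
            raise ValidationError("empty mask in time-lapse")
        vals.append(float(f[mm].sum()))
    return TimelapseTrace(
        cell_id=cell_id, marker=marker, values=np.array(vals),
        frame_interval=frame_interval,
    )


def overall_correlation(table: pd.DataFrame, markers=None) -> pd.DataFrame:
    """Marker x marker Pearson correlation of per-cell mean intensities
    across cells at a single time point."""
    if markers is None:
        markers = [c[5:] for c in table.columns if c.startswith("mean_")]
        cols = {m: f"mean_{m}" for m in markers}
    else:
        cols = {m: (f"mean_{m}" if f"mean_{m}" in table.columns else m)
                for m in markers}
    if len(table) < 3:
        raise ValidationError("need >= 3 cells")
    out = pd.DataFrame(index=list(markers), columns=list(markers), dtype=float)
    for a in markers:
        for b in markers:
            out.loc[a, b] = _pearson(
                table[cols[a]].to_numpy(float), table[cols[b]].to_numpy(float)
            )
    return out


def fluctuation_correlation(
    traces: dict[str, TimelapseTrace], detrend: bool = True
) -> pd.DataFrame:
    """Marker x marker Pearson correlation between one cell's traces
    over time (optionally after linear detrending, which separates slow
    drift from the stochastic fluctuation)."""
    markers = list(traces)
    if not markers:
        raise ValidationError("no traces")
    n = {m: traces[m].values.size for m in markers}
    dt = {m: traces[m].frame_interval for m in markers}
    if len(set(n.values())) != 1 or len(set(dt.values())) != 1:
        raise ValidationError("traces must share length and frame interval")
    series = {
        m: (_lin_detrend(traces[m].values) if detrend else traces[m].values)
        for m in markers
    }
    out = pd.DataFrame(index=markers, columns=markers, dtype=float)
    for a in markers:
        for b in markers:
            out.loc[a, b] = _pearson(series[a], series[b])
    return out


def autocorrelation(trace: TimelapseTrace, max_lag: int | None = None) -> ACFResult:
    """Biased (divide-by-n) ACF of the mean-subtracted trace.

    The biased estimator guarantees a positive semidefinite sequence;
    acf[0] = 1 for any non-constant trace.
    """
    x = trace.values
    n = x.size
    if max_lag is None:
        max_lag = n // 2 - 1
    if not 0 < max_lag < n / 2:
        raise ValidationError("max_lag must be in (0, n_frames/2)")
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0:
        raise UndefinedStatisticError("ACF undefined for a constant trace")
    acf = np.array(
        [np.dot(xc[: n - k], xc[k:]) / denom for k in range(max_lag + 1)]
    )
    return ACFResult(
        lags=np.arange(max_lag + 1) * trace.frame_interval,
        acf=acf,
        frame_interval=trace.frame_interval,
    )


def average_acf(acfs: list[ACFResult]) -> ACFResult:
    """Ensemble mean of equally sampled ACFs."""
    if not acfs:
        raise ValidationError("no ACFs to average")
    L = min(a.acf.size for a in acfs)
    mean = np.mean([a.acf[:L] for a in acfs], axis=0)
    return ACFResult(
        lags=acfs[0].lags[:L], acf=mean, frame_interval=acfs[0].frame_interval
    )


def fit_correlation_time(acf: ACFResult, max_head_fraction: float = 0.25) -> float:
    """Correlation time from an exponential fit to the head of the ACF.

    The head spans lag 0 up to the first zero crossing, capped at
    ``max_head_fraction`` of the available lags (the anticorrelated
    tail expected from finite measurement duration is excluded).
    Least-squares fit of exp(-lag/tau); returns tau in minutes and
    stores it (with the fit range) on the ACFResult.
    """
    a = acf.acf
    neg = np.flatnonzero(a <= 0)
    stop = int(neg[0]) if neg.size else a.size
    stop = min(stop, max(int(a.size * max_head_fraction), 3))
    if stop < 3:
        raise FitFailureError(
            f"ACF head has only {stop} points before the first zero crossing"
        )
    head = a[:stop]
    if head[1] >= head[0]:
        raise FitFailureError("ACF head is not decaying")
    lags = acf.lags[:stop]
    tau0 = max(float(lags[1]), 1e-6)
    (tau,), _ = curve_fit(
        lambda l, tau: np.exp(-l / tau), lags, head, p0=[tau0 * 5], maxfev=10000
    )
    if tau <= 0:
        raise FitFailureError(f"non-positive fitted correlation time {tau}")
    acf.correlation_time = float(tau)
    acf.fit_range = (0, stop)
    return float(tau)


def project_intracellular(
    stack,
    masks,
    pixel_pitch: float = 1.0,
    frame_interval: float = 2.0,
    n_positions: int = PROFILE_LENGTH,
) -> SpatioTemporalMap:
    """Kymograph-style map: vertical-axis projection per frame.

    For each frame, the in-mask pixels of every column of the cell's
    bounding box are averaged (projection over the image vertical axis),
    and the resulting 1-D profile across the cell is resampled to
    ``n_positions`` bins so frames of a moving, deforming cell remain
    comparable.  Columns of the result are frames.
    """
    frames = [np.asarray(f, dtype=np.float64) for f in stack]
    m = np.asarray(masks)
    mask_list = (
        [m.astype(bool)] * len(frames)
        if m.ndim == 2
        else [np.asarray(mm, dtype=bool) for mm in masks]
    )
    if len(mask_list) != len(frames):
        raise ValidationError("frame/mask count mismatch")
    profiles, occs, widths = [], [], []
    for f, mm in zip(frames, mask_list):
        if not mm.any():
            raise ValidationError("mask vanished at some frame")
        cols = np.flatnonzero(mm.any(axis=0))
        c0, c1 = cols[0], cols[-1] + 1
        sub, msub = f[:, c0:c1], mm[:, c0:c1]
        counts = msub.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            prof = np.where(counts > 0, (sub * msub).sum(axis=0) / counts, np.nan)
        # fill interior gaps (columns with no in-mask pixel) by interpolation
        if np.isnan(prof).any():
            idx = np.arange(prof.size)
            good = ~np.isnan(prof)
            prof = np.interp(idx, idx[good], prof[good])
            counts = np.interp(idx, idx[good], counts[good])
        src = np.linspace(0.0, 1.0, prof.size)
        dst = np.linspace(0.0, 1.0, n_positions)
        profiles.append(np.interp(dst, src, prof))
        occs.append(np.interp(dst, src, counts) * prof.size / n_positions)
        widths.append(c1 - c0)
    return SpatioTemporalMap(
        matrix=np.column_stack(profiles),
        pixel_pitch=pixel_pitch * float(np.mean(widths)) / n_positions,
        frame_interval=frame_interval,
        occupancy=np.column_stack(occs),
    )


def fft2_map(stmap: SpatioTemporalMap, window: bool = False):
    """2-D Fourier magnitude spectrum of a spatiotemporal map.

    The map is mean-subtracted (and optionally Hann-windowed), its 2-D
    DFT magnitude is zero-frequency-centred, and the axes are returned
    in physical units: cycles/um along positions and cycles/min along
    frames.  Returns (spectrum, spatial_freqs, temporal_freqs).
    """
    x = stmap.matrix
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite entries in map")
    x = x - x.mean()
    if window:
        wr = np.hanning(x.shape[0])[:, None]
        wc = np.hanning(x.shape[1])[None, :]
        x = x * wr * wc
    spec = np.abs(np.fft.fftshift(np.fft.fft2(x)))
    f_space = np.fft.fftshift(np.fft.fftfreq(x.shape[0], d=stmap.pixel_pitch))
    f_time = np.fft.fftshift(np.fft.fftfreq(x.shape[1], d=stmap.frame_interval))
    return spec, f_space, f_time
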