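"""Receptive-field estimation by reverse correlation of dense-noise stimuli.

The space-time receptive field F(x, y, tau) is the response-weighted average
of the stimulus at delay tau. Thresholds for signal pixels come from an
independent-noise control (reverse correlation against freshly generated
noise the cell never saw): mean + 3 SD of that control volume. The
space-time profile along the motion-preference axis (the stRF) yields, per
spatial column, a peak time and an activation time; the least-squares slope
of peak time against position (s/um) inverts to a predicted optimal
velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal

from delaysum.stimuli import StimulusMovie
from delaysum.traces import Trace

__all__ = [
    "StRFVolume",
    "StRF",
    "StRFStats",
    "SpatialRF",
    "TemporalFilter",
    "reverse_correlate",
    "control_threshold",
    "strf_profile",
    "strf_slope_and_activation",
    "spatial_rf_from_events",
    "temporal_rf",
    "partition_temporal_filters",
]


@dataclass
class StRFVolume:
    """Reverse-correlation volume over (x, y, lag)."""

    values: np.ndarray
    lag_step_s: float
    max_lag_s: float
    px_size_um: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("volume must be 3-D (x, y, lag)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume must be finite")

    @property
    def lags_s(self) -> np.ndarray:
        return np.arange(self.values.shape[2]) * self.lag_step_s

    def peak_pixel(self) -> tuple[int, int]:
        """Pixel with the largest absolute filter value at any lag."""
        amp = np.abs(self.values).max(axis=2)
        return tuple(np.unravel_index(int(np.argmax(amp)), amp.shape))


@dataclass
class StRF:
    """Space-time profile along the motion-preference axis: (position, lag)."""

    values: np.ndarray
    positions_um: np.ndarray
    lag_step_s: float
    axis_deg: float = 0.0
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.values.shape[0] != self.positions_um.size:
            raise ValueError("positions and profile rows disagree")

    @property
    def lags_s(self) -> np.ndarray:
        return np.arange(self.values.shape[1]) * self.lag_step_s


@dataclass
class StRFStats:
    """Slope and activation summary of a thresholded stRF."""

    slope_s_per_um: float
    optimal_speed_um_s: float
    mean_activation_s: float
    n_columns: int
    peak_times_s: np.ndarray
    activation_times_s: np.ndarray
    columns_um: np.ndarray
    ok: bool


@dataclass
class SpatialRF:
    """Event-triggered spatial receptive field with a 2-D Gaussian fit."""

    map: np.ndarray
    px_size_um: float
    gauss_fit: dict
    area_um2: float
    n_events: int
    ok: bool
    origin: tuple[float, float] = (0.0, 0.0)


@dataclass
class TemporalFilter:
    """Temporal profile around the receptive-field centre pixel."""

    values: np.ndarray
    lag_step_s: float
    peak_latency_s: float
    decay_tau_s: float | None = None
    meta: dict = field(default_factory=dict)


def _response_on_stimulus_base(response: Trace, noise: StimulusMovie) -> np.ndarray:
    """Response averaged into stimulus frame bins (time-aligned at 0)."""
    nt = noise.n_frames
    if abs(response.rate_hz - noise.refresh_hz) < 1e-9:
        r = response.values
    else:
        per = response.rate_hz / noise.refresh_hz
        n_full = int(np.floor(response.values.size / per))
        edges = (np.arange(n_full + 1) * per).astype(int)
        r = np.add.reduceat(response.values, edges[:-1]) / np.diff(edges)
    if r.size < nt:
        raise ValueError("response shorter than the stimulus")
    return r[:nt]


def reverse_correlate(
    response: Trace, noise: StimulusMovie, max_lag_s: float = 1.0
) -> StRFVolume:
    """Response-weighted average of the stimulus at delays 0..max_lag.

    ``F[x, y, k] = mean_t r(t) S(x, y, t - k)``; lag 0 is the synaptic input
    time. The averaging count is held fixed across lags, so the estimator is
    exactly linear in the response.
    """
    r = _response_on_stimulus_base(response, noise)
    nlag = int(round(max_lag_s * noise.refresh_hz)) + 1
    nt = noise.n_frames
    if nlag >= nt:
        raise ValueError("max_lag_s exceeds the record length")
    n_avg = nt - nlag
    vol = np.empty(noise.frames.shape[:2] + (nlag,))
    for k in range(nlag):
        vol[:, :, k] = (
            np.tensordot(noise.frames[:, :, : n_avg], r[k : k + n_avg], axes=([2], [0]))
            / n_avg
        )
    return StRFVolume(
        values=vol,
        lag_step_s=1.0 / noise.refresh_hz,
        max_lag_s=max_lag_s,
        px_size_um=noise.px_size_um,
        origin=noise.origin,
    )


def control_threshold(
    response: Trace,
    independent_noise: StimulusMovie,
    max_lag_s: float = 1.0,
    k: float = 3.0,
) -> float:
    """Signal threshold: mean + k SD of the control reverse-correlation volume.

    The control volume correlates the same response against freshly generated
    noise the cell never saw; it must not share the seed of the stimulus that
    evoked the response.
    """
    stim_seed = response.meta.get("stimulus_seed")
    ctrl_seed = independent_noise.meta.get("seed")
    if stim_seed is not None and ctrl_seed is not None and stim_seed == ctrl_seed:
        raise ValueError("control noise shares the stimulus seed")
    ctrl = reverse_correlate(response, independent_noise, max_lag_s)
    return float(ctrl.values.mean() + k * ctrl.values.std(ddof=1))


def strf_profile(
    volume: StRFVolume,
    axis_deg: float = 0.0,
    width_um: float = 40.0,
    length_um: float = 800.0,
    center_um: tuple[float, float] | None = None,
) -> StRF:
    """Average the volume across a rectangle's width along the preference axis.

    The rectangle (``width_um`` across x ``length_um`` along the axis) is
    centred on ``center_um`` (default: the volume's peak pixel). Sampling is
    bilinear at the volume's own pixel pitch.
    """
    nx, ny, nlag = volume.values.shape
    px = volume.px_size_um
    if center_um is None:
        pi, pj = volume.peak_pixel()
        center_um = (volume.origin[0] + pi * px, volume.origin[1] + pj * px)

    n_pos = max(3, int(round(length_um / px)))
    n_w = max(1, int(round(width_um / px)))
    s = (np.arange(n_pos) - (n_pos - 1) / 2.0) * px
    w = (np.arange(n_w) - (n_w - 1) / 2.0) * px
    th = np.deg2rad(axis_deg)
    ux, uy = np.cos(th), np.sin(th)
    X = center_um[0] + s[:, None] * ux - w[None, :] * uy
    Y = center_um[1] + s[:, None] * uy + w[None, :] * ux
    I = (X - volume.origin[0]) / px
    J = (Y - volume.origin[1]) / px
    if I.min() < -0.5 or J.min() < -0.5 or I.max() > nx - 0.5 or J.max() > ny - 0.5:
        raise ValueError("profile rectangle extends outside the volume footprint")

    prof = np.empty((n_pos, nlag))
    coords = np.stack([I.ravel(), J.ravel()])
    for k in range(nlag):
        vals = ndimage.map_coordinates(volume.values[:, :, k], coords, order=1,
                                       mode="nearest")
        prof[:, k] = vals.reshape(n_pos, n_w).mean(axis=1)
    return StRF(values=prof, positions_um=s, lag_step_s=volume.lag_step_s,
                axis_deg=axis_deg)


def strf_slope_and_activation(strf: StRF, threshold: float | None = None) -> StRFStats:
    """Least-squares slope of per-column peak time vs position, and mean
    activation time (earliest suprathreshold lag per column).

    Columns with no suprathreshold pixel are excluded; fewer than 3 such
    columns flags the result (``ok = False``). Peak times are defined on the
    absolute filter value. ``optimal_speed_um_s`` is 1/|slope|.
    """
    if threshold is None:
        threshold = strf.threshold
    if threshold is None:
        raise ValueError("no threshold supplied or stored on the stRF")
    absv = np.abs(strf.values)
    supra = absv >= threshold
    cols = np.nonzero(supra.any(axis=1))[0]
    lags = strf.lags_s
    peak_t = np.array([lags[int(np.argmax(absv[c]))] for c in cols])
    act_t = np.array([lags[int(np.argmax(supra[c]))] for c in cols])
    if cols.size < 3:
        return StRFStats(np.nan, np.nan, float(act_t.mean()) if cols.size else np.nan,
                         int(cols.size), peak_t, act_t, strf.positions_um[cols], False)
    slope = float(np.polyfit(strf.positions_um[cols], peak_t, 1)[0])
    speed = float(1.0 / abs(slope)) if slope != 0 else np.inf
    return StRFStats(slope, speed, float(act_t.mean()), int(cols.size),
                     peak_t, act_t, strf.positions_um[cols], True)


def _gauss2d(params, X, Y):
    amp, cx, cy, sx, sy, off = params
    return amp * np.exp(-0.5 * (((X - cx) / sx) ** 2 + ((Y - cy) / sy) ** 2)) + off


def spatial_rf_from_events(
    trace: Trace,
    noise: StimulusMovie,
    k: float = 3.0,
    max_lag_s: float = 1.0,
    min_events: int = 10,
    seed: int = 0,
) -> SpatialRF:
    """Event-triggered average spatial receptive field with a 2-D Gaussian fit.

    Transient events are trace samples exceeding mean + k SD of the full
    record (local maxima). The spatial map is the event-triggered stimulus
    average at the most informative delay; its suprathreshold area is scored
    against a shuffled-event control (mean + k SD), and the thresholded map
    is fitted with a 2-D Gaussian by least squares.
    """
    r = _response_on_stimulus_base(trace, noise)
    thr = r.mean() + k * r.std(ddof=1)
    peaks, _ = signal.find_peaks(r, height=thr)
    nlag = int(round(max_lag_s * noise.refresh_hz)) + 1
    peaks = peaks[peaks >= nlag]
    empty = SpatialRF(np.zeros(noise.frames.shape[:2]), noise.px_size_um, {},
                      0.0, int(peaks.size), False, noise.origin)
    if peaks.size < min_events:
        return empty

    def eta(events: np.ndarray) -> np.ndarray:
        vol = np.zeros(noise.frames.shape[:2] + (nlag,))
        for t in events:
            vol += noise.frames[:, :, t - nlag + 1 : t + 1][:, :, ::-1]
        return vol / events.size

    vol = eta(peaks)
    best_lag = int(np.argmax(np.abs(vol).max(axis=(0, 1))))
    rf_map = vol[:, :, best_lag]

    rng = np.random.default_rng(seed)
    ctrl_events = rng.integers(nlag, noise.n_frames, size=peaks.size)
    ctrl = eta(np.sort(ctrl_events))
    ctrl_thr = float(np.abs(ctrl).mean() + k * np.abs(ctrl).std(ddof=1))
    supra = np.abs(rf_map) >= ctrl_thr
    area = float(supra.sum() * noise.px_size_um**2)

    x = noise.x_um
    y = noise.y_um
    X, Y = np.meshgrid(x, y, indexing="ij")
    if supra.any():
        i0, j0 = np.unravel_index(int(np.argmax(np.abs(rf_map))), rf_map.shape)
        p0 = [rf_map[i0, j0], x[i0], y[j0], 2 * noise.px_size_um,
              2 * noise.px_size_um, 0.0]
        try:
            res = optimize.least_squares(
                lambda p: (_gauss2d(p, X, Y) - rf_map).ravel(), p0,
                bounds=([-np.inf, x[0], y[0], 0.1, 0.1, -np.inf],
                        [np.inf, x[-1], y[-1], x[-1] - x[0], y[-1] - y[0], np.inf]),
            )
            amp, cx, cy, sx, sy, off = res.x
            fit = {"amplitude": amp, "center_um": (float(cx), float(cy)),
                   "sigma_um": (float(sx), float(sy)), "offset": float(off),
                   "residual": float(np.sqrt(np.mean(res.fun**2)))}
            ok = True
        except Exception:
            fit, ok = {}, False
    else:
        fit, ok = {}, False
    return SpatialRF(rf_map, noise.px_size_um, fit, area, int(peaks.size), ok,
                     noise.origin)


def temporal_rf(volume: StRFVolume) -> TemporalFilter:
    """Temporal profile: average of the 3x3 pixel neighbourhood around the
    peak pixel (truncated at borders)."""
    i, j = volume.peak_pixel()
    nx, ny, _ = volume.values.shape
    sl = volume.values[max(0, i - 1) : i + 2, max(0, j - 1) : j + 2, :]
    values = sl.mean(axis=(0, 1))
    lag = float(np.argmax(np.abs(values)) * volume.lag_step_s)
    decay = _fit_decay_tau(values, volume.lag_step_s)
    return TemporalFilter(values=values, lag_step_s=volume.lag_step_s,
                          peak_latency_s=lag, decay_tau_s=decay)


def _fit_decay_tau(values: np.ndarray, dt: float) -> float | None:
    p = int(np.argmax(np.abs(values)))
    tail = np.abs(values[p:])
    pos = tail > 1e-3 * tail[0] if tail.size else np.array([])
    if tail.size < 3 or pos.sum() < 3:
        return None
    n = int(np.argmin(pos)) if not pos.all() else tail.size
    if n < 3:
        return None
    t = np.arange(n) * dt
    coef = np.polyfit(t, np.log(tail[:n]), 1)
    return float(-1.0 / coef[0]) if coef[0] < 0 else None


def partition_temporal_filters(
    strf: StRF, threshold: float | None = None
) -> dict[str, TemporalFilter | None]:
    """Split the thresholded stRF into preferred-side, centre and null-side
    temporal filters.

    The centre part is the 3 columns around the maximum-filter column; the
    preferred / null parts span from the centre column to the outermost
    suprathreshold column on the negative / positive side of the position
    axis. Each filter is the mean over its columns; a side without
    suprathreshold columns is returned as None.
    """
    if threshold is None:
        threshold = strf.threshold
    if threshold is None:
        raise ValueError("no threshold supplied or stored on the stRF")
    absv = np.abs(strf.values)
    supra_cols = np.nonzero((absv >= threshold).any(axis=1))[0]
    if supra_cols.size == 0:
        return {"preferred": None, "center": None, "null": None}
    c = int(np.unravel_index(int(np.argmax(absv)), absv.shape)[0])
    n_cols = strf.values.shape[0]

    def mk(cols: np.ndarray) -> TemporalFilter:
        vals = strf.values[cols].mean(axis=0)
        return TemporalFilter(
            values=vals,
            lag_step_s=strf.lag_step_s,
            peak_latency_s=float(np.argmax(np.abs(vals)) * strf.lag_step_s),
            decay_tau_s=_fit_decay_tau(vals, strf.lag_step_s),
            meta={"columns": cols.tolist()},
        )

    center_cols = np.arange(max(0, c - 1), min(n_cols, c + 2))
    out: dict[str, TemporalFilter | None] = {"center": mk(center_cols)}
    left = supra_cols[supra_cols < c]
    right = supra_cols[supra_cols > c]
    out["preferred"] = mk(np.arange(left.min(), c + 1)) if left.size else None
    out["null"] = mk(np.arange(c, right.max() + 1)) if right.size else None
    return out
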