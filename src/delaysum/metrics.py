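"""Scalar response metrics: DSI, DCI and change indices, exponential decay
fits, frequency/contrast sensitivity from modulating-flash responses, and
speed-tuning curves with a Gaussian-fit optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from delaysum.traces import Trace

__all__ = [
    "DirectionalResponse",
    "TuningCurve",
    "DecayFit",
    "dsi",
    "dci",
    "change_index",
    "fit_decay",
    "freq_contrast_sensitivity",
    "speed_tuning",
    "directional_response",
    "mww_test",
    "signed_rank_test",
]

#: classification cutoffs from the recording conventions: ON DS cells have
#: firing DSI > 0.3 at 150 um/s; non-DS cells stay below 0.2 at all speeds
ON_DS_MIN_DSI = 0.3
NON_DS_MAX_DSI = 0.2


def dsi(resp_pref: float, resp_null: float) -> float:
    """Direction selectivity index (p - n) / (p + n).

    Both responses must be non-negative magnitudes and not both zero.
    """
    if resp_pref < 0 or resp_null < 0:
        raise ValueError("responses must be non-negative magnitudes")
    if resp_pref == 0 and resp_null == 0:
        raise ValueError("DSI undefined for two zero responses")
    return (resp_pref - resp_null) / (resp_pref + resp_null)


def dci(tau_control: float, tau_blocker: float) -> float:
    """Decay change index (tau_c - tau_b) / (tau_c + tau_b).

    Negative values mean the blocker prolonged the decay.
    """
    if tau_control <= 0 or tau_blocker <= 0:
        raise ValueError("decay constants must be positive")
    return (tau_control - tau_blocker) / (tau_control + tau_blocker)


def change_index(x_control: float, x_blocker: float) -> float:
    """The DCI contract applied to any positive metric (latency, amplitude,
    input amount)."""
    return dci(x_control, x_blocker)


@dataclass
class DecayFit:
    tau_s: float
    amplitude: float
    offset: float
    rms_residual: float
    ok: bool


def fit_decay(trace: Trace, window_s: tuple[float, float] | None = None) -> DecayFit:
    """Least-squares single-exponential fit from the response peak.

    ``window_s`` (relative to the trace start) defaults to peak-to-end. A
    non-decaying segment is flagged ``ok = False`` with the fitted tau and
    residual still reported.
    """
    v = trace.values
    t = trace.times - trace.t0_s
    if window_s is None:
        p = int(np.argmax(v))
        sl = slice(p, v.size)
    else:
        i0 = int(round(window_s[0] * trace.rate_hz))
        i1 = int(round(window_s[1] * trace.rate_hz))
        sl = slice(i0, max(i0 + 3, i1))
    y = v[sl]
    tt = t[sl] - t[sl][0]
    if y.size < 3 or y[0] <= 0:
        return DecayFit(np.nan, np.nan, np.nan, np.nan, False)

    def model(p):
        a, tau, c = p
        return a * np.exp(-tt / tau) + c

    a0 = max(y[0] - y[-1], 1e-12)
    p0 = [a0, max(tt[-1] / 3.0, 1e-3), y[-1]]
    try:
        res = optimize.least_squares(
            lambda p: model(p) - y, p0,
            bounds=([0, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
        )
        a, tau, c = res.x
        rms = float(np.sqrt(np.mean(res.fun**2)))
    except Exception:
        return DecayFit(np.nan, np.nan, np.nan, np.nan, False)
    decaying = y[0] - y[-1] > 3 * np.std(np.diff(y)) / np.sqrt(2) and a > 0
    return DecayFit(float(tau), float(a), float(c), rms, bool(decaying))


@dataclass
class TuningCurve:
    """A response-vs-stimulus-parameter curve with a fitted optimum."""

    x: np.ndarray
    y: np.ndarray
    fit_params: dict = field(default_factory=dict)
    optimum_x: float = np.nan
    at_boundary: bool = False
    kind: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.size != self.y.size:
            raise ValueError("x and y must match")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")


def _poly_optimum(x: np.ndarray, y: np.ndarray, order: int) -> tuple[dict, float, bool]:
    order = min(order, x.size - 1)
    coef = np.polyfit(x, y, order)
    xs = np.linspace(x[0], x[-1], 512)
    ys = np.polyval(coef, xs)
    i = int(np.argmax(ys))
    boundary = i in (0, xs.size - 1)
    return {"poly_coef": coef.tolist(), "order": order}, float(xs[i]), boundary


def freq_contrast_sensitivity(
    trace: Trace,
    flash_schedule: list[dict],
    baseline_s: float = 1.0,
    poly_order: int = 3,
    n_bins: int = 12,
) -> tuple[TuningCurve, TuningCurve]:
    """Frequency and contrast tuning from a modulating-flash response.

    For the frequency-sweep and contrast-ramp phases, per-cycle response
    amplitudes (peak minus trough envelope in time bins) are normalised by the
    mean response over the ``baseline_s`` window before each phase and plotted
    against the instantaneous frequency / contrast; a polynomial fit (default
    cubic) supplies the preferred frequency and contrast.
    """
    v = trace.values
    rate = trace.rate_hz

    def phase(name: str) -> dict:
        for ph in flash_schedule:
            if ph["name"] == name:
                return ph
        raise ValueError(f"schedule lacks phase {name!r}")

    def phase_curve(ph: dict, x_of_t) -> tuple[np.ndarray, np.ndarray]:
        i0 = int(round(ph["t_start_s"] * rate))
        i1 = int(round(ph["t_end_s"] * rate))
        b0 = max(0, i0 - int(round(baseline_s * rate)))
        base = float(np.mean(v[b0:i0])) if i0 > b0 else float(np.mean(v[:i0]))
        if base == 0:
            raise ValueError("zero baseline before a modulating phase")
        seg = v[i0:i1]
        edges = np.linspace(0, seg.size, n_bins + 1).astype(int)
        amps, xs = [], []
        dur = ph["t_end_s"] - ph["t_start_s"]
        for a, b in zip(edges[:-1], edges[1:]):
            if b - a < 2:
                continue
            amps.append((seg[a:b].max() - seg[a:b].min()) / abs(base))
            t_mid = (a + b) / 2.0 / rate
            xs.append(x_of_t(t_mid, dur))
        return np.asarray(xs), np.asarray(amps)

    fp = phase("freq_sweep")
    f0, f1 = fp["f0_hz"], fp["f1_hz"]
    xf, yf = phase_curve(fp, lambda t, dur: f0 + (f1 - f0) * t / dur)
    fitf, optf, bf = _poly_optimum(xf, yf, poly_order)
    freq = TuningCurve(xf, yf, fitf, optf, bf, kind="frequency")

    cp = phase("contrast_ramp")
    c0, c1 = cp["c0"], cp["c1"]
    xc, yc = phase_curve(cp, lambda t, dur: c0 + (c1 - c0) * t / dur)
    fitc, optc, bc = _poly_optimum(xc, yc, poly_order)
    contrast = TuningCurve(xc, yc, fitc, optc, bc, kind="contrast")
    return freq, contrast


def speed_tuning(
    responses_by_speed: dict[float, float] | tuple[np.ndarray, np.ndarray],
    log_axis: bool = True,
) -> TuningCurve:
    """Gaussian least-squares fit of response vs speed; optimum = fitted mean.

    Speed grids are typically log-spaced and the tuning falls off over a
    decade, so the Gaussian is fitted on log10(speed) by default
    (``log_axis=False`` fits on the linear axis). Falls back to the arg-max
    speed (flagged) when the fit degenerates; an optimum at the grid boundary
    is flagged.
    """
    if isinstance(responses_by_speed, dict):
        speeds = np.array(sorted(responses_by_speed))
        resp = np.array([responses_by_speed[s] for s in speeds])
    else:
        speeds, resp = map(np.asarray, responses_by_speed)
    if speeds.size < 4:
        raise ValueError("need at least 4 speeds")
    x = np.log10(speeds) if log_axis else speeds

    def model(p):
        a, mu, sig, c = p
        return a * np.exp(-0.5 * ((x - mu) / sig) ** 2) + c

    span = x[-1] - x[0]
    p0 = [resp.max() - resp.min(), x[int(np.argmax(resp))], span / 4.0, resp.min()]
    try:
        res = optimize.least_squares(
            lambda p: model(p) - resp, p0,
            bounds=([0, x[0] - span, 1e-6, -np.inf],
                    [np.inf, x[-1] + span, np.inf, np.inf]),
        )
        a, mu, sig, c = res.x
        degenerate = a <= 1e-12 or not np.isfinite(mu)
    except Exception:
        degenerate = True
    if degenerate:
        opt = float(speeds[int(np.argmax(resp))])
        return TuningCurve(speeds, resp, {"fallback": "argmax"}, opt,
                           opt in (speeds[0], speeds[-1]), kind="speed")
    mu_speed = float(10**mu) if log_axis else float(mu)
    opt = float(np.clip(mu_speed, speeds[0], speeds[-1]))
    return TuningCurve(
        speeds, resp,
        {"amplitude": float(a), "mean": mu_speed, "sigma": float(sig),
         "offset": float(c), "log_axis": log_axis},
        opt, bool(mu_speed <= speeds[0] or mu_speed >= speeds[-1]), kind="speed",
    )


@dataclass
class DirectionalResponse:
    """Responses to the 8-direction moving-spot protocol and the derived DSI."""

    directions_deg: np.ndarray
    resp: np.ndarray
    preferred_deg: float
    null_deg: float
    dsi: float

    @property
    def is_on_ds(self) -> bool:
        return self.dsi > ON_DS_MIN_DSI

    @property
    def is_non_ds(self) -> bool:
        return self.dsi < NON_DS_MAX_DSI


def directional_response(
    traces_by_direction: dict[float, Trace],
    motion_window_s: tuple[float, float] | None = None,
    baseline_window_s: tuple[float, float] | None = None,
    measure: str = "amplitude",
) -> DirectionalResponse:
    """Per-direction response magnitudes and the resulting DSI.

    The response per direction is the maximum of the absolute baseline-
    subtracted trace during motion (``measure="amplitude"``) or its time
    integral (``measure="charge"``). The preferred direction maximises the
    response; the null direction is preferred + 180 (mod 360).
    """
    if measure not in ("amplitude", "charge"):
        raise ValueError("measure must be 'amplitude' or 'charge'")
    dirs = np.array(sorted(traces_by_direction))
    resp = []
    for d in dirs:
        tr = traces_by_direction[d]
        v = tr.values
        if baseline_window_s is not None:
            b0 = int(round(baseline_window_s[0] * tr.rate_hz))
            b1 = int(round(baseline_window_s[1] * tr.rate_hz))
            v = v - v[b0:max(b0 + 1, b1)].mean()
        if motion_window_s is not None:
            i0 = int(round(motion_window_s[0] * tr.rate_hz))
            i1 = int(round(motion_window_s[1] * tr.rate_hz))
            v = v[i0:i1]
        if measure == "amplitude":
            resp.append(float(np.abs(v).max()))
        else:
            resp.append(abs(float(np.trapezoid(v, dx=1.0 / tr.rate_hz))))
    resp = np.array(resp)
    ip = int(np.argmax(resp))
    pref = float(dirs[ip])
    null = (pref + 180.0) % 360.0
    inull = int(np.argmin(np.abs(((dirs - null) + 180) % 360 - 180)))
    return DirectionalResponse(dirs, resp, pref, null,
                               dsi(resp[ip], resp[inull]))


def mww_test(a, b, alternative: str = "two-sided"):
    """Mann-Whitney-Wilcoxon rank-sum test (thin wrapper for report tables)."""
    from scipy.stats import mannwhitneyu

    return mannwhitneyu(a, b, alternative=alternative)


def signed_rank_test(a, b=None, alternative: str = "two-sided"):
    """Wilcoxon signed-rank test (thin wrapper for report tables)."""
    from scipy.stats import wilcoxon

    return wilcoxon(a, b, alternative=alternative)
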