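"""Uniformly sampled time series used across the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: recognised trace kinds
TRACE_KINDS = ("fluorescence_dff", "current", "model_input")


@dataclass
class Trace:
    """A uniformly sampled time series (fluorescence dF/F, current, or model input).

    Parameters
    ----------
    values : ndarray
        Sample values.
    rate_hz : float
        Sampling rate in Hz; must be positive.
    t0_s : float
        Time of the first sample in seconds.
    kind : str
        One of ``fluorescence_dff``, ``current``, ``model_input``.
    """

    values: np.ndarray
    rate_hz: float
    t0_s: float = 0.0
    kind: str = "model_input"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("Trace values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Trace values must be finite")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.kind not in TRACE_KINDS:
            raise ValueError(f"unknown trace kind {self.kind!r}")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0_s + np.arange(self.values.size) / self.rate_hz

    @property
    def duration_s(self) -> float:
        return self.values.size / self.rate_hz

    def charge(self) -> float:
        """Time integral of the trace (trapezoidal)."""
        return float(np.trapezoid(self.values, dx=1.0 / self.rate_hz))

    def resample(self, rate_hz: float) -> "Trace":
        """Linear-interpolation resample to a new rate on the same time span."""
        if rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        t_old = self.times
        n_new = max(2, int(round(self.duration_s * rate_hz)))
        t_new = self.t0_s + np.arange(n_new) / rate_hz
        vals = np.interp(t_new, t_old, self.values)
        return Trace(vals, rate_hz, self.t0_s, self.kind, dict(self.meta))
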