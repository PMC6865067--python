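"""Synthesis of observable data from ground-truth circuits: noisy unit traces,
two-photon-style imaging movies with planted ROI footprints, and summed
excitatory-current traces.

Everything here shares the forward model of :mod:`delaysum.model`; these
functions only add measurement structure (frame sampling, optical footprints,
photon or Gaussian noise) and return the ground truth alongside, so detection
and estimation stages can be scored against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from delaysum.circuit import CircuitModel, GlutUnit
from delaysum.model import MODEL_DT_S, simulate_population, simulate_unit
from delaysum.traces import Trace

__all__ = ["ImagingMovie", "unit_response", "render_imaging_movie", "synthesize_epsc"]


@dataclass
class ImagingMovie:
    """Pixel x time fluorescence movie (8-15 Hz class two-photon acquisition)."""

    frames: np.ndarray  # (nx, ny, nt), non-negative fluorescence
    frame_rate_hz: float
    px_size_um: float
    baseline: np.ndarray  # (nx, ny) mean pre-stimulus fluorescence
    origin: tuple[float, float] = (0.0, 0.0)
    pre_stimulus_s: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (x, y, t)")
        if self.frame_rate_hz <= 0 or self.px_size_um <= 0:
            raise ValueError("frame_rate_hz and px_size_um must be positive")
        if np.any(self.frames < 0):
            raise ValueError("fluorescence must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    @property
    def x_um(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.frames.shape[0]) * self.px_size_um

    @property
    def y_um(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.frames.shape[1]) * self.px_size_um


def unit_response(
    unit: GlutUnit,
    stimulus,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt: float = MODEL_DT_S,
    apply_envelope: bool = True,
) -> Trace:
    """Single-unit response trace: the forward model plus additive Gaussian noise.

    With ``noise_sd = 0`` this is bit-identical to
    :func:`delaysum.model.simulate_unit`.
    """
    trace = simulate_unit(unit, stimulus, dt=dt, apply_envelope=apply_envelope)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace = Trace(
            trace.values + rng.normal(0.0, noise_sd, trace.values.size),
            trace.rate_hz,
            trace.t0_s,
            trace.kind,
            dict(trace.meta),
        )
    return trace


def _bin_to_frames(values: np.ndarray, dt: float, frame_rate_hz: float) -> np.ndarray:
    """Average a dt-sampled trace into imaging frames (integrating detector)."""
    per = 1.0 / (frame_rate_hz * dt)
    n_frames = int(np.floor(values.size / per))
    edges = (np.arange(n_frames + 1) * per).astype(int)
    return np.add.reduceat(values, edges[:-1]) / np.diff(edges)


def render_imaging_movie(
    circuit: CircuitModel,
    stimulus,
    frame_rate_hz: float = 10.0,
    px_size_um: float = 0.5,
    psf_sigma_um: float = 0.9,
    noise_model: str = "gaussian",
    noise_sd: float = 0.02,
    photon_scale: float = 500.0,
    baseline: float = 1.0,
    pre_stimulus_s: float = 3.0,
    seed: int = 0,
    fov_um: tuple[float, float] | None = None,
) -> tuple[ImagingMovie, dict]:
    """Render a fluorescence movie of the circuit's responses to a stimulus.

    Each unit deposits its response trace onto a Gaussian optical footprint
    (sigma ``psf_sigma_um``; half-maximum area of a few um^2, matching bouton-
    sized ROIs). ``pre_stimulus_s`` of baseline-only frames are prepended so
    downstream dF/F normalisation has a spontaneous segment. Noise is either
    Gaussian (sd ``noise_sd`` in baseline units) or Poisson photon noise with
    ``photon_scale`` expected photons per baseline unit per frame.

    Returns the movie and a ground-truth dict with per-unit footprint masks
    (half-maximum, in movie pixel coordinates), centroids and noiseless traces.
    """
    if not 5.0 <= frame_rate_hz <= 20.0:
        raise ValueError("frame_rate_hz outside the supported 5-20 Hz range")
    if noise_model not in ("gaussian", "poisson", "none"):
        raise ValueError(f"unknown noise_model {noise_model!r}")
    import warnings

    if px_size_um > 2.0 * psf_sigma_um:
        warnings.warn("pixel size exceeds 2x the footprint sigma; footprints may vanish")

    pos = np.array([u.pos_um for u in circuit.units])
    margin = 4.0 * psf_sigma_um + 2.0
    if fov_um is None:
        x0, x1 = pos[:, 0].min() - margin, pos[:, 0].max() + margin
        y0, y1 = pos[:, 1].min() - margin, pos[:, 1].max() + margin
    else:
        (x0, x1), (y0, y1) = fov_um
    nx = int(np.ceil((x1 - x0) / px_size_um))
    ny = int(np.ceil((y1 - y0) / px_size_um))
    x = x0 + np.arange(nx) * px_size_um
    y = y0 + np.arange(ny) * px_size_um

    out = simulate_population(circuit, stimulus)
    # rows of per_unit are sorted by u; map back to circuit order
    per_unit = np.empty_like(out.per_unit)
    per_unit[out.unit_order] = out.per_unit
    frame_traces = np.stack(
        [_bin_to_frames(row, 1.0 / out.summed.rate_hz, frame_rate_hz) for row in per_unit]
    )
    n_pre = int(round(pre_stimulus_s * frame_rate_hz))
    frame_traces = np.concatenate(
        [np.zeros((frame_traces.shape[0], n_pre)), frame_traces], axis=1
    )
    nt = frame_traces.shape[1]

    movie = np.full((nx, ny, nt), float(baseline))
    masks: list[list[tuple[int, int]]] = []
    centroids: list[tuple[float, float]] = []
    for i, unit in enumerate(circuit.units):
        cx, cy = unit.pos_um
        fx = np.exp(-0.5 * ((x - cx) / psf_sigma_um) ** 2)
        fy = np.exp(-0.5 * ((y - cy) / psf_sigma_um) ** 2)
        foot = fx[:, None] * fy[None, :]
        movie += foot[:, :, None] * (baseline * frame_traces[i][None, None, :])
        mask = np.argwhere(foot >= 0.5)
        masks.append([tuple(p) for p in mask])
        centroids.append((cx, cy))

    rng = np.random.default_rng(seed)
    if noise_model == "gaussian":
        movie = movie + rng.normal(0.0, noise_sd * baseline, movie.shape)
    elif noise_model == "poisson":
        movie = rng.poisson(np.clip(movie, 0, None) * photon_scale) / photon_scale
    movie = np.clip(movie, 0.0, None)

    imaging = ImagingMovie(
        frames=movie,
        frame_rate_hz=frame_rate_hz,
        px_size_um=px_size_um,
        baseline=np.full((nx, ny), float(baseline)),
        origin=(float(x0), float(y0)),
        pre_stimulus_s=pre_stimulus_s,
        meta={"seed": seed, "noise_model": noise_model},
    )
    truth = {
        "masks_px": masks,
        "centroids_um": centroids,
        "traces": frame_traces,
        "groups": [u.group for u in circuit.units],
        "footprint_sigma_um": psf_sigma_um,
    }
    return imaging, truth


def synthesize_epsc(
    circuit: CircuitModel,
    stimulus,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt: float = MODEL_DT_S,
    apply_envelope: bool = True,
) -> Trace:
    """Summed excitatory input ("EPSC") trace: population sum plus noise.

    The magnitude convention is positive-going (metrics use magnitudes); flip
    the sign for inward-current plotting.
    """
    out = simulate_population(circuit, stimulus, dt=dt, apply_envelope=apply_envelope)
    values = out.summed.values
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, values.size)
    return Trace(values, 1.0 / dt, 0.0, "current", {"speed_um_s": out.speed_um_s,
                                                    "direction_deg": out.direction_deg})
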