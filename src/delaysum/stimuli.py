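"""Visual stimulus generators: dense noise, moving/static spots and bars, modulating flash.

All stimuli are Weber-contrast movies: pixel values are
``C = (L_stim - L_bg) / (L_stim + L_bg)`` and therefore live in [-1, 1].
The spatial frame is the dendritic plane of the modelled cell: the x axis is
the motion-preference axis (u), increasing along the preferred direction of
motion, with the dendritic-field centre at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusMovie",
    "make_dense_noise",
    "make_moving_spot",
    "make_modulating_flash",
    "make_static_spot",
]


@dataclass
class StimulusMovie:
    """A space x time contrast movie.

    ``frames`` has shape (nx, ny, nt) with values in [-1, 1]; ``origin`` is the
    position in micrometres of the centre of pixel (0, 0).
    """

    frames: np.ndarray
    px_size_um: float
    refresh_hz: float
    duration_s: float
    origin: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be 3-D (x, y, t)")
        if self.px_size_um <= 0 or self.refresh_hz <= 0 or self.duration_s <= 0:
            raise ValueError("px_size_um, refresh_hz and duration_s must be positive")
        amax = float(np.abs(self.frames).max(initial=0.0))
        if amax > 1.0 + 1e-9:
            raise ValueError("contrast values must lie in [-1, 1]")
        expected = int(round(self.duration_s * self.refresh_hz))
        if self.frames.shape[2] != expected:
            raise ValueError(
                f"frame count {self.frames.shape[2]} != round(duration*rate) = {expected}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Frame onset times in seconds."""
        return np.arange(self.n_frames) / self.refresh_hz

    @property
    def x_um(self) -> np.ndarray:
        """Pixel-centre x coordinates (motion-preference axis) in micrometres."""
        return self.origin[0] + np.arange(self.frames.shape[0]) * self.px_size_um

    @property
    def y_um(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.frames.shape[1]) * self.px_size_um


def _centered_origin(nx: int, ny: int, px: float) -> tuple[float, float]:
    return (-(nx - 1) / 2.0 * px, -(ny - 1) / 2.0 * px)


def make_dense_noise(
    px_size_um: float = 20.0,
    grid: tuple[int, int] = (20, 20),
    refresh_hz: float = 20.0,
    duration_s: float = 60.0,
    seed: int = 0,
) -> StimulusMovie:
    """Binary dense-noise checkerboard: each pixel flips independently between -1 and +1.

    Defaults follow the standard receptive-field mapping configuration: a
    20 x 20 matrix of black/white pixels refreshed at 20 Hz, pixel side
    10-20 um for imaging and 30-50 um for somatic-current recordings.
    """
    if duration_s <= 0 or refresh_hz <= 0:
        raise ValueError("duration_s and refresh_hz must be positive")
    if px_size_um <= 0:
        raise ValueError("px_size_um must be positive")
    nx, ny = grid
    if nx <= 0 or ny <= 0:
        raise ValueError("grid dimensions must be positive")
    nt = int(round(duration_s * refresh_hz))
    rng = np.random.default_rng(seed)
    frames = rng.integers(0, 2, size=(nx, ny, nt)).astype(float) * 2.0 - 1.0
    return StimulusMovie(
        frames,
        px_size_um,
        refresh_hz,
        duration_s,
        origin=_centered_origin(nx, ny, px_size_um),
        meta={"kind": "dense_noise", "seed": seed},
    )


def make_moving_spot(
    diameter_um: float = 300.0,
    contrast: float = 1.0,
    direction_deg: float = 0.0,
    speed_um_s: float = 200.0,
    field_um: float = 1200.0,
    window_um: tuple[float, float] | None = None,
    px_size_um: float = 10.0,
    refresh_hz: float = 60.0,
    field_width_um: float | None = None,
    shape: str = "disc",
) -> StimulusMovie:
    """A spot (or square bar) of fixed contrast traversing the field edge to edge.

    ``direction_deg = 0`` moves along +x, the preferred direction; the stimulus
    therefore enters on the preferred side (x < 0) first. The traversal time is
    ``(field_um + diameter_um) / speed_um_s``.  ``window_um = (width, length)``
    optionally masks contrast to a rectangle centred on the field (local-motion
    stimuli); width is across, length along, the motion axis.
    """
    if speed_um_s <= 0:
        raise ValueError("speed_um_s must be positive")
    if diameter_um > field_um:
        raise ValueError("spot diameter exceeds the stimulus field")
    if shape not in ("disc", "bar"):
        raise ValueError("shape must be 'disc' or 'bar'")
    if field_width_um is None:
        field_width_um = min(field_um, 2.0 * diameter_um)
    nx = int(round(field_um / px_size_um))
    ny = int(round(field_width_um / px_size_um))
    duration_s = (field_um + diameter_um) / speed_um_s
    nt = int(round(duration_s * refresh_hz))
    duration_s = nt / refresh_hz  # make frame count exact

    origin = _centered_origin(nx, ny, px_size_um)
    x = origin[0] + np.arange(nx) * px_size_um
    y = origin[1] + np.arange(ny) * px_size_um
    X, Y = np.meshgrid(x, y, indexing="ij")

    theta = np.deg2rad(direction_deg)
    ux, uy = np.cos(theta), np.sin(theta)
    # signed coordinate of each pixel along the motion axis
    P = X * ux + Y * uy
    Q = -X * uy + Y * ux
    start = -(field_um + diameter_um) / 2.0
    r = diameter_um / 2.0

    frames = np.zeros((nx, ny, nt))
    t = np.arange(nt) / refresh_hz
    centers = start + speed_um_s * t
    for k in range(nt):
        if shape == "disc":
            mask = (P - centers[k]) ** 2 + Q**2 <= r**2
        else:
            mask = (np.abs(P - centers[k]) <= r) & (np.abs(Q) <= r)
        frames[:, :, k] = np.where(mask, contrast, 0.0)

    if window_um is not None:
        w, l = window_um
        win = (np.abs(P) <= l / 2.0) & (np.abs(Q) <= w / 2.0)
        frames *= win[:, :, None]

    return StimulusMovie(
        frames,
        px_size_um,
        refresh_hz,
        duration_s,
        origin=origin,
        meta={
            "kind": "moving_spot",
            "shape": shape,
            "diameter_um": diameter_um,
            "direction_deg": direction_deg,
            "speed_um_s": speed_um_s,
            "start_center_um": start,
        },
    )


def make_static_spot(
    diameter_um: float = 500.0,
    contrast: float = 1.0,
    duration_s: float = 2.0,
    field_um: float | None = None,
    px_size_um: float = 10.0,
    refresh_hz: float = 60.0,
    pre_s: float = 0.0,
    post_s: float = 0.0,
) -> StimulusMovie:
    """Static disc of given contrast on a zero-contrast background.

    ``pre_s``/``post_s`` prepend/append blank frames (useful as a baseline
    segment for dF/F normalisation).
    """
    if field_um is None:
        field_um = max(1.5 * diameter_um, diameter_um + 2 * px_size_um)
    nx = ny = int(round(field_um / px_size_um))
    total_s = pre_s + duration_s + post_s
    nt = int(round(total_s * refresh_hz))
    origin = _centered_origin(nx, ny, px_size_um)
    x = origin[0] + np.arange(nx) * px_size_um
    y = origin[1] + np.arange(ny) * px_size_um
    X, Y = np.meshgrid(x, y, indexing="ij")
    disc = (X**2 + Y**2) <= (diameter_um / 2.0) ** 2

    frames = np.zeros((nx, ny, nt))
    on0 = int(round(pre_s * refresh_hz))
    on1 = int(round((pre_s + duration_s) * refresh_hz))
    frames[:, :, on0:on1] = np.where(disc, contrast, 0.0)[:, :, None]
    return StimulusMovie(
        frames,
        px_size_um,
        refresh_hz,
        total_s,
        origin=origin,
        meta={
            "kind": "static_spot",
            "diameter_um": diameter_um,
            "onset_s": pre_s,
            "offset_s": pre_s + duration_s,
        },
    )


def modulating_flash_profile(
    refresh_hz: float = 60.0,
    step_s: float = 3.0,
    chirp_s: float = 8.0,
    ramp_s: float = 8.0,
    gap_s: float = 1.0,
    chirp_f0_hz: float = 0.5,
    chirp_f1_hz: float = 8.0,
    ramp_c0: float = 0.05,
    ramp_c1: float = 0.80,
    ramp_carrier_hz: float = 2.0,
) -> tuple[np.ndarray, list[dict]]:
    """Temporal contrast profile of the four-phase modulating flash.

    Phases, each preceded by a ``gap_s`` blank baseline: (1) flash at 100 %
    contrast, (2) flash at 50 % contrast, (3) sinusoid of full contrast with
    frequency increasing from ``chirp_f0_hz`` to ``chirp_f1_hz``, (4) sinusoid
    at ``ramp_carrier_hz`` with contrast increasing from 5 % to 80 %.

    Returns the profile (one value per frame) and the phase schedule.
    """
    dt = 1.0 / refresh_hz
    segments: list[np.ndarray] = []
    schedule: list[dict] = []
    t_cursor = 0.0

    def add(values: np.ndarray, name: str, **extra) -> None:
        nonlocal t_cursor
        segments.append(values)
        schedule.append(
            {"name": name, "t_start_s": t_cursor, "t_end_s": t_cursor + values.size * dt, **extra}
        )
        t_cursor += values.size * dt

    def blank() -> None:
        add(np.zeros(int(round(gap_s * refresh_hz))), "gap")

    blank()
    add(np.full(int(round(step_s * refresh_hz)), 1.0), "step_full", contrast=1.0)
    blank()
    add(np.full(int(round(step_s * refresh_hz)), 0.5), "step_half", contrast=0.5)
    blank()
    n = int(round(chirp_s * refresh_hz))
    t = np.arange(n) * dt
    phase = 2 * np.pi * (chirp_f0_hz * t + (chirp_f1_hz - chirp_f0_hz) * t**2 / (2 * chirp_s))
    add(np.sin(phase), "freq_sweep", f0_hz=chirp_f0_hz, f1_hz=chirp_f1_hz)
    blank()
    n = int(round(ramp_s * refresh_hz))
    t = np.arange(n) * dt
    env = ramp_c0 + (ramp_c1 - ramp_c0) * t / ramp_s
    add(env * np.sin(2 * np.pi * ramp_carrier_hz * t), "contrast_ramp",
        c0=ramp_c0, c1=ramp_c1, carrier_hz=ramp_carrier_hz)

    return np.concatenate(segments), schedule


def make_modulating_flash(
    diameter_um: float = 500.0,
    px_size_um: float = 10.0,
    refresh_hz: float = 60.0,
    **profile_kwargs,
) -> StimulusMovie:
    """Four-phase modulating-flash spot (full flash, half-contrast flash,
    0.5-8 Hz frequency sweep, 5-80 % contrast ramp)."""
    profile, schedule = modulating_flash_profile(refresh_hz=refresh_hz, **profile_kwargs)
    field_um = 1.2 * diameter_um
    nx = ny = int(round(field_um / px_size_um))
    origin = _centered_origin(nx, ny, px_size_um)
    x = origin[0] + np.arange(nx) * px_size_um
    y = origin[1] + np.arange(ny) * px_size_um
    X, Y = np.meshgrid(x, y, indexing="ij")
    disc = ((X**2 + Y**2) <= (diameter_um / 2.0) ** 2).astype(float)

    frames = disc[:, :, None] * profile[None, None, :]
    duration_s = profile.size / refresh_hz
    return StimulusMovie(
        frames,
        px_size_um,
        refresh_hz,
        duration_s,
        origin=origin,
        meta={
            "kind": "modulating_flash",
            "diameter_um": diameter_um,
            "phases": schedule,
            "profile": profile,
        },
    )
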