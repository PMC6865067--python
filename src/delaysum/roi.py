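"""ROI detection in glutamate-imaging movies and dendritic-field geometry.

The detection pipeline follows the standard bouton-scale segmentation recipe:
3x3 Gaussian smoothing per frame, spatial downsampling to 0.7 of the original
grid, a responsive-pixel mask at baseline mean + 3 SD, Pearson correlation of
neighbouring pixel time courses, connected grouping above a correlation
threshold, and a 1-10 um^2 size filter matching bipolar-cell axonal boutons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage.transform import resize

from delaysum.synth import ImagingMovie
from delaysum.traces import Trace

__all__ = [
    "ROI",
    "detect_rois",
    "extract_trace",
    "dendritic_field_center",
    "roi_position_histogram",
]

#: accepted ROI area range (um^2), matching bipolar bouton size
ROI_AREA_RANGE_UM2 = (1.0, 10.0)


@dataclass
class ROI:
    """A detected region of interest.

    ``pixel_set`` is in original movie pixel coordinates, ``centroid_um`` in
    the movie's spatial frame.
    """

    id: int
    pixel_set: list[tuple[int, int]]
    area_um2: float
    centroid_um: tuple[float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pixel_set:
            raise ValueError("ROI pixel set is empty")


def _gaussian_3x3(frames: np.ndarray) -> np.ndarray:
    # sigma chosen so the kernel mass is essentially contained in 3x3 pixels
    return ndimage.gaussian_filter(frames, sigma=(0.65, 0.65, 0.0), radius=(1, 1, 0))


def detect_rois(
    movie: ImagingMovie,
    corr_threshold: float = 0.7,
    responsive_k_sd: float = 3.0,
    downsample: float = 0.7,
    footprint_fraction: float = 0.3,
) -> list[ROI]:
    """Detect bouton-scale ROIs in an imaging movie.

    Pipeline order is fixed: smooth, downsample (bilinear), mask pixels whose
    response exceeds their baseline mean + ``responsive_k_sd`` SD, group
    4-connected responsive pixels whose time courses correlate at or above
    ``corr_threshold``, and keep groups with area in 1-10 um^2. Returns an
    empty list (with a warning) when nothing is responsive.
    """
    if movie.n_frames < 50:
        raise ValueError("movie too short (need >= 50 frames)")
    n_base = int(round(movie.pre_stimulus_s * movie.frame_rate_hz))
    if n_base < 2:
        raise ValueError("movie lacks a pre-stimulus baseline segment")

    smoothed = _gaussian_3x3(movie.frames)
    nx, ny, nt = smoothed.shape
    dnx, dny = max(2, round(downsample * nx)), max(2, round(downsample * ny))
    ds = resize(smoothed, (dnx, dny, nt), order=1, anti_aliasing=False,
                preserve_range=True)
    px_ds_x = movie.px_size_um * nx / dnx
    px_ds_y = movie.px_size_um * ny / dny
    area_per_px = px_ds_x * px_ds_y

    base = ds[:, :, :n_base]
    mu = base.mean(axis=2)
    sd = base.std(axis=2, ddof=1)
    # responsive statistic: peak of the lightly time-smoothed stimulus-period
    # trace (3-frame boxcar), which suppresses single-frame noise excursions
    stim_part = ds[:, :, n_base:]
    kernel = np.ones(3) / 3.0
    sm = ndimage.convolve1d(stim_part, kernel, axis=2, mode="nearest")
    peak = sm.max(axis=2)
    responsive = peak > mu + responsive_k_sd * sd
    if not responsive.any():
        warnings.warn("no responsive pixels found")
        return []

    # correlation between 4-adjacent responsive pixels on baseline-subtracted
    # time courses
    z = ds - mu[:, :, None]
    norm = np.sqrt((z**2).sum(axis=2))
    norm[norm == 0] = np.inf
    zn = z / norm[:, :, None]

    labels = -np.ones((dnx, dny), dtype=int)
    next_label = 0
    idx = np.argwhere(responsive)
    idx_set = {tuple(p) for p in idx}
    for p in map(tuple, idx):
        if labels[p] >= 0:
            continue
        labels[p] = next_label
        stack = [p]
        while stack:
            cx, cy = stack.pop()
            for qx, qy in ((cx + 1, cy), (cx - 1, cy), (cx, cy + 1), (cx, cy - 1)):
                if (qx, qy) in idx_set and labels[qx, qy] < 0:
                    r = float((zn[cx, cy] * zn[qx, qy]).sum())
                    if r >= corr_threshold:
                        labels[qx, qy] = next_label
                        stack.append((qx, qy))
        next_label += 1

    x_ds = movie.origin[0] + (np.arange(dnx) + 0.5) * px_ds_x
    y_ds = movie.origin[1] + (np.arange(dny) + 0.5) * px_ds_y
    resp_amp = peak - mu
    candidates: list[tuple[np.ndarray, float]] = []
    oversized: set[tuple[int, int]] = set()
    for lab in range(next_label):
        pix = np.argwhere(labels == lab)
        # the bouton footprint is the part of the correlated patch above a
        # fraction of its peak response, which makes the area noise-invariant
        amp = resp_amp[pix[:, 0], pix[:, 1]]
        trimmed = pix[amp >= footprint_fraction * amp.max()]
        area = trimmed.shape[0] * area_per_px
        if area > ROI_AREA_RANGE_UM2[1]:
            oversized.update(map(tuple, pix))
            continue
        if area >= ROI_AREA_RANGE_UM2[0]:
            candidates.append((trimmed, area))

    rois: list[ROI] = []
    roi_id = 0
    for pix, area in candidates:
        # suppress rim fragments of structures already rejected as oversized
        near_oversized = any(
            (i + di, j + dj) in oversized
            for i, j in map(tuple, pix)
            for di in (-2, -1, 0, 1, 2)
            for dj in (-2, -1, 0, 1, 2)
        )
        if near_oversized:
            continue
        cx = float(x_ds[pix[:, 0]].mean()) - 0.5 * movie.px_size_um
        cy = float(y_ds[pix[:, 1]].mean()) - 0.5 * movie.px_size_um
        # map downsampled pixels back to original-grid coordinates
        orig = sorted(
            {(int(round(i * nx / dnx)), int(round(j * ny / dny))) for i, j in pix}
        )
        rois.append(
            ROI(
                id=roi_id,
                pixel_set=[p for p in orig if 0 <= p[0] < nx and 0 <= p[1] < ny],
                area_um2=float(area),
                centroid_um=(cx, cy),
                meta={"n_px_downsampled": int(pix.shape[0])},
            )
        )
        roi_id += 1
    return rois


def extract_trace(
    movie: ImagingMovie,
    roi: ROI,
    baseline_window_s: tuple[float, float] | None = None,
) -> Trace:
    """Mean fluorescence over the ROI pixels, normalised by its baseline mean.

    The baseline window defaults to all frames before stimulus onset
    (``movie.pre_stimulus_s``); it must precede the stimulus.
    """
    if not roi.pixel_set:
        raise ValueError("empty ROI")
    if baseline_window_s is None:
        baseline_window_s = (0.0, movie.pre_stimulus_s)
    b0, b1 = baseline_window_s
    if movie.pre_stimulus_s > 0 and b1 > movie.pre_stimulus_s + 1e-9:
        raise ValueError("baseline window must precede stimulus onset")
    ix = np.array([p[0] for p in roi.pixel_set])
    iy = np.array([p[1] for p in roi.pixel_set])
    raw = movie.frames[ix, iy, :].mean(axis=0)
    i0 = int(round(b0 * movie.frame_rate_hz))
    i1 = max(i0 + 1, int(round(b1 * movie.frame_rate_hz)))
    base = raw[i0:i1].mean() if i1 > i0 else raw.mean()
    if base <= 0:
        raise ValueError("non-positive baseline")
    return Trace(raw / base, movie.frame_rate_hz, 0.0, "fluorescence_dff",
                 {"roi_id": roi.id})


def dendritic_field_center(dendrite_mask: np.ndarray, px_size_um: float = 1.0,
                           origin: tuple[float, float] = (0.0, 0.0)
                           ) -> tuple[tuple[float, float], np.ndarray]:
    """Convex hull of a binary dendrite mask; returns (centroid, hull polygon).

    The centroid is the area centroid of the hull polygon, in micrometres.
    """
    mask = np.asarray(dendrite_mask, dtype=bool)
    pts = np.argwhere(mask).astype(float)
    if pts.shape[0] == 0:
        raise ValueError("empty dendrite mask")
    pts_um = origin + pts * px_size_um
    if pts.shape[0] < 3:
        return (tuple(pts_um.mean(axis=0))), pts_um
    hull = ConvexHull(pts_um)
    poly = pts_um[hull.vertices]
    # polygon area centroid (shoelace)
    x, y = poly[:, 0], poly[:, 1]
    xs, ys = np.roll(x, -1), np.roll(y, -1)
    cross = x * ys - xs * y
    area = cross.sum() / 2.0
    cx = ((x + xs) * cross).sum() / (6.0 * area)
    cy = ((y + ys) * cross).sum() / (6.0 * area)
    return (float(cx), float(cy)), poly


def roi_position_histogram(
    rois: list[ROI],
    center: tuple[float, float],
    axis_deg: float = 0.0,
    bin_um: float = 25.0,
    groups: list[str] | None = None,
    extent_um: float = 250.0,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Histogram of ROI centroids projected on the motion-preference axis.

    Returns ``{group: (counts, bin_edges)}``; with no group labels all ROIs
    are pooled under ``"all"``. Counts sum to the number of ROIs.
    """
    th = np.deg2rad(axis_deg)
    proj = np.array(
        [
            (r.centroid_um[0] - center[0]) * np.cos(th)
            + (r.centroid_um[1] - center[1]) * np.sin(th)
            for r in rois
        ]
    )
    nbin = max(1, int(np.ceil(2 * extent_um / bin_um)))
    edges = -extent_um + np.arange(nbin + 1) * bin_um
    proj = np.clip(proj, edges[0], edges[-1] - 1e-9)
    if groups is None:
        labels = ["all"] * len(rois)
    else:
        labels = list(groups)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for g in sorted(set(labels)):
        sel = proj[[i for i, lab in enumerate(labels) if lab == g]]
        counts, _ = np.histogram(sel, bins=edges)
        out[g] = (counts, edges)
    return out
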