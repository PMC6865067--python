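"""Readers/writers for the package's artifact formats.

Movies go to multi-page TIFF (pages = time) with a JSON/YAML metadata
sidecar; traces to CSV (time, value); circuits and ROIs to JSON. Every
writer records the generator seed when one is known.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from delaysum.circuit import CircuitModel, GlutUnit, TemporalKinetics
from delaysum.roi import ROI
from delaysum.stimuli import StimulusMovie
from delaysum.traces import Trace

__all__ = [
    "save_movie_tiff",
    "load_movie_tiff",
    "save_trace_csv",
    "load_trace_csv",
    "circuit_to_json",
    "circuit_from_json",
    "rois_to_json",
]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_movie_tiff(path, movie: StimulusMovie) -> None:
    """Write frames as a multi-page TIFF (pages = time) plus a YAML sidecar."""
    path = Path(path)
    pages = np.moveaxis(movie.frames, 2, 0).astype(np.float32)
    tifffile.imwrite(path, pages)
    meta = {
        "px_size_um": movie.px_size_um,
        "refresh_hz": movie.refresh_hz,
        "duration_s": movie.duration_s,
        "origin": list(movie.origin),
        "meta": {k: _jsonable(v) for k, v in movie.meta.items()
                 if not isinstance(v, np.ndarray)},
    }
    path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(meta))


def load_movie_tiff(path) -> StimulusMovie:
    path = Path(path)
    pages = tifffile.imread(path)
    meta = yaml.safe_load(path.with_suffix(path.suffix + ".yaml").read_text())
    return StimulusMovie(
        frames=np.moveaxis(pages, 0, 2).astype(float),
        px_size_um=meta["px_size_um"],
        refresh_hz=meta["refresh_hz"],
        duration_s=meta["duration_s"],
        origin=tuple(meta["origin"]),
        meta=meta.get("meta", {}),
    )


def save_trace_csv(path, trace: Trace) -> None:
    t = trace.times
    header = f"time_s,value # rate_hz={trace.rate_hz} kind={trace.kind}"
    np.savetxt(path, np.column_stack([t, trace.values]), delimiter=",",
               header=header, comments="")


def load_trace_csv(path, kind: str = "model_input") -> Trace:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    t, v = data[:, 0], data[:, 1]
    rate = 1.0 / np.median(np.diff(t))
    return Trace(v, float(rate), float(t[0]), kind)


def circuit_to_json(circuit: CircuitModel) -> str:
    units = [
        {
            "group": u.group,
            "pos_um": list(u.pos_um),
            "rf_center_um": list(u.rf_center_um),
            "rf_sigma_um": list(u.rf_sigma_um),
            "gain": u.gain,
            "kinetics": dataclasses.asdict(u.kinetics),
        }
        for u in circuit.units
    ]
    return json.dumps(
        {
            "units": units,
            "dendritic_center_um": list(circuit.dendritic_center_um),
            "dendritic_diameter_um": circuit.dendritic_diameter_um,
            "preferred_direction_deg": circuit.preferred_direction_deg,
            "seed": circuit.seed,
        },
        indent=1,
    )


def circuit_from_json(text: str) -> CircuitModel:
    d = json.loads(text)
    units = [
        GlutUnit(
            group=u["group"],
            pos_um=tuple(u["pos_um"]),
            kinetics=TemporalKinetics(**u["kinetics"]),
            rf_center_um=tuple(u["rf_center_um"]),
            rf_sigma_um=tuple(u["rf_sigma_um"]),
            gain=u["gain"],
        )
        for u in d["units"]
    ]
    return CircuitModel(
        units=units,
        dendritic_center_um=tuple(d["dendritic_center_um"]),
        dendritic_diameter_um=d["dendritic_diameter_um"],
        preferred_direction_deg=d["preferred_direction_deg"],
        seed=d.get("seed"),
    )


def rois_to_json(rois: list[ROI]) -> str:
    return json.dumps(
        [
            {
                "id": r.id,
                "pixel_set": [list(p) for p in r.pixel_set],
                "area_um2": r.area_um2,
                "centroid_um": list(r.centroid_um),
            }
            for r in rois
        ],
        indent=1,
    )
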