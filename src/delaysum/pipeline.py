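"""End-to-end orchestration: generate -> detect -> rf -> metrics -> cluster ->
model -> report, with a serialized config, per-stage seeding and an artifact
manifest with checksums.

A single run seed fans out to per-stage seeds through a counter-based spawn
(`numpy.random.SeedSequence(seed).spawn`), so any stage can be re-run in
isolation with an identical stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from delaysum import io as dio
from delaysum.circuit import (
    DEFAULT_GROUP_KINETICS,
    GROUPS,
    make_ground_truth_cell,
)
from delaysum.clustering import fit_gmm_bic, spca_features
from delaysum.metrics import fit_decay
from delaysum.model import (
    DEFAULT_SPEEDS,
    BarStimulus,
    model_dsi_curve,
    shuffled_model,
    simulate_unit,
    sustained_model,
)
from delaysum.receptive_fields import (
    control_threshold,
    reverse_correlate,
    strf_profile,
    strf_slope_and_activation,
)
from delaysum.roi import detect_rois, extract_trace
from delaysum.stimuli import make_dense_noise, make_modulating_flash
from delaysum.synth import render_imaging_movie, synthesize_epsc, unit_response
from delaysum.traces import Trace

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "report", "STAGES"]

STAGES = ("synth", "detect", "rf", "metrics", "cluster", "model", "report")

_CONFIG_KEYS = {
    "seed",
    "outdir",
    "stages",
    "circuit",
    "detection",
    "rf",
    "clustering",
    "model",
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run; unknown keys are rejected."""

    seed: int = 0
    outdir: str = "delaysum_run"
    stages: tuple[str, ...] = STAGES
    circuit: dict = field(default_factory=dict)
    detection: dict = field(default_factory=lambda: {"corr_threshold": 0.7})
    rf: dict = field(default_factory=lambda: {"noise_minutes": 4.0})
    clustering: dict = field(
        default_factory=lambda: {"n_rois": 150, "k_range": [2, 9], "n_restarts": 3}
    )
    model: dict = field(
        default_factory=lambda: {"variants": ["delay_sum", "shuffled", "sustained"],
                                 "n_shuffles": 10}
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        bad = [s for s in cfg.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        return cfg

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return yaml.safe_dump(d, sort_keys=True)


@dataclass
class RunManifest:
    """Artifacts produced by each executed stage, with sha256 checksums."""

    config_checksum: str
    stages: dict[str, dict] = field(default_factory=dict)

    def add(self, stage: str, outdir: Path, paths: list[Path]) -> None:
        self.stages[stage] = {
            "artifacts": {
                str(p.relative_to(outdir)): hashlib.sha256(p.read_bytes()).hexdigest()
                for p in paths
            }
        }

    def to_json(self) -> str:
        return json.dumps(
            {"config_checksum": self.config_checksum, "stages": self.stages}, indent=1
        )


def _stage_seed(seed: int, stage: str) -> int:
    # counter-based fan-out: child i of the run's SeedSequence
    child = np.random.SeedSequence(seed).spawn(len(STAGES))[STAGES.index(stage)]
    return int(child.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages in order; halt on the first failure.

    Every artifact lands under ``config.outdir``; the manifest lists each
    stage's files with checksums. Rerunning an identical config reproduces
    identical checksums.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = config.to_yaml()
    (out / "config.yaml").write_text(cfg_text)
    manifest = RunManifest(hashlib.sha256(cfg_text.encode()).hexdigest())

    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        runner = _STAGE_RUNNERS[stage]
        try:
            paths = runner(config, out, state)
        except Exception as exc:
            (out / "manifest.json").write_text(manifest.to_json())
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest.add(stage, out, paths)
        (out / "manifest.json").write_text(manifest.to_json())
    return manifest


# --------------------------------------------------------------------------
# stages


def _stage_synth(config: RunConfig, out: Path, state: dict) -> list[Path]:
    seed = _stage_seed(config.seed, "synth")
    circuit = make_ground_truth_cell(seed=seed, **config.circuit)
    state["circuit"] = circuit
    p = out / "circuit.json"
    p.write_text(dio.circuit_to_json(circuit))
    return [p]


def _stage_detect(config: RunConfig, out: Path, state: dict) -> list[Path]:
    seed = _stage_seed(config.seed, "detect")
    # a small, well-separated sub-circuit keeps the imaging fixture compact
    sub = make_ground_truth_cell(
        counts_by_group={g: 2 for g in GROUPS},
        seed=seed,
        scatter_sd_um=45.0,
        dendritic_diameter_um=160.0,
    )
    from delaysum.stimuli import make_static_spot

    stim = make_static_spot(diameter_um=500.0, contrast=1.0, duration_s=2.0,
                            pre_s=0.0, post_s=1.0)
    movie, truth = render_imaging_movie(sub, stim, seed=seed, noise_sd=0.02)
    rois = detect_rois(movie, **config.detection)
    state["rois"] = rois
    state["movie"] = movie
    paths = [out / "rois.json"]
    paths[0].write_text(dio.rois_to_json(rois))
    rows = []
    for r in rois:
        tr = extract_trace(movie, r)
        rows.append(pd.DataFrame({"roi": r.id, "time_s": tr.times, "dff": tr.values}))
    p = out / "roi_traces.csv"
    if rows:
        pd.concat(rows).to_csv(p, index=False)
    else:
        p.write_text("roi,time_s,dff\n")
    paths.append(p)
    return paths


def _stage_rf(config: RunConfig, out: Path, state: dict) -> list[Path]:
    seed = _stage_seed(config.seed, "rf")
    minutes = float(config.rf.get("noise_minutes", 4.0))
    noise = make_dense_noise(px_size_um=40.0, grid=(20, 20), refresh_hz=20.0,
                             duration_s=60.0 * minutes, seed=seed)
    circuit = state.get("circuit") or make_ground_truth_cell(
        seed=_stage_seed(config.seed, "synth"), **config.circuit
    )
    resp = synthesize_epsc(circuit, noise, noise_sd=0.0, apply_envelope=False)
    resp = Trace(resp.values, resp.rate_hz, kind="current",
                 meta={"stimulus_seed": seed})
    vol = reverse_correlate(resp, noise, max_lag_s=2.0)
    ctrl = make_dense_noise(px_size_um=40.0, grid=(20, 20), refresh_hz=20.0,
                            duration_s=60.0 * minutes, seed=seed + 1)
    thr = control_threshold(resp, ctrl, max_lag_s=2.0)
    prof = strf_profile(vol, axis_deg=0.0, width_um=80.0, length_um=640.0,
                        center_um=(0.0, 0.0))
    stats = strf_slope_and_activation(prof, thr)
    p = out / "strf.json"
    p.write_text(json.dumps({
        "threshold": thr,
        "slope_s_per_um": stats.slope_s_per_um,
        "optimal_speed_um_s": stats.optimal_speed_um_s,
        "mean_activation_s": stats.mean_activation_s,
        "n_columns": stats.n_columns,
        "ok": stats.ok,
    }, indent=1))
    state["strf_stats"] = stats
    return [p]


def _flash_responses(n_rois: int, seed: int, noise_sd: float = 0.15,
                     frame_hz: float = 20.0):
    """Noisy modulating-flash responses drawn from the six group archetypes."""
    from delaysum.circuit import GlutUnit

    flash = make_modulating_flash(px_size_um=25.0, refresh_hz=30.0)
    rng = np.random.default_rng(seed)
    groups = rng.choice(len(GROUPS), size=n_rois)
    base: dict[str, np.ndarray] = {}
    for g in GROUPS:
        unit = GlutUnit(group=g, pos_um=(0.0, 0.0),
                        kinetics=DEFAULT_GROUP_KINETICS[g])
        tr = unit_response(unit, flash, noise_sd=0.0)
        per = int(round(tr.rate_hz / frame_hz))
        base[g] = tr.values[: (tr.values.size // per) * per].reshape(-1, per).mean(axis=1)
    n_min = min(v.size for v in base.values())
    base = {g: v[:n_min] for g, v in base.items()}
    X = np.stack([
        base[GROUPS[g]] + rng.normal(0.0, noise_sd * np.abs(base[GROUPS[g]]).max(),
                                     base[GROUPS[g]].size)
        for g in groups
    ])
    return X, np.array([GROUPS[g] for g in groups]), flash


def _stage_metrics(config: RunConfig, out: Path, state: dict) -> list[Path]:
    from delaysum.circuit import GlutUnit
    from delaysum.stimuli import make_static_spot

    spot = make_static_spot(diameter_um=500.0, contrast=1.0, duration_s=2.0,
                            post_s=2.0)
    rows = []
    for g in GROUPS:
        unit = GlutUnit(group=g, pos_um=(0.0, 0.0),
                        kinetics=DEFAULT_GROUP_KINETICS[g])
        tr = unit_response(unit, spot)
        fit = fit_decay(tr)
        rows.append({
            "group": g,
            "peak_latency_s": DEFAULT_GROUP_KINETICS[g].peak_latency_s,
            "decay_tau_s": fit.tau_s,
            "decay_fit_ok": fit.ok,
            "peak_amplitude": float(tr.values.max()),
        })
    p = out / "group_metrics.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    return [p]


def _stage_cluster(config: RunConfig, out: Path, state: dict) -> list[Path]:
    seed = _stage_seed(config.seed, "cluster")
    n_rois = int(config.clustering.get("n_rois", 150))
    k_lo, k_hi = config.clustering.get("k_range", [2, 9])
    n_restarts = int(config.clustering.get("n_restarts", 3))
    X, truth, _ = _flash_responses(n_rois, seed)
    feats = spca_features(X, n_components=min(20, X.shape[1] - 1), sparsity=10,
                          seed=seed)
    cm = fit_gmm_bic(feats, k_range=range(k_lo, k_hi + 1),
                     n_restarts=n_restarts, seed=seed)
    state["cluster_model"] = cm
    p1 = out / "cluster_labels.csv"
    pd.DataFrame({"roi": np.arange(n_rois), "label": cm.labels,
                  "true_group": truth}).to_csv(p1, index=False)
    p2 = out / "bic_curve.csv"
    pd.DataFrame({"K": list(cm.bic_by_k), "bic": list(cm.bic_by_k.values())
                  }).to_csv(p2, index=False)
    return [p1, p2]


def _stage_model(config: RunConfig, out: Path, state: dict) -> list[Path]:
    seed = _stage_seed(config.seed, "model")
    circuit = state.get("circuit") or make_ground_truth_cell(
        seed=_stage_seed(config.seed, "synth"), **config.circuit
    )
    variants = config.model.get("variants", ["delay_sum"])
    rows = []
    results = {}
    if "delay_sum" in variants:
        results["delay_sum"] = model_dsi_curve(circuit)
    if "shuffled" in variants:
        results["shuffled"] = shuffled_model(
            circuit, n_shuffles=int(config.model.get("n_shuffles", 10)), seed=seed
        )
    if "sustained" in variants:
        results["sustained"] = sustained_model(circuit)
    for name, res in results.items():
        for i, v in enumerate(res.speeds):
            rows.append({
                "variant": name,
                "speed_um_s": v,
                "amplitude_pref": res.amplitude_pref[i],
                "amplitude_null": res.amplitude_null[i],
                "dsi_amplitude": res.dsi_amplitude[i],
                "dsi_charge": res.dsi_charge[i],
            })
    state["model_results"] = results
    p = out / "speed_tuning.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    return [p]


def _stage_report(config: RunConfig, out: Path, state: dict) -> list[Path]:
    return report_files(out)


_STAGE_RUNNERS = {
    "synth": _stage_synth,
    "detect": _stage_detect,
    "rf": _stage_rf,
    "metrics": _stage_metrics,
    "cluster": _stage_cluster,
    "model": _stage_model,
    "report": _stage_report,
}


def report_files(outdir) -> list[Path]:
    """Render summary figures for whichever stage outputs are present.

    Missing inputs skip their section with a notice in the summary; the
    rendering is idempotent.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    cfg_sum = ""
    if (out / "config.yaml").exists():
        cfg_sum = hashlib.sha256((out / "config.yaml").read_bytes()).hexdigest()[:12]
    produced: list[Path] = []
    notices: list[str] = []

    tuning = out / "speed_tuning.csv"
    if tuning.exists():
        df = pd.read_csv(tuning)
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        for name, sub in df.groupby("variant"):
            axes[0].plot(sub.speed_um_s, sub.amplitude_pref, "o-", label=name)
            axes[1].plot(sub.speed_um_s, sub.dsi_amplitude, "o-", label=name)
        for ax, ylab in zip(axes, ["summed peak amplitude", "amplitude DSI"]):
            ax.set_xscale("log")
            ax.set_xlabel("speed (um/s)")
            ax.set_ylabel(ylab)
        axes[0].legend(fontsize=7)
        fig.suptitle(f"config {cfg_sum}", fontsize=7)
        fig.tight_layout()
        p = out / "fig_speed_tuning.png"
        fig.savefig(p, dpi=110, metadata={"Software": f"delaysum {cfg_sum}"})
        plt.close(fig)
        produced.append(p)
    else:
        notices.append("model stage outputs missing: tuning figure skipped")

    bic = out / "bic_curve.csv"
    if bic.exists():
        df = pd.read_csv(bic)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(df.K, df.bic, "o-")
        ax.set_xlabel("number of clusters K")
        ax.set_ylabel("BIC")
        fig.suptitle(f"config {cfg_sum}", fontsize=7)
        fig.tight_layout()
        p = out / "fig_bic.png"
        fig.savefig(p, dpi=110, metadata={"Software": f"delaysum {cfg_sum}"})
        plt.close(fig)
        produced.append(p)
    else:
        notices.append("cluster stage outputs missing: BIC figure skipped")

    summary = out / "report_summary.json"
    summary.write_text(json.dumps(
        {"config_checksum": cfg_sum, "figures": [p.name for p in produced],
         "notices": notices}, indent=1))
    produced.append(summary)
    return produced


def report(manifest_or_dir) -> list[Path]:
    """Regenerate report figures from a manifest or a run directory."""
    if isinstance(manifest_or_dir, RunManifest):
        raise TypeError("pass the run directory; the manifest does not store paths")
    return report_files(manifest_or_dir)
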