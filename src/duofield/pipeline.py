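"""End-to-end orchestration: bundle I/O, configuration, the full run.

A *bundle* is a directory holding one session's inputs: per-area event
matrices (HDF5: values + timestamps + frame rate), the behavior log
(CSV lever trace plus CSV event timestamps), and a JSON configuration.
``run_full_analysis`` executes behavior → resampling → movement-related
classification → population matrices → affinity-propagation clustering
→ cross-area covariation statistics, and writes a report with full
provenance (config hash, seed, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .behavior import BehaviorLog, annotate_trials, detect_trials
from .population import (
    affinity_propagation,
    build_population_matrix,
    classify_movement_related,
    cluster_distance_agreement,
    cross_area_intra_cluster_cc,
    inter_cluster_distances,
    trial_similarity_matrix,
)
from .synthetic import SessionSpec, gen_behavior_log, gen_dual_area_session
from .traces import EventMatrix, resample_to_clock, union_clock


class PipelineError(RuntimeError):
    """A stage of the full analysis failed."""


@dataclass
class AnalysisConfig:
    """Every stage parameter of the full analysis, with printed defaults."""

    input_dir: str = "."
    output_dir: str = "out"
    areas: tuple[str, str] = ("RFA", "CFA")
    # behavior
    pull_threshold_mm: float = 5.0
    hold_s: float = 0.4
    response_window_s: float = 1.0
    rt_bounds_s: tuple[float, float] = (0.1, 0.5)
    lever_corr_window_s: tuple[float, float] = (-0.43, 1.85)
    # population
    move_win_frames: tuple[int, int] = (-5, 20)
    rest_win_frames: tuple[int, int] = (-25, -10)
    alpha: float = 0.05
    similarity: str = "cc"
    preference: str = "median"
    damping: float = 0.9
    n_shuffles: int = 1000
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisConfig":
        data = json.loads(text)
        fields = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in data.items() if k in fields}
        for name in ("areas", "rt_bounds_s", "lever_corr_window_s",
                     "move_win_frames", "rest_win_frames"):
            if name in kwargs:
                kwargs[name] = tuple(kwargs[name])
        return cls(**kwargs)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# bundle I/O


def write_events_h5(path: Path, ev: EventMatrix) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=ev.values)
        f.create_dataset("timestamps", data=ev.clock())
        f.create_dataset("unit_ids", data=np.asarray(ev.unit_ids))
        f.attrs["frame_rate"] = ev.frame_rate


def read_events_h5(path: Path) -> EventMatrix:
    with h5py.File(path, "r") as f:
        return EventMatrix(
            values=f["values"][()],
            frame_rate=float(f.attrs["frame_rate"]),
            timestamps=f["timestamps"][()],
            unit_ids=f["unit_ids"][()],
        )


def write_behavior_csv(dirpath: Path, log: BehaviorLog) -> None:
    t = log.times
    pd.DataFrame({"time_s": t, "lever_mm": log.lever_mm}).to_csv(
        dirpath / "behavior_lever.csv", index=False
    )
    events = pd.concat(
        [
            pd.DataFrame({"kind": "cue", "time_s": log.cue_times}),
            pd.DataFrame({"kind": "reward", "time_s": log.reward_times}),
        ]
    )
    events.to_csv(dirpath / "behavior_events.csv", index=False)


def read_behavior_csv(dirpath: Path) -> BehaviorLog:
    lever = pd.read_csv(dirpath / "behavior_lever.csv")
    events = pd.read_csv(dirpath / "behavior_events.csv")
    t = lever["time_s"].to_numpy()
    rate = 1.0 / float(np.median(np.diff(t)))
    return BehaviorLog(
        lever_mm=lever["lever_mm"].to_numpy(),
        rate=rate,
        cue_times=events.loc[events["kind"] == "cue", "time_s"].to_numpy(),
        reward_times=events.loc[events["kind"] == "reward", "time_s"].to_numpy(),
    )


def write_session_bundle(
    out_dir: str | Path, spec: SessionSpec, cfg: AnalysisConfig | None = None
) -> Path:
    """Emit a complete synthetic session bundle into ``out_dir``.

    The behavior log is generated first; the successful, selected pull
    onsets become the trial onsets of the dual-area event session, so
    the behavioral and neural files are mutually consistent.  Latent
    ground truth is stored alongside as JSON for recovery tests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = cfg or AnalysisConfig(seed=spec.seed)

    # oversample trials so that, after failures and selection, enough remain
    log, _planted = gen_behavior_log(
        n_trials=int(np.ceil(spec.n_trials / 0.8)) + 3,
        failure_fraction=0.1,
        pre_pull_fraction=0.05,
        seed=spec.seed,
    )
    trials = annotate_trials(
        log,
        detect_trials(log, cfg.pull_threshold_mm, cfg.hold_s, cfg.response_window_s),
        lever_corr_window=cfg.lever_corr_window_s,
    )
    onsets = trials.loc[trials["selected"], "pull_onset"].to_numpy()
    if onsets.size < spec.n_trials:
        raise PipelineError(
            f"only {onsets.size} selected trials generated; "
            f"{spec.n_trials} requested"
        )
    onsets = onsets[: spec.n_trials] + 8.0  # leave room for the rest window
    # truncate the log just after the last used trial so that re-detection
    # on the stored bundle recovers exactly these selected onsets
    stop_s = onsets[-1] - 8.0 + 4.0
    cues = np.asarray(log.cue_times)
    rewards = np.asarray(log.reward_times)
    n_keep = min(int(round((stop_s + 8.0) * log.rate)) - int(8.0 * log.rate),
                 log.lever_mm.size)
    shifted = BehaviorLog(
        lever_mm=np.concatenate(
            [np.zeros(int(8.0 * log.rate)), log.lever_mm[:n_keep]]
        ),
        rate=log.rate,
        cue_times=cues[cues <= stop_s] + 8.0,
        reward_times=rewards[rewards <= stop_s] + 8.0,
    )
    areas, truth = gen_dual_area_session(spec, onset_times=onsets)

    write_behavior_csv(out, shifted)
    for area in cfg.areas:
        write_events_h5(out / f"events_{area}.h5", areas[area].events_field)
    (out / "config.json").write_text(cfg.to_json())
    ground_truth = {
        "cluster_ids": {a: truth.cluster_ids[a].tolist() for a in truth.cluster_ids},
        "onset_times": onsets.tolist(),
        "spec": dataclasses.asdict(spec),
    }
    (out / "ground_truth.json").write_text(json.dumps(ground_truth, indent=2))
    return out


# ---------------------------------------------------------------------------
# full run


def run_covariation(
    events_by_area: dict[str, EventMatrix],
    onset_times: np.ndarray,
    cfg: AnalysisConfig,
) -> dict:
    """Population-covariation core on already-loaded event matrices.

    Resamples both areas onto their union clock, classifies movement-
    related neurons, builds population matrices, clusters trials on the
    first area's vectors, and scores the second area's within-cluster
    similarity against the shuffle null plus the inter-cluster distance
    agreement between areas.
    """
    area_a, area_b = cfg.areas
    clocks = [events_by_area[a].clock() for a in cfg.areas]
    clock = union_clock(*clocks)
    # restrict to the overlap so neither field needs extrapolation
    lo = max(c[0] for c in clocks)
    hi = min(c[-1] for c in clocks)
    clock = clock[(clock >= lo) & (clock <= hi)]
    resampled = {
        a: resample_to_clock(events_by_area[a], clock) for a in cfg.areas
    }
    pms = {}
    for a in cfg.areas:
        related, pvals, _ = classify_movement_related(
            resampled[a], onset_times, cfg.move_win_frames,
            cfg.rest_win_frames, cfg.alpha,
        )
        if not related.any():
            raise PipelineError(f"no movement-related neurons in {a}")
        pms[a] = build_population_matrix(
            resampled[a], onset_times, related, cfg.move_win_frames, area=a
        )
    S = trial_similarity_matrix(pms[area_a], kind=cfg.similarity)
    clusters = affinity_propagation(
        S, preference=cfg.preference, damping=cfg.damping, seed=cfg.seed
    )
    intra = cross_area_intra_cluster_cc(
        clusters, pms[area_b], n_shuffles=cfg.n_shuffles, seed=cfg.seed
    )
    report = {
        "resampled_rate_hz": float(resampled[area_a].frame_rate),
        "n_trials": int(onset_times.size),
        "n_related": {a: int(pms[a].matrix.shape[0]) for a in cfg.areas},
        "k_clusters": clusters.k,
        "converged": bool(clusters.converged),
        "preference": clusters.preference,
        "intra_cluster_cc": intra.observed,
        "shuffle_null_mean": intra.null_mean,
        "null_band_2p5": float(np.percentile(intra.null_values, 2.5)),
        "null_band_97p5": float(np.percentile(intra.null_values, 97.5)),
    }
    if clusters.k >= 3:
        dist = {
            a: inter_cluster_distances(pms[a], clusters, metric="cc")
            for a in cfg.areas
        }
        agreement = cluster_distance_agreement(dist[area_a], dist[area_b])
        report["distance_agreement_r"] = agreement["r"]
        report["distance_matrices"] = {
            a: dist[a].tolist() for a in cfg.areas
        }
    return report


def run_full_analysis(cfg: AnalysisConfig) -> dict:
    """Execute all stages on a bundle directory and write the report."""
    in_dir = Path(cfg.input_dir)
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    for fname in ["behavior_lever.csv", "behavior_events.csv"] + [
        f"events_{a}.h5" for a in cfg.areas
    ]:
        if not (in_dir / fname).exists():
            raise PipelineError(f"missing input file: {in_dir / fname}")

    log = _stage("load-behavior", read_behavior_csv, in_dir)
    trials = _stage(
        "behavior",
        lambda: annotate_trials(
            log,
            detect_trials(
                log, cfg.pull_threshold_mm, cfg.hold_s, cfg.response_window_s
            ),
            lever_corr_window=cfg.lever_corr_window_s,
        ),
    )
    selected = trials[trials["selected"]]
    if selected.empty:
        raise PipelineError("stage 'behavior' failed: no selected trials")
    onsets = selected["pull_onset"].to_numpy()

    events = {
        a: _stage(f"load-events-{a}", read_events_h5, in_dir / f"events_{a}.h5")
        for a in cfg.areas
    }
    report = _stage("covariation", run_covariation, events, onsets, cfg)
    report["n_trials_detected"] = int(len(trials))
    report["n_trials_selected"] = int(len(selected))
    report["provenance"] = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "duofield_version": __version__,
    }
    trials.to_csv(out_dir / "trials.csv", index=False)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out_dir / "config.json").write_text(cfg.to_json())
    return report
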