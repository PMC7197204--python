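"""Seeded end-to-end experiment runner.

Re-enacts the study's pipeline on synthetic data: build each
participant's pseudo-randomized schedule, simulate every trial in the
closed loop, generate subjective reports, export the tidy behavioral
table, synthesize multichannel neural data per trial, estimate
cortico-motor coherence against the human's ("self") and the VP's
("other") movement velocity with phase-scrambled controls, contrast
conditions with Z-coherence, and run group-level sign-flip permutation
statistics (max-stat over channels; cluster statistics over the
frequency axis) plus an FDR-corrected alpha-power contrast between the
interaction and a solo condition.

All randomness derives from one master seed through named
numpy SeedSequence spawns, recorded in the run manifest together with
SHA-256 checksums of every output file, so a run is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._version import __version__ as _version
from . import behavior, io
from .behavior import (interaction_segments, normalize_per_participant,
                       session_table, three_point_velocity)
from .neural import NeuralSimConfig, simulate_neural
from .oscillator import VPParams
from .participant import (HumanParams, ObserverParams, make_schedule,
                          simulate_reports, simulate_session)
from .permstats import (PermSpec, chain_adjacency, cluster_test, fdr_bh,
                        paired_t, sign_flip_test)
from .records import TrialRecord
from .spectral import (CoherenceResult, WindowSpec, band_summarize,
                       cortico_motor_coherence, default_bands,
                       phase_scramble, windowed_spectra, z_coherence)

logger = logging.getLogger("hdclamp")

__all__ = ["RunConfig", "RunManifest", "run_experiment"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to re-run a synthetic experiment."""

    n_participants: int = 20
    n_trials: int = 80
    block_size: int = 10
    master_seed: int = 0
    write_trials: bool = True
    vp: VPParams = field(default_factory=VPParams)
    human: HumanParams = field(default_factory=HumanParams)
    observer: ObserverParams = field(default_factory=ObserverParams)
    neural: NeuralSimConfig = field(default_factory=NeuralSimConfig)
    window: WindowSpec = field(default_factory=WindowSpec)
    perm: PermSpec = field(default_factory=lambda: PermSpec(
        mode="monte-carlo", n_perm=2000, seed=0))

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants for group stats")


@dataclass
class RunManifest:
    config: Dict
    version: str
    stage_seeds: Dict[str, int]
    files: Dict[str, str]
    timings_s: Dict[str, float]

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _stage_seed(master: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed below 2^31 derived from the master."""
    tag = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    ss = np.random.SeedSequence([master, tag, index])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _theta_band(f_move: float):
    return [b for b in default_bands(f_move) if b.name == "Theta"]


def run_experiment(cfg: RunConfig, outdir) -> RunManifest:
    """Run the full synthetic pipeline; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    timings: Dict[str, float] = {}
    files: Dict[str, str] = {}
    seeds: Dict[str, int] = {}

    def _finish_stage(name: str, t0: float) -> None:
        timings[name] = round(time.time() - t0, 3)
        logger.info("stage %s done in %.2f s", name, timings[name])

    # ---- stage: schedules and closed-loop simulation -------------------
    t0 = time.time()
    sessions: List[List[TrialRecord]] = []
    for p in range(cfg.n_participants):
        sched_seed = _stage_seed(cfg.master_seed, "schedule", p)
        sim_seed = _stage_seed(cfg.master_seed, "simulate", p)
        seeds[f"schedule_p{p}"] = sched_seed
        seeds[f"simulate_p{p}"] = sim_seed
        configs = make_schedule(cfg.n_trials, cfg.block_size,
                                seed=sched_seed, fs=1.0 / cfg.vp.dt)
        try:
            records = simulate_session(configs, cfg.human, cfg.vp,
                                       seed=sim_seed)
        except Exception as e:
            raise RuntimeError(
                f"stage simulate failed for participant {p}: {e}"
            ) from e
        for i, rec in enumerate(records):
            rep_seed = _stage_seed(cfg.master_seed, "report",
                                   p * cfg.n_trials + i)
            rec.reports = simulate_reports(rec, cfg.observer, seed=rep_seed)
        sessions.append(records)
    _finish_stage("simulate", t0)

    if cfg.write_trials:
        t0 = time.time()
        trial_dir = outdir / "trials"
        trial_dir.mkdir(exist_ok=True)
        for i, rec in enumerate(sessions[0]):
            path = trial_dir / f"trial_{i:03d}.tsv"
            io.write_trial(rec, path)
            files[str(path.relative_to(outdir))] = io.file_sha256(path)
            side = path.with_name(path.name + ".meta.json")
            files[str(side.relative_to(outdir))] = io.file_sha256(side)
        _finish_stage("write_trials", t0)

    # ---- stage: behavioral table ---------------------------------------
    t0 = time.time()
    tables = [session_table(records, participant=p)
              for p, records in enumerate(sessions)]
    table = pd.concat(tables, ignore_index=True)
    table = normalize_per_participant(
        table, ["report_coop", "humanness"], "participant")
    behavior_path = outdir / "behavior_table.tsv"
    behavior.export_trial_table(table, behavior_path)
    files["behavior_table.tsv"] = io.file_sha256(behavior_path)
    _finish_stage("behavior", t0)

    # ---- stage: synthetic neural data + coherence ----------------------
    t0 = time.time()
    f_move = sessions[0][0].config.f_move
    theta = _theta_band(f_move)
    fs = 1.0 / cfg.vp.dt
    n_ch = cfg.neural.n_channels
    # per participant x condition x channel theta coherence (self & other)
    theta_coh = {key: np.empty((cfg.n_participants, 2, n_ch))
                 for key in ("self", "other")}
    z_maps = {key: [] for key in ("self", "other")}
    alpha_power = np.empty((cfg.n_participants, 2, n_ch))
    alpha_band = [b for b in default_bands(f_move)
                  if b.name == "High-alpha"]
    z_freqs = None

    for p, records in enumerate(sessions):
        neural_trials, solo_trials = [], []
        vel = {"self": [], "other": []}
        for i, rec in enumerate(records):
            seg = interaction_segments(len(rec.human_x), fs,
                                       rec.config.interaction_s)
            nseed = _stage_seed(cfg.master_seed, "neural",
                                p * cfg.n_trials + i)
            nrec = simulate_neural(rec, cfg.neural, seed=nseed,
                                   condition="interaction",
                                   window=cfg.window)
            sseed = _stage_seed(cfg.master_seed, "neural_solo",
                                p * cfg.n_trials + i)
            srec = simulate_neural(rec, cfg.neural, seed=sseed,
                                   condition="solo", window=cfg.window)
            neural_trials.append(nrec.data[:, seg.retained])
            solo_trials.append(srec.data[:, seg.retained])
            vel["self"].append(
                three_point_velocity(rec.human_x, fs)[seg.retained])
            vel["other"].append(
                three_point_velocity(rec.vp_x, fs)[seg.retained])

        for key in ("self", "other"):
            real = cortico_motor_coherence(neural_trials, vel[key], fs,
                                           cfg.window)
            scr_seed = _stage_seed(cfg.master_seed, f"scramble_{key}", p)
            scrambled_vel = [
                phase_scramble(v, seed=scr_seed + i)
                for i, v in enumerate(vel[key])
            ]
            ctrl = cortico_motor_coherence(neural_trials, scrambled_vel,
                                           fs, cfg.window)
            theta_coh[key][p, 0] = band_summarize(
                real.coh, real.freqs, theta)["Theta"]
            theta_coh[key][p, 1] = band_summarize(
                ctrl.coh, ctrl.freqs, theta)["Theta"]
            z_maps[key].append(z_coherence(real.coh, real.df,
                                           ctrl.coh, ctrl.df))
            z_freqs = real.freqs
            seeds[f"scramble_{key}_p{p}"] = scr_seed

        for c, trials in enumerate((neural_trials, solo_trials)):
            sets = [windowed_spectra(tr, fs, cfg.window) for tr in trials]
            alpha_power[p, c] = band_summarize(
                np.mean(np.abs(np.concatenate(
                    [s.F for s in sets], axis=1)) ** 2, axis=1),
                sets[0].freqs, alpha_band)["High-alpha"]
    _finish_stage("neural", t0)

    # ---- stage: group statistics ---------------------------------------
    t0 = time.time()
    perm = PermSpec(mode=cfg.perm.mode, n_perm=cfg.perm.n_perm,
                    seed=_stage_seed(cfg.master_seed, "perm"))
    seeds["perm"] = int(perm.seed)
    stats: Dict[str, Dict] = {}
    for key in ("self", "other"):
        res = sign_flip_test(theta_coh[key], perm)
        flagged = [int(i) for i in
                   np.nonzero((res.p_maxstat < 0.05) & (res.t > 0))[0]]
        stats[f"{key}_vs_scrambled"] = dict(
            t=[float(v) for v in res.t],
            p_maxstat=[float(v) for v in res.p_maxstat],
            flagged_channels=flagged,
            n_permutations=res.n_permutations,
        )
        zbar = np.mean(np.stack(z_maps[key]), axis=0)
        zres = CoherenceResult(coh=zbar, freqs=z_freqs,
                               df=2 * 8 * cfg.n_trials)
        zpath = outdir / f"zcoherence_{key}.tsv"
        io.write_coherence(zres, zpath, condition=f"{key} vs scrambled")
        files[zpath.name] = io.file_sha256(zpath)
        files[zpath.name + ".meta.json"] = io.file_sha256(
            zpath.with_name(zpath.name + ".meta.json"))

    # cluster statistics over the frequency axis for planted self channels
    self_idx = list(cfg.neural.groups["self"])
    if self_idx and z_freqs is not None:
        keep = z_freqs <= 20.0
        zspec = np.stack([np.mean(z[self_idx][:, keep], axis=0)
                          for z in z_maps["self"]])
        cres = cluster_test(zspec, chain_adjacency(int(keep.sum())),
                            spec=perm)
        stats["self_z_frequency_clusters"] = dict(
            freqs=[float(f) for f in z_freqs[keep]],
            clusters=[dict(features=list(c.features), mass=c.mass,
                           sign=c.sign, p_value=c.p_value)
                      for c in cres.clusters],
        )

    # alpha-power contrast interaction vs solo, FDR corrected
    t_alpha = paired_t(alpha_power)
    from scipy.stats import t as t_dist
    p_alpha = 2.0 * t_dist.sf(np.abs(t_alpha), cfg.n_participants - 1)
    stats["alpha_power_interaction_vs_solo"] = dict(
        t=[float(v) for v in t_alpha],
        fdr_rejected=[bool(b) for b in fdr_bh(p_alpha, 0.05)],
    )
    stats_path = outdir / "group_stats.json"
    stats_path.write_text(json.dumps(stats, indent=1))
    files["group_stats.json"] = io.file_sha256(stats_path)
    _finish_stage("stats", t0)

    manifest = RunManifest(
        config=_config_snapshot(cfg),
        version=_version,
        stage_seeds=seeds,
        files=files,
        timings_s=timings,
    )
    manifest.save(outdir / "manifest.json")
    logger.info("experiment complete in %.1f s", time.time() - t_start)
    return manifest


def _config_snapshot(cfg: RunConfig) -> Dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        return obj

    return enc(cfg)
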