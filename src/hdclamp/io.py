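"""Plain-text file formats: trials, neural records, maps, and configs.

Everything is inspectable text: tab-separated tables for time series and
maps, JSON sidecars for metadata, and flat key=value sections for
parameter blocks. Round trips preserve full float precision.
"""

from __future__ import annotations

import ast
import configparser
import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .neural import NeuralRecord
from .oscillator import VPParams
from .records import Reports, TrialConfig, TrialRecord
from .spectral import CoherenceResult

__all__ = [
    "write_trial",
    "read_trial",
    "write_neural",
    "read_neural",
    "write_coherence",
    "read_coherence",
    "params_to_config",
    "params_from_config",
    "read_adjacency",
    "file_sha256",
]

_TRIAL_COLUMNS = ["time_s", "human_pos", "vp_pos", "vp_mu"]


def _sidecar(path: Union[str, Path]) -> Path:
    p = Path(path)
    return p.with_name(p.name + ".meta.json")


def write_trial(rec: TrialRecord, path: Union[str, Path]) -> None:
    """Write a trial as TSV (time_s, human_pos, vp_pos, vp_mu) + sidecar."""
    path = Path(path)
    df = pd.DataFrame({
        "time_s": rec.t,
        "human_pos": rec.human_x,
        "vp_pos": rec.vp_x,
        "vp_mu": rec.config.mu_series(),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    cfg = rec.config
    meta = {
        "task": cfg.task,
        "trial_type": cfg.trial_type,
        "pacing_s": cfg.pacing_s,
        "interaction_s": cfg.interaction_s,
        "fs": cfg.fs,
        "f_move": cfg.f_move,
        "vp_schedule": [list(s) for s in cfg.vp_schedule],
        "reports": None if rec.reports is None else list(rec.reports),
        "seed": rec.seed,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_trial(path: Union[str, Path]) -> TrialRecord:
    """Read a trial written by write_trial; validates format strictly."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path} is missing required column(s) {missing}"
        )
    side = _sidecar(path)
    if not side.exists():
        raise ValueError(f"missing metadata sidecar {side}")
    try:
        meta = json.loads(side.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed sidecar {side}: {e}") from e
    t = df["time_s"].to_numpy()
    dt = 1.0 / float(meta["fs"])
    steps = np.diff(t)
    bad = np.nonzero(~np.isclose(steps, dt, rtol=1e-6, atol=1e-9))[0]
    if bad.size:
        raise ValueError(
            f"non-uniform time grid in {path}: first bad step at index "
            f"{int(bad[0]) + 1} (dt={steps[bad[0]]!r}, expected {dt!r})"
        )
    cfg = TrialConfig(
        task=meta["task"],
        trial_type=meta["trial_type"],
        pacing_s=float(meta["pacing_s"]),
        interaction_s=float(meta["interaction_s"]),
        fs=float(meta["fs"]),
        f_move=float(meta["f_move"]),
        vp_schedule=tuple(
            (float(s), float(e), int(m)) for s, e, m in meta["vp_schedule"]
        ),
    )
    reports = meta.get("reports")
    return TrialRecord(
        config=cfg,
        t=t,
        human_x=df["human_pos"].to_numpy(),
        vp_x=df["vp_pos"].to_numpy(),
        reports=None if reports is None else Reports(*reports),
        seed=meta.get("seed"),
    )


def write_neural(rec: NeuralRecord, path: Union[str, Path]) -> None:
    """Header row of channel labels, then one row per channel."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(rec.labels) + "\n")
        np.savetxt(fh, rec.data, delimiter="\t", fmt="%.17g")
    meta = {
        "fs": rec.fs,
        "condition": rec.condition,
        "groups": {k: list(v) for k, v in rec.groups.items()},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_neural(path: Union[str, Path]) -> NeuralRecord:
    path = Path(path)
    with open(path) as fh:
        labels = fh.readline().rstrip("\n").split("\t")
        data = np.loadtxt(fh, delimiter="\t")
    data = np.atleast_2d(data)
    if data.shape[0] != len(labels):
        raise ValueError(
            f"{path}: {len(labels)} labels but {data.shape[0]} channel rows"
        )
    side = _sidecar(path)
    if not side.exists():
        raise ValueError(f"missing metadata sidecar {side}")
    meta = json.loads(side.read_text())
    return NeuralRecord(
        data=data,
        fs=float(meta["fs"]),
        labels=labels,
        groups={k: tuple(v) for k, v in meta["groups"].items()},
        condition=meta.get("condition", "interaction"),
    )


def write_coherence(res: CoherenceResult, path: Union[str, Path],
                    labels: Optional[Sequence[str]] = None,
                    condition: str = "") -> None:
    """Coherence (or Z) map as TSV with a frequency-axis header."""
    path = Path(path)
    coh = np.atleast_2d(res.coh)
    header = "\t".join(f"{f:g}Hz" for f in res.freqs)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, coh, delimiter="\t", fmt="%.17g")
    meta = {
        "df": int(res.df),
        "freqs_hz": [float(f) for f in res.freqs],
        "labels": None if labels is None else list(labels),
        "condition": condition,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_coherence(path: Union[str, Path]) -> CoherenceResult:
    path = Path(path)
    with open(path) as fh:
        fh.readline()
        coh = np.atleast_2d(np.loadtxt(fh, delimiter="\t"))
    meta = json.loads(_sidecar(path).read_text())
    return CoherenceResult(coh=coh, freqs=np.asarray(meta["freqs_hz"]),
                           df=int(meta["df"]))


def params_to_config(params, section: str = "vp") -> str:
    """Serialize a parameter dataclass as a [section] of key=value lines."""
    lines = [f"[{section}]"]
    for f in dataclasses.fields(params):
        lines.append(f"{f.name} = {getattr(params, f.name)!r}")
    return "\n".join(lines) + "\n"


def params_from_config(text: str, cls=VPParams, section: str = "vp"):
    """Parse a parameter block written by params_to_config.

    Values are parsed as Python literals only (ast.literal_eval); unknown
    keys are rejected with an explicit error.
    """
    cp = configparser.ConfigParser()
    cp.read_string(text)
    if section not in cp:
        raise ValueError(f"config has no [{section}] section")
    known = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, raw in cp[section].items():
        if key not in known:
            raise ValueError(
                f"unknown key {key!r} in [{section}] (expected one of "
                f"{sorted(known)})"
            )
        try:
            kwargs[key] = ast.literal_eval(raw)
        except (ValueError, SyntaxError) as e:
            raise ValueError(
                f"value for {key!r} is not a plain literal: {raw!r}"
            ) from e
    return cls(**kwargs)


def read_adjacency(path: Union[str, Path], n_features: int):
    """Symmetric adjacency from a two-column (i j) edge-list text file.

    Lines starting with '#' are ignored; indices are zero-based.
    """
    from .permstats import adjacency_from_edges

    edges = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(
                f"{path}:{ln}: expected two indices per line, got {line!r}"
            )
        edges.append((int(parts[0]), int(parts[1])))
    return adjacency_from_edges(edges, n_features)


def file_sha256(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
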