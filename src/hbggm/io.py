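"""File formats and configuration.

Time-series panels are plain delimited text (tab or comma), one file per
subject, listed in a JSON manifest::

    {
      "subjects": [
        {"id": "sub01", "path": "sub01.tsv", "orientation": "roi"},
        {"id": "sub02", "path": "sub02.tsv", "orientation": "time"}
      ],
      "labels": "labels.txt"        # optional, one ROI name per line
    }

``orientation`` declares whether rows are regions (``roi``, the default) or
time points (``time``).  Matrices and edge lists are written as TSV; specs,
configs and summaries as JSON/YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import TimeSeriesPanel
from .priors import HyperConstants
from .sampler import SamplerConfig
from .simulate import GroundTruth, SimulationSpec

__all__ = [
    "read_panel",
    "write_panel",
    "read_matrix",
    "write_matrix",
    "write_edge_list",
    "load_config",
    "spec_from_json",
    "spec_to_json",
    "write_truth",
]


def read_matrix(path) -> np.ndarray:
    """Read a delimited numeric matrix (tab or comma, optional header)."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    sep = "\t" if "\t" in path.read_text().splitlines()[0] else ","
    first = pd.read_csv(path, sep=sep, header=None, nrows=1)
    header = 0 if first.apply(lambda c: c.map(_non_numeric)).any().any() else None
    df = pd.read_csv(path, sep=sep, header=header, float_precision="round_trip")
    arr = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path}: non-numeric or non-finite cells")
    return arr


def _non_numeric(x) -> bool:
    try:
        float(x)
        return False
    except (TypeError, ValueError):
        return True


def write_matrix(M: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(M), delimiter="\t", fmt="%.17g")


def read_panel(manifest_path) -> TimeSeriesPanel:
    """Load a multi-subject panel from a JSON manifest (see module docs)."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    subjects = []
    p_seen: dict[str, int] = {}
    for entry in manifest["subjects"]:
        path = base / entry["path"]
        arr = read_matrix(path)
        if entry.get("orientation", "roi") == "time":
            arr = arr.T
        subjects.append(arr)
        p_seen[str(path)] = arr.shape[0]
    if len(set(p_seen.values())) > 1:
        detail = ", ".join(f"{k}: p={v}" for k, v in p_seen.items())
        raise ValueError(f"inconsistent ROI counts across subjects ({detail})")
    labels = None
    if manifest.get("labels"):
        labels = (base / manifest["labels"]).read_text().split()
    return TimeSeriesPanel(subjects, labels)


def write_panel(panel: TimeSeriesPanel, out_dir, prefix: str = "subject") -> Path:
    """Write each subject as TSV plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, y in enumerate(panel.subjects):
        name = f"{prefix}{i:03d}.tsv"
        write_matrix(y, out_dir / name)
        entries.append({"id": f"{prefix}{i:03d}", "path": name, "orientation": "roi"})
    manifest = {"subjects": entries}
    if panel.labels:
        (out_dir / "labels.txt").write_text("\n".join(panel.labels) + "\n")
        manifest["labels"] = "labels.txt"
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def write_edge_list(path, matrix: np.ndarray, prob: np.ndarray | None = None) -> None:
    """TSV edge list ``i, j, weight[, probability]`` over unordered pairs."""
    p = matrix.shape[0]
    iu = np.triu_indices(p, k=1)
    cols = {"i": iu[0] + 1, "j": iu[1] + 1, "weight": matrix[iu]}
    if prob is not None:
        cols["probability"] = prob[iu]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_truth(truth: GroundTruth, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, om in enumerate(truth.precisions):
        write_matrix(om, out_dir / f"truth_precision{i:03d}.tsv")
    write_matrix(truth.group_mean, out_dir / "truth_group_mean.tsv")
    write_edge_list(out_dir / "truth_graph.tsv", truth.graph.astype(float))


def spec_to_json(spec: SimulationSpec, path) -> None:
    d = asdict(spec)
    if d["graph"] is not None:
        d["graph"] = np.asarray(d["graph"]).astype(int).tolist()
    Path(path).write_text(json.dumps(d, indent=2))


def spec_from_json(path) -> SimulationSpec:
    d = json.loads(Path(path).read_text())
    if d.get("graph") is not None:
        d["graph"] = np.asarray(d["graph"])
    return SimulationSpec(**d)


def load_config(path) -> SamplerConfig:
    """Build a :class:`SamplerConfig` from a YAML/JSON document.

    Every sampler field and hyper-constant is overridable; unspecified
    values keep their defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    const = raw.pop("constants", {})
    cfg = SamplerConfig(**raw)
    if const:
        cfg.constants = HyperConstants(**{**asdict(cfg.constants), **const})
    return cfg
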