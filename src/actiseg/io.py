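"""Readers and writers for every artifact format, plus YAML configuration.

All tabular artifacts are plain CSV.  Writers prepend a small provenance
header of ``#``-prefixed comment lines (tool version, seed, config hash);
readers skip comment lines, so every writer/reader pair round-trips
numeric content at full float precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluate import PipelineConfig
from .models import SequenceModel
from .preprocess import ActivityLabeling, LabeledInterval, PreprocessConfig, TriaxialRecording
from .quantize import Codebook, PrimitiveSequence
from .subclass import SubclassMap

_FLOAT_FMT = "%.17g"


def _provenance(seed=None, config_hash=None) -> str:
    lines = [f"# generated-by: actiseg {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config_hash is not None:
        lines.append(f"# config-hash: {config_hash}")
    return "\n".join(lines) + "\n"


def _write_csv(df: pd.DataFrame, path, seed=None, config_hash=None, index=False):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance(seed, config_hash))
        df.to_csv(fh, index=index, float_format=_FLOAT_FMT)


def _read_csv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip", **kwargs)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# -- signals and labels ------------------------------------------------------

def write_signal_csv(recording: TriaxialRecording, path, seed=None) -> None:
    df = pd.DataFrame(
        {"timestamp": recording.timestamps, "x": recording.x,
         "y": recording.y, "z": recording.z}
    )
    _write_csv(df, path, seed=seed)


def read_signal_csv(path, run_id: str | None = None) -> TriaxialRecording:
    df = _read_csv(path)
    missing = {"timestamp", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return TriaxialRecording(
        run_id or Path(path).stem, df["timestamp"].to_numpy(),
        df["x"].to_numpy(), df["y"].to_numpy(), df["z"].to_numpy(),
    )


def write_labels_csv(labeling: ActivityLabeling, path, seed=None) -> None:
    df = pd.DataFrame(
        [{"start": iv.start, "end": iv.end, "activity": iv.activity}
         for iv in labeling.intervals],
        columns=["start", "end", "activity"],
    )
    _write_csv(df, path, seed=seed)


def read_labels_csv(path) -> ActivityLabeling:
    df = _read_csv(path)
    return ActivityLabeling(
        [LabeledInterval(r.start, r.end, str(r.activity)) for r in df.itertuples()]
    )


# -- codebook ----------------------------------------------------------------

def write_codebook(codebook: Codebook, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _write_csv(pd.DataFrame(codebook.centroids, columns=list(codebook.feature_order)),
               directory / "codebook.csv", seed=codebook.seed)
    (directory / "codebook.json").write_text(json.dumps(
        {"M": codebook.M, "seed": codebook.seed,
         "feature_order": list(codebook.feature_order)}, indent=1))


def read_codebook(directory) -> Codebook:
    directory = Path(directory)
    meta = json.loads((directory / "codebook.json").read_text())
    df = _read_csv(directory / "codebook.csv")
    return Codebook(centroids=df.to_numpy(), seed=meta.get("seed"),
                    feature_order=tuple(meta["feature_order"]))


# -- primitive sequences -----------------------------------------------------

def write_sequences_csv(seqs: list[PrimitiveSequence], path, seed=None) -> None:
    rows = [
        {"run_id": s.run_id, "position": t,
         "primitive": int(p), "label": str(lab)}
        for s in seqs for t, (p, lab) in enumerate(zip(s.primitives, s.labels))
    ]
    _write_csv(pd.DataFrame(rows, columns=["run_id", "position", "primitive", "label"]),
               path, seed=seed)


def read_sequences_csv(path) -> list[PrimitiveSequence]:
    df = _read_csv(path)
    out = []
    for run_id, grp in df.groupby("run_id", sort=False):
        grp = grp.sort_values("position")
        out.append(PrimitiveSequence(
            str(run_id), grp["primitive"].to_numpy(int),
            grp["label"].to_numpy(object)))
    return out


# -- sequence model ----------------------------------------------------------

def write_model(model: SequenceModel, directory, seed=None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "states": model.states, "M": model.M, "kmer_k": model.kmer_k,
        "kappa": model.kappa.tolist(), "weights": list(model.weights),
        "alpha": model.alpha, "pi": model.pi.tolist(),
        "kmer_default_logp": np.asarray(model.kmer_default_logp, float).tolist(),
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=1))
    _write_csv(pd.DataFrame(model.A, index=model.states, columns=model.states),
               directory / "A.csv", seed=seed, index=True)
    _write_csv(pd.DataFrame(model.B, index=model.states,
                            columns=[str(k + 1) for k in range(model.M)]),
               directory / "B.csv", seed=seed, index=True)
    rows = [
        {"state": model.states[i], "kmer": "-".join(map(str, km)), "logp": lp}
        for i, table in enumerate(model.kmer_logp) for km, lp in sorted(table.items())
    ]
    _write_csv(pd.DataFrame(rows, columns=["state", "kmer", "logp"]),
               directory / "kmers.csv", seed=seed)


def read_model(directory) -> SequenceModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    states = list(meta["states"])
    A = _read_csv(directory / "A.csv", index_col=0).to_numpy(float)
    B = _read_csv(directory / "B.csv", index_col=0).to_numpy(float)
    kdf = _read_csv(directory / "kmers.csv")
    tables: list[dict] = [{} for _ in states]
    sindex = {s: i for i, s in enumerate(states)}
    for r in kdf.itertuples():
        kmer = tuple(int(v) for v in str(r.kmer).split("-"))
        tables[sindex[str(r.state)]][kmer] = float(r.logp)
    return SequenceModel(
        states=states, M=int(meta["M"]), A=A, B=B,
        pi=np.asarray(meta["pi"], float), kmer_k=int(meta["kmer_k"]),
        kmer_logp=tables,
        kmer_default_logp=np.asarray(meta["kmer_default_logp"], float),
        kappa=np.asarray(meta["kappa"], int),
        weights=tuple(meta["weights"]), alpha=float(meta["alpha"]),
    )


# -- subclass map ------------------------------------------------------------

def write_subclass_map(submap: SubclassMap, path, seed=None) -> None:
    rows = [{"subclass": sub, "original_class": orig}
            for sub, orig in sorted(submap.mapping.items())]
    _write_csv(pd.DataFrame(rows, columns=["subclass", "original_class"]),
               path, seed=seed)


def read_subclass_map(path) -> SubclassMap:
    df = _read_csv(path)
    mapping = {str(r.subclass): str(r.original_class) for r in df.itertuples()}
    counts: dict[str, int] = {}
    for orig in mapping.values():
        counts[orig] = counts.get(orig, 0) + 1
    return SubclassMap(fragment_counts=counts, mapping=mapping)


# -- configuration -----------------------------------------------------------

def load_config(path) -> PipelineConfig:
    """Parse and validate a YAML pipeline configuration file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    pre = raw.pop("preprocess", {})
    known_pre = {"smoothing_n", "window_length", "overlap_fraction"}
    bad = set(pre) - known_pre
    if bad:
        raise ValueError(f"{path}: unknown preprocess keys {sorted(bad)}")
    known = {
        "n_primitives", "kmer_k", "alpha", "weights", "method",
        "transition_mode", "subclass_method", "subclass_fixed",
        "subclass_max_k", "time_bin_minutes", "seed",
    }
    bad = set(raw) - known
    if bad:
        raise ValueError(f"{path}: unknown keys {sorted(bad)}")
    if "weights" in raw:
        raw["weights"] = tuple(float(w) for w in raw["weights"])
    return PipelineConfig(preprocess=PreprocessConfig(**pre), **raw)


def save_config(config: PipelineConfig, path) -> None:
    data = asdict(config)
    data["weights"] = list(config.weights)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
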