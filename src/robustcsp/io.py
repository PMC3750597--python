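"""Plain-text trial archives: a JSON manifest plus one CSV matrix per trial.

The format is deliberately dependency-free and inspectable: ``manifest.json``
records shape, labels, sampling rate and provenance; each trial is a
channels-by-samples CSV written at full double precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .types import TrialDataset

FORMAT_VERSION = 1


def write_trial_archive(dataset: TrialDataset, path, provenance=None):
    """Write a dataset as manifest.json + trial_####.csv files; returns the manifest path."""
    dataset.validate()
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    files = []
    for i, trial in enumerate(dataset.trials):
        name = f"trial_{i:04d}.csv"
        np.savetxt(root / name, trial, delimiter=",", fmt="%.17g")
        files.append(name)
    manifest = {
        "format_version": FORMAT_VERSION,
        "n_trials": dataset.n_trials,
        "n_channels": dataset.n_channels,
        "n_samples": dataset.n_samples,
        "sampling_rate": dataset.sampling_rate,
        "channel_names": list(dataset.channel_names),
        "labels": [int(v) for v in dataset.labels],
        "role": dataset.role,
        "trials": files,
        "provenance": provenance or {},
    }
    mpath = root / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return mpath


def read_trial_archive(path) -> TrialDataset:
    """Load and validate a trial archive written by :func:`write_trial_archive`."""
    root = Path(path)
    mpath = root / "manifest.json" if root.is_dir() else root
    root = mpath.parent
    try:
        with open(mpath) as fh:
            manifest = json.load(fh)
    except FileNotFoundError:
        raise ValueError(f"corrupt archive: missing manifest at {mpath}")
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt archive: unreadable manifest ({exc})")
    files = manifest.get("trials", [])
    if len(files) != manifest.get("n_trials"):
        raise ValueError("corrupt archive: manifest n_trials does not match trial file list")
    trials = []
    for name in files:
        fpath = root / name
        if not fpath.exists():
            raise ValueError(f"corrupt archive: missing trial file {name}")
        try:
            X = np.loadtxt(fpath, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise ValueError(f"parse error: {name}: {exc}")
        if X.shape[0] != manifest["n_channels"]:
            raise ValueError(f"corrupt archive: {name} has {X.shape[0]} channels, "
                             f"manifest says {manifest['n_channels']}")
        trials.append(X)
    return TrialDataset(
        trials=trials,
        labels=np.array(manifest["labels"], dtype=int),
        sampling_rate=float(manifest["sampling_rate"]),
        channel_names=list(manifest["channel_names"]),
        role=manifest.get("role", "train"),
    )


def write_dataset_pair(train: TrialDataset, test: TrialDataset, path, provenance=None):
    """Write train/ and test/ sub-archives under one directory."""
    root = Path(path)
    write_trial_archive(train, root / "train", provenance=provenance)
    write_trial_archive(test, root / "test", provenance=provenance)
    return root


def read_dataset_pair(path):
    root = Path(path)
    return (read_trial_archive(root / "train"),
            read_trial_archive(root / "test"))


def write_mask(mask, path):
    """Corruption mask as a JSON sidecar."""
    with open(path, "w") as fh:
        json.dump({"entries": mask}, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return Path(path)


def read_mask(path):
    with open(path) as fh:
        return json.load(fh)["entries"]


def write_filterset(fset, path, extra=None):
    """Spatial filter set as JSON (matrix, scores, method, alpha, channels)."""
    payload = {
        "method": fset.method,
        "n_pairs": fset.n_pairs,
        "alpha": fset.alpha,
        "channel_names": fset.channel_names,
        "scores": [float(v) for v in fset.scores],
        "filters": [[float(v) for v in row] for row in fset.filters],
    }
    if extra:
        payload["config"] = extra
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return Path(path)


def write_predictions(results, path):
    """Pooled per-trial predictions/truths per (method, rate), for later McNemar."""
    payload = {"entries": [
        {"method": r.method, "rate": r.outlier_rate,
         "predictions": [int(v) for v in r.predictions],
         "truths": [int(v) for v in r.truths],
         "accuracies": [float(v) for v in r.accuracies]}
        for r in results]}
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)
        fh.write("\n")
    return Path(path)


def read_predictions(path):
    from .evaluation import EvaluationResult

    with open(path) as fh:
        payload = json.load(fh)
    return [EvaluationResult(method=e["method"], outlier_rate=float(e["rate"]),
                             accuracies=np.array(e["accuracies"], dtype=float),
                             predictions=np.array(e["predictions"], dtype=int),
                             truths=np.array(e["truths"], dtype=int))
            for e in payload["entries"]]


def read_config_file(path, cls):
    """Parse a flat ``key=value`` config file into a dataclass instance."""
    import dataclasses

    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"parse error: {path}:{lineno}: expected key=value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in fields:
                raise ValueError(f"parse error: {path}:{lineno}: unknown key {key!r}")
            default = fields[key].default
            if isinstance(default, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(value)
            elif isinstance(default, float):
                kwargs[key] = float(value)
            elif isinstance(default, tuple):
                kwargs[key] = tuple(float(v) for v in value.split(","))
            else:
                kwargs[key] = value
    return cls(**kwargs)
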