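"""Delimited-text readers/writers, flat-config parsing and run manifests.

External conventions: feature tables are CSV/TSV with a header row of
feature names, one sample per row, and an optional integer ``label`` column
holding 1-based class codes (the delimiter is auto-detected on read, comma
on write).  Class code 0 never appears in files — internally it indexes the
whole-domain membership column.  Every CLI fit writes a JSON run manifest
(config snapshot, input digests, seed, package version) before training so
a run can be reproduced bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "write_predictions",
    "read_predictions",
    "write_memberships",
    "parse_flat_config",
    "RunManifest",
]

LABEL_COLUMN = "label"
ID_COLUMN = "id"


def _detect_delimiter(path: Path) -> str:
    with open(path, "r") as handle:
        header = handle.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_feature_table(path, expect_labels: bool = False):
    """Read a delimited feature table.

    Returns ``(features, sample_ids, labels)``; ``labels`` is ``None`` unless
    ``expect_labels`` and then holds 1-based integer class codes.  Ragged
    rows, non-numeric or non-finite cells and a missing label column are
    rejected with the offending row/column named.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_detect_delimiter(path))
    if frame.shape[0] == 0:
        raise ValueError(f"{path}: table has no data rows")
    if ID_COLUMN in frame.columns:
        sample_ids = frame[ID_COLUMN].astype(str).to_numpy()
        frame = frame.drop(columns=[ID_COLUMN])
    else:
        sample_ids = np.array([f"s{i}" for i in range(frame.shape[0])])

    labels = None
    if expect_labels:
        if LABEL_COLUMN not in frame.columns:
            raise ValueError(f"{path}: expected a '{LABEL_COLUMN}' column")
    if LABEL_COLUMN in frame.columns:
        raw = frame[LABEL_COLUMN]
        if not np.array_equal(raw.to_numpy(), raw.astype(int).to_numpy()):
            raise ValueError(f"{path}: '{LABEL_COLUMN}' column must be integer")
        labels = raw.astype(int).to_numpy()
        if labels.min() < 1:
            raise ValueError(f"{path}: labels must be 1-based positive integers")
        frame = frame.drop(columns=[LABEL_COLUMN])

    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(numeric.to_numpy(dtype=float))
    if bad.any():
        row, col = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-numeric or non-finite value at row {row} "
            f"column '{frame.columns[col]}'"
        )
    features = numeric.to_numpy(dtype=float)
    return features, sample_ids, labels


def write_feature_table(path, features, sample_ids=None, labels=None, feature_names=None):
    """Write a feature table in the package's delimited convention."""
    features = np.asarray(features, dtype=float)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(features.shape[1])]
    frame = pd.DataFrame(features, columns=feature_names)
    if labels is not None:
        frame[LABEL_COLUMN] = np.asarray(labels, dtype=int)
    if sample_ids is not None:
        frame.insert(0, ID_COLUMN, sample_ids)
    frame.to_csv(path, index=False)


def write_predictions(path, sample_ids, labels, scores) -> None:
    """Write ``id, predicted_label, score_1..score_C`` rows."""
    sample_ids = np.asarray(sample_ids)
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or len(sample_ids) != len(labels) or len(labels) != scores.shape[0]:
        raise ValueError("sample_ids, labels and scores must have matching lengths")
    frame = pd.DataFrame({ID_COLUMN: sample_ids, "predicted_label": labels})
    for c in range(scores.shape[1]):
        frame[f"score_{c + 1}"] = scores[:, c]
    frame.to_csv(path, index=False)


def read_predictions(path):
    """Read back a predictions file; returns ``(sample_ids, labels, scores)``."""
    frame = pd.read_csv(path)
    score_cols = [c for c in frame.columns if c.startswith("score_")]
    return (
        frame[ID_COLUMN].astype(str).to_numpy(),
        frame["predicted_label"].astype(int).to_numpy(),
        frame[score_cols].to_numpy(dtype=float),
    )


def write_memberships(path, sample_ids, memberships) -> None:
    """Export the membership matrix with sample ids for outlier inspection."""
    memberships = np.asarray(memberships, dtype=float)
    frame = pd.DataFrame({ID_COLUMN: np.asarray(sample_ids)})
    frame["domain"] = memberships[:, 0]
    for c in range(1, memberships.shape[1]):
        frame[f"class_{c}"] = memberships[:, c]
    frame.to_csv(path, index=False)


def parse_flat_config(path) -> dict:
    """Parse a flat ``key = value`` config file into typed values.

    Blank lines and ``#`` comments are ignored; values are parsed as int,
    float, bool or left as strings.
    """
    config: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, raw = (part.strip() for part in line.split("=", 1))
        config[key] = _coerce(raw)
    return config


def _coerce(raw: str):
    lowered = raw.lower()
    if lowered in ("true", "false"):
        return lowered == "true"
    if lowered in ("none", ""):
        return None
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    return raw


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written before fitting starts."""

    config: dict
    input_digests: dict
    seed: int | None
    package_version: str
    log_path: str

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
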