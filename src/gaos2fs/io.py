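"""Matrix readers, run reports and config (de)serialisation.

The interchange format is a delimited numeric matrix (CSV/TSV), samples in
rows and features in columns by default, with empty cells, ``NA`` or ``NaN``
marking missing entries and an optional header row of feature identifiers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitness import ClassifierSpec, EvalProtocol
from .ga import GAParams
from .lfa import LfaParams
from .stream import SelectionState, StreamConfig

__all__ = [
    "MatrixFile",
    "read_matrix",
    "read_svmlight",
    "write_matrix",
    "read_labels",
    "write_run_report",
    "write_selected_tsv",
    "config_to_yaml",
    "config_from_yaml",
]

DEFAULT_MISSING = ("", "NA", "NaN", "nan")


@dataclass
class MatrixFile:
    """How to parse a delimited matrix file."""

    path: str
    delimiter: str = ","
    orientation: str = "samples_by_features"  # or "features_by_samples"
    missing_markers: tuple = DEFAULT_MISSING
    header: bool = True

    def __post_init__(self) -> None:
        if self.orientation not in ("samples_by_features", "features_by_samples"):
            raise ValueError("orientation must be samples_by_features or features_by_samples")


def read_matrix(file: MatrixFile | str):
    """Parse a delimited matrix into ``(values, mask, feature_ids)``.

    The result is normalised to samples x features; ``mask`` is True where a
    value was observed.  Feature ids come from the header when present and
    are synthesised as ``f0001, f0002, ...`` otherwise.
    """
    if isinstance(file, str):
        file = MatrixFile(path=file)
    path = Path(file.path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        df = pd.read_csv(
            path,
            sep=file.delimiter,
            header=0 if file.header else None,
            na_values=list(file.missing_markers),
            keep_default_na=False,
            skipinitialspace=True,
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"ragged or malformed matrix in {path}: {exc}") from exc
    values = df.to_numpy(dtype=float)
    if file.orientation == "features_by_samples":
        values = values.T
        ids = [f"f{j + 1:04d}" for j in range(values.shape[1])]
    elif file.header:
        ids = [str(c) for c in df.columns]
    else:
        ids = [f"f{j + 1:04d}" for j in range(values.shape[1])]
    mask = ~np.isnan(values)
    return values, mask, ids


def read_svmlight(path, absent_is_missing: bool = False):
    """Read a sparse svmlight/libsvm file into ``(values, mask, ids, labels)``.

    svmlight files store only explicit entries, so absent entries are
    ambiguous: by default they are zeros (the format's usual convention);
    with ``absent_is_missing=True`` they are treated as unobserved cells.
    """
    from sklearn.datasets import load_svmlight_file

    X, y = load_svmlight_file(str(path))
    dense = np.asarray(X.todense(), dtype=float)
    if absent_is_missing:
        mask = np.asarray((X != 0).todense())
    else:
        mask = np.ones_like(dense, dtype=bool)
    ids = [f"f{j + 1:04d}" for j in range(dense.shape[1])]
    return dense, mask, ids, y


def write_matrix(path, values, mask=None, feature_ids=None, delimiter: str = ",") -> None:
    """Write a samples x features matrix, masking hidden cells as ``NA``."""
    values = np.asarray(values, dtype=float)
    out = values.copy()
    if mask is not None:
        out[~np.asarray(mask, dtype=bool)] = np.nan
    cols = feature_ids if feature_ids is not None else [f"f{j + 1:04d}" for j in range(out.shape[1])]
    pd.DataFrame(out, columns=[str(c) for c in cols]).to_csv(
        path, sep=delimiter, index=False, na_rep="NA"
    )


def read_labels(path, delimiter: str = ",") -> np.ndarray:
    """Read a one-column label file (header optional, auto-detected)."""
    df = pd.read_csv(path, sep=delimiter, header=None)
    first = df.iloc[0, 0]
    try:
        float(first)
        col = df.iloc[:, 0]
    except (TypeError, ValueError):
        col = df.iloc[1:, 0]
    try:
        return pd.to_numeric(col).to_numpy()
    except (TypeError, ValueError):
        return col.to_numpy()


def _config_dict(config: StreamConfig) -> dict:
    return {
        "buffer_width": config.buffer_width,
        "lfa": asdict(config.lfa),
        "ga": asdict(config.ga),
        "classifier": asdict(config.classifier),
        "protocol": asdict(config.protocol),
        "redundancy_alpha": config.redundancy_alpha,
        "max_cond": config.max_cond,
        "master_seed": config.master_seed,
    }


def config_to_yaml(config: StreamConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_dict(config), fh, sort_keys=True)


def config_from_yaml(path) -> StreamConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["classifier"]["neighbors"] = int(d["classifier"].get("neighbors", 3))
    return StreamConfig(
        buffer_width=int(d["buffer_width"]),
        lfa=LfaParams(**d["lfa"]),
        ga=GAParams(**d["ga"]),
        classifier=ClassifierSpec(**d["classifier"]),
        protocol=EvalProtocol(**d["protocol"]),
        redundancy_alpha=float(d["redundancy_alpha"]),
        max_cond=int(d["max_cond"]),
        master_seed=int(d["master_seed"]),
    )


def write_run_report(state: SelectionState, config: StreamConfig, path) -> None:
    """JSON run report: selected ids, per-block history, parameters, seed."""
    report = {
        "software_version": __version__,
        "master_seed": config.master_seed,
        "config": _config_dict(config),
        "selected_ids": [str(i) for i in state.selected_ids],
        "total_features_seen": state.total_features_seen,
        "blocks": [
            {
                "block_index": r.block_index,
                "feature_ids": [str(i) for i in r.feature_ids],
                "missing_rate": r.missing_rate,
                "candidate_count": r.candidate_count,
                "ga_convergence": [float(v) for v in r.ga_curve],
                "ga_selected": [str(i) for i in r.ga_selected],
                "relevance_dropped": [str(i) for i in r.relevance_dropped],
                "prune_removed": [str(i) for i in r.prune_removed],
                "selected_after": [str(i) for i in r.selected_after],
            }
            for r in state.records
        ],
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)


def write_selected_tsv(state: SelectionState, path) -> None:
    """TSV of selected feature ids with the block in which each was selected."""
    first_block = {}
    for r in state.records:
        for fid in r.selected_after:
            first_block.setdefault(str(fid), r.block_index)
    with open(path, "w") as fh:
        fh.write("feature_id\tblock_of_selection\n")
        for fid in state.selected_ids:
            fh.write(f"{fid}\t{first_block.get(str(fid), -1)}\n")
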