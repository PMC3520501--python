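"""Data ingestion, the positivity shift transform, run configuration.

Input layout: a tab- (or otherwise) delimited expression matrix with genes in
rows — first column gene identifiers, header row of sample identifiers — and
a sample annotation table with columns ``sample_id``, ``group``, ``batch``.
Exactly two groups are supported.  Readers reject malformed input rather than
coerce it.

Pre-processing beyond the shift transform (normalisation, batch-effect
removal, covariate adjustment) is upstream responsibility: the package
consumes already-processed matrices.  The only transform offered is the
offset ``x + k`` that restores strict positivity after pre-processing steps
that can produce negative values (required by the gamma model; the log-normal
model also needs positive input).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .batch import ExpressionBatch
from .decisions import UtilityParams
from .sequential import DesignSpec

__all__ = [
    "read_expression_matrix",
    "read_sample_annotation",
    "assemble_batch",
    "write_expression_matrix",
    "shift_transform",
    "RunConfig",
    "write_manifest",
]

_AUTO_EPS = 1e-3


def read_expression_matrix(path: str | Path, *, sep: str = "\t") -> pd.DataFrame:
    """Read a genes-by-samples matrix; index = gene ids, columns = sample ids."""
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dupes[:10]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        gene, sample = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell in {path} at gene {df.index[gene]!r}, "
            f"sample {df.columns[sample]!r}: {df.iat[gene, sample]!r}"
        )
    if numeric.isna().to_numpy().any():
        gene, sample = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing value in {path} at gene {df.index[gene]!r}, "
            f"sample {df.columns[sample]!r}"
        )
    return numeric


def write_expression_matrix(df: pd.DataFrame, path: str | Path, *, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index_label="gene_id")


def read_sample_annotation(path: str | Path, *, sep: str = "\t") -> pd.DataFrame:
    """Read the sample table (sample_id, group, batch); validate its shape."""
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    required = {"sample_id", "group", "batch"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation {path} lacks columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in annotation")
    groups = df["group"].unique()
    if len(groups) != 2:
        raise ValueError(
            f"exactly two groups are supported, found {len(groups)}: "
            f"{sorted(map(str, groups))[:5]}"
        )
    batches = np.sort(df["batch"].astype(int).unique())
    if not np.array_equal(batches, np.arange(1, len(batches) + 1)):
        raise ValueError(
            f"batch numbering must be contiguous from 1, found {batches.tolist()}"
        )
    return df


def assemble_batch(matrix: pd.DataFrame, annotation: pd.DataFrame) -> ExpressionBatch:
    """Join matrix columns with the annotation into an ExpressionBatch.

    Sample order follows the matrix header; group labels are mapped to 0/1 in
    sorted label order.
    """
    unmatched = sorted(set(matrix.columns) ^ set(annotation["sample_id"]))
    if unmatched:
        raise ValueError(
            f"matrix header and annotation disagree on samples: {unmatched[:10]}"
        )
    ann = annotation.set_index("sample_id").loc[list(matrix.columns)]
    labels = sorted(ann["group"].unique(), key=str)
    groups = ann["group"].map({labels[0]: 0, labels[1]: 1}).to_numpy()
    return ExpressionBatch(
        values=matrix.to_numpy(dtype=float),
        groups=groups,
        batch_index=ann["batch"].astype(int).to_numpy(),
        gene_ids=matrix.index.to_numpy(),
        meta={"group_labels": {0: str(labels[0]), 1: str(labels[1])}},
    )


def shift_transform(batch: ExpressionBatch, k: float | str = "auto") -> ExpressionBatch:
    """Add an offset k to every value so that all outputs are strictly positive.

    ``k="auto"`` chooses ``max(0, eps - min(values))`` with ``eps = 1e-3``;
    an explicit k that leaves any value at or below zero is an error.  The
    applied offset is recorded in ``batch.meta['shift_k']``.
    """
    if batch.n_samples == 0:
        raise ValueError("cannot shift an empty batch")
    vmin = float(batch.values.min())
    if k == "auto":
        k = max(0.0, _AUTO_EPS - vmin)
    k = float(k)
    shifted = batch.values + k
    if shifted.min() <= 0:
        raise ValueError(
            f"offset k={k} leaves non-positive values (min {shifted.min():.4g}); "
            f"need k > {-vmin:.4g}"
        )
    meta = dict(batch.meta)
    meta["shift_k"] = k
    return replace(batch, values=shifted, meta=meta)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run bit-for-bit (given the seed)."""

    model_id: str = "nn"
    util: UtilityParams = field(default_factory=UtilityParams)
    design: DesignSpec = field(default_factory=lambda: DesignSpec(T=10))
    B: int = 500
    monitor_draws: int = 100
    grid_b0: tuple[float, float, int] = (0.0, 150.0, 21)  # lo, hi, steps
    grid_b1: tuple[float, float, int] = (-50.0, 50.0, 21)
    seed: int = 0
    shift_k: float | str = 0.0

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.linspace(*self.grid_b0[:2], int(self.grid_b0[2])),
            np.linspace(*self.grid_b1[:2], int(self.grid_b1[2])),
        )

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["util"] = dataclasses.asdict(self.util)
        out["design"] = dataclasses.asdict(self.design)
        return out

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "util" in raw and isinstance(raw["util"], dict):
            raw["util"] = UtilityParams(**raw["util"])
        if "design" in raw and isinstance(raw["design"], dict):
            d = dict(raw["design"])
            if "batch_composition" in d:
                d["batch_composition"] = tuple(d["batch_composition"])
            raw["design"] = DesignSpec(**d)
        for key in ("grid_b0", "grid_b1"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def write_manifest(path: str | Path, config: RunConfig, extra: dict | None = None) -> None:
    """Write the reproducibility manifest (config, seed, package version)."""
    from . import __version__

    payload = {"version": __version__, "config": config.to_dict()}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def write_hyperparams(path: str | Path, hyper, model_id: str) -> None:
    """Serialise a fitted hyperparameter vector as YAML."""
    import yaml

    payload = {"model": model_id}
    payload.update({k: float(v) for k, v in dataclasses.asdict(hyper).items()})
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_hyperparams(path: str | Path):
    """Load a hyperparameter YAML; returns (hyper, model_id)."""
    import yaml

    from .models import GaGaHyperParams, NNHyperParams

    raw = yaml.safe_load(Path(path).read_text())
    model_id = raw.pop("model")
    cls = {"gaga": GaGaHyperParams, "nn": NNHyperParams}.get(model_id)
    if cls is None:
        raise ValueError(f"unknown model {model_id!r} in {path}")
    return cls(**{k: float(v) for k, v in raw.items()}), model_id
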