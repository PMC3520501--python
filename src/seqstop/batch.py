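"""Expression data container shared by all models and the sequential engine.

An :class:`ExpressionBatch` holds a genes-by-samples matrix together with the
two-group labels and the batch index of every sample.  Data accrue in batches:
batch indices are contiguous integers starting at 1, and the number of observed
batches ``t`` is the largest index present (0 for an empty container, which is
a valid starting point for design before any data exist).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = ["ExpressionBatch"]


@dataclass(frozen=True)
class ExpressionBatch:
    """Genes x samples expression measurements with group and batch labels.

    Parameters
    ----------
    values
        Array of shape ``(n_genes, n_samples)``.  Strictly positive values are
        required by the gamma model; the log-normal model log-transforms
        internally and therefore also requires positive values.  Positivity is
        not enforced here (a shifted transform may be applied first) but is
        checked by the models.
    groups
        Integer array of shape ``(n_samples,)`` with entries in ``{0, 1}``.
    batch_index
        Integer array of shape ``(n_samples,)``; contiguous values starting
        at 1, each batch non-empty.
    gene_ids
        Sequence of ``n_genes`` unique identifiers.
    meta
        Free-form provenance (e.g. the shift offset applied on ingest).
    """

    values: np.ndarray
    groups: np.ndarray
    batch_index: np.ndarray
    gene_ids: np.ndarray
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        groups = np.asarray(self.groups, dtype=int)
        batch_index = np.asarray(self.batch_index, dtype=int)
        gene_ids = np.asarray(self.gene_ids)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D genes-by-samples array")
        n, j = values.shape
        if groups.shape != (j,):
            raise ValueError(f"groups has shape {groups.shape}, expected ({j},)")
        if batch_index.shape != (j,):
            raise ValueError(f"batch_index has shape {batch_index.shape}, expected ({j},)")
        if gene_ids.shape != (n,):
            raise ValueError(f"gene_ids has shape {gene_ids.shape}, expected ({n},)")
        if len(np.unique(gene_ids)) != n:
            raise ValueError("gene_ids must be unique")
        if j > 0:
            bad = set(np.unique(groups)) - {0, 1}
            if bad:
                raise ValueError(f"group labels must be 0/1, found {sorted(bad)}")
            t = batch_index.max()
            present = np.unique(batch_index)
            if batch_index.min() < 1 or not np.array_equal(present, np.arange(1, t + 1)):
                raise ValueError(
                    "batch indices must be contiguous integers 1..t with every "
                    f"batch non-empty; found {present.tolist()}"
                )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "groups", groups)
        object.__setattr__(self, "batch_index", batch_index)
        object.__setattr__(self, "gene_ids", gene_ids)

    # -- basic geometry -----------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def t(self) -> int:
        """Number of batches observed so far (0 when empty)."""
        return 0 if self.n_samples == 0 else int(self.batch_index.max())

    def samples_per_group(self) -> tuple[int, int]:
        return int(np.sum(self.groups == 0)), int(np.sum(self.groups == 1))

    def values_by_group(self) -> tuple[np.ndarray, np.ndarray]:
        """Split the matrix into the two group sub-matrices (columns)."""
        return self.values[:, self.groups == 0], self.values[:, self.groups == 1]

    # -- construction helpers ----------------------------------------------

    @classmethod
    def empty(cls, gene_ids: np.ndarray | list[str]) -> "ExpressionBatch":
        gene_ids = np.asarray(gene_ids)
        return cls(
            values=np.empty((len(gene_ids), 0)),
            groups=np.empty(0, dtype=int),
            batch_index=np.empty(0, dtype=int),
            gene_ids=gene_ids,
        )

    def extend(self, new_values: np.ndarray, new_groups: np.ndarray) -> "ExpressionBatch":
        """Append one batch of new sample columns, incrementing the batch index."""
        new_values = np.asarray(new_values, dtype=float)
        new_groups = np.asarray(new_groups, dtype=int)
        if new_values.shape[0] != self.n_genes:
            raise ValueError(
                f"new batch has {new_values.shape[0]} genes, expected {self.n_genes}"
            )
        if new_values.shape[1] == 0:
            raise ValueError("a batch must contain at least one sample")
        nb = np.full(new_values.shape[1], self.t + 1, dtype=int)
        return replace(
            self,
            values=np.hstack([self.values, new_values]),
            groups=np.concatenate([self.groups, new_groups]),
            batch_index=np.concatenate([self.batch_index, nb]),
        )

    def up_to_batch(self, t: int) -> "ExpressionBatch":
        """Restrict to the samples of batches ``1..t`` (``t=0`` gives empty)."""
        keep = self.batch_index <= t
        return replace(
            self,
            values=self.values[:, keep],
            groups=self.groups[keep],
            batch_index=self.batch_index[keep],
        )
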