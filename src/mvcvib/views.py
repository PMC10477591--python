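"""Construction of the second data view: Euclidean distances to training samples.

Each sample's nearest-neighbor information is its vector of Euclidean
distances, computed on relative abundances, to every sample of a fixed
reference set. During model fitting the reference set is always the current
fit's training samples, so a held-out sample's view has training-set
dimension and never sees other held-out samples (no test-set leakage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .io_tables import AbundanceTable

__all__ = ["DistanceView", "MultiViewInput", "pairwise_euclidean", "build_views"]


@dataclass(frozen=True)
class DistanceView:
    """Per-sample vector of distances to reference (training) samples."""

    sample_ids: tuple[str, ...]
    reference_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "reference_ids", tuple(self.reference_ids))
        if values.shape != (len(self.sample_ids), len(self.reference_ids)):
            raise ValueError("distance matrix shape mismatch")
        if np.any(values < 0):
            raise ValueError("distances must be nonnegative")

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=list(self.sample_ids),
                          columns=list(self.reference_ids))
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.17g")


@dataclass(frozen=True)
class MultiViewInput:
    """An ordered collection of per-sample views sharing sample order."""

    views: tuple[np.ndarray, ...]
    view_names: tuple[str, ...]
    labels: np.ndarray | None = None

    def __post_init__(self):
        views = tuple(np.asarray(v, dtype=np.float64) for v in self.views)
        object.__setattr__(self, "views", views)
        object.__setattr__(self, "view_names", tuple(self.view_names))
        if len(views) != len(self.view_names):
            raise ValueError("one name per view required")
        if len(views) < 1:
            raise ValueError("at least one view required")
        n = views[0].shape[0]
        if any(v.shape[0] != n for v in views):
            raise ValueError("all views must have the same sample count")
        if self.labels is not None:
            labels = np.asarray(self.labels, dtype=np.int64)
            object.__setattr__(self, "labels", labels)
            if labels.shape != (n,):
                raise ValueError("labels must parallel samples")

    @property
    def n_samples(self) -> int:
        return self.views[0].shape[0]

    @property
    def n_views(self) -> int:
        return len(self.views)


def pairwise_euclidean(
    query: AbundanceTable,
    reference: AbundanceTable,
    squared: bool = False,
) -> DistanceView:
    """Distances from every query sample to every reference sample.

    entry (q, r) = sqrt( sum_i (a_i - b_i)^2 ) over shared features, where a
    is query row q and b is reference row r. With ``squared=True`` the
    radical is omitted (sum of squared differences).
    """
    if query.feature_ids != reference.feature_ids:
        raise ValueError("query and reference must share an identical feature list")
    d = cdist(query.values, reference.values,
              metric="sqeuclidean" if squared else "euclidean")
    # cdist can return tiny negatives from rounding in sqeuclidean
    return DistanceView(query.sample_ids, reference.sample_ids,
                        np.maximum(d, 0.0))


def build_views(table: AbundanceTable, reference: AbundanceTable, config) -> MultiViewInput:
    """Assemble the model input: abundance view, plus the distance view when
    multi-view mode is enabled. ``config`` is a :class:`~mvcvib.vib_model.ModelConfig`.
    """
    views: list[np.ndarray] = [table.values]
    names = ["abundance"]
    if config.multi_view:
        dv = pairwise_euclidean(table, reference,
                                squared=getattr(config, "squared_distance", False))
        views.append(dv.values)
        names.append("distance")
    return MultiViewInput(tuple(views), tuple(names))
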