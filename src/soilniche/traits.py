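"""Trait space assembled from standardized SEM path coefficients.

Each taxon's nine standardized driver coefficients form a trait vector.
Two summaries follow: ternary soil/vegetation/climate coordinates (the
absolute coefficients of each driver family as a percentage of the
absolute total, so the three axes sum to 100), and Ward hierarchical
clustering into response groups (default 10), with average silhouette
width profiling for the automatic choice of k.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score

from .io import ENV_COLUMNS

__all__ = [
    "DRIVER_FAMILIES",
    "COEFFICIENT_ORDER",
    "ternary_coordinates",
    "ward_cluster",
    "coefficient_matrix",
    "WardResponseGroups",
]

#: Column order of the coefficient matrix (fixed and documented).
COEFFICIENT_ORDER = (
    "MAT",
    "humidity",
    "precipitation",
    "C3_macrothermal",
    "C3_mesothermal",
    "C4_megathermal",
    "OC",
    "conductivity",
    "pH",
)

DRIVER_FAMILIES: dict[str, tuple[str, ...]] = {
    "climate": ("MAT", "humidity", "precipitation"),
    "vegetation": ("C3_macrothermal", "C3_mesothermal", "C4_megathermal"),
    "soil": ("OC", "conductivity", "pH"),
}


def ternary_coordinates(coeffs: pd.DataFrame) -> pd.DataFrame:
    """Soil/vegetation/climate ternary coordinates per taxon.

    Axis value = 100 * sum(|coefficients in family|) / sum(all nine
    |coefficients|); the three axes sum to 100 for any nonzero row.
    """
    missing = [c for c in COEFFICIENT_ORDER if c not in coeffs.columns]
    if missing:
        raise ValueError(f"coefficient matrix missing driver columns: {missing}")
    absval = coeffs[list(COEFFICIENT_ORDER)].abs()
    total = absval.sum(axis=1)
    if (total == 0).any():
        taxon = total.index[total == 0][0]
        raise ValueError(f"all-zero coefficient row for taxon {taxon!r}")
    out = pd.DataFrame(index=coeffs.index)
    for family, cols in DRIVER_FAMILIES.items():
        out[family] = 100.0 * absval[list(cols)].sum(axis=1) / total
    return out[["soil", "vegetation", "climate"]]


class WardResponseGroups(BaseEstimator, ClusterMixin):
    """Ward hierarchical clustering of coefficient rows into response
    groups.

    Parameters
    ----------
    k : int or "auto"
        Number of groups; default 10.  ``"auto"`` scans ``k_range`` and
        keeps the k maximising average silhouette width.
    k_range : tuple
        Inclusive (low, high) scan bounds for auto mode.

    Attributes
    ----------
    labels_ : ndarray of 1-based group labels
    linkage_ : scipy linkage matrix (Euclidean, Ward)
    silhouette_by_k_ : dict of k -> average silhouette width
    k_ : the k actually used
    """

    def __init__(self, k: int | str = 10, k_range: tuple[int, int] = (2, 15)):
        self.k = k
        self.k_range = k_range

    def fit(self, X: pd.DataFrame | np.ndarray, y=None) -> "WardResponseGroups":
        arr = np.asarray(X, dtype=float)
        n = arr.shape[0]
        Z = linkage(arr, method="ward")
        self.linkage_ = Z
        self.silhouette_by_k_ = {}
        if self.k == "auto":
            lo, hi = self.k_range
            for k in range(lo, min(hi, n - 1) + 1):
                labels = fcluster(Z, t=k, criterion="maxclust")
                if len(np.unique(labels)) < 2:
                    continue
                self.silhouette_by_k_[k] = float(silhouette_score(arr, labels))
            if not self.silhouette_by_k_:
                raise ValueError("too few rows for automatic k selection")
            self.k_ = max(self.silhouette_by_k_, key=self.silhouette_by_k_.get)
        else:
            k = int(self.k)
            if k > n:
                raise ValueError(f"k={k} exceeds number of rows {n}")
            self.k_ = k
        self.labels_ = fcluster(Z, t=self.k_, criterion="maxclust")
        return self


def ward_cluster(
    coeffs: pd.DataFrame, k: int | str = 10, k_range: tuple[int, int] = (2, 15)
) -> tuple[pd.Series, np.ndarray, dict[int, float]]:
    """Group labels, Ward linkage matrix and silhouette profile."""
    model = WardResponseGroups(k=k, k_range=k_range).fit(coeffs)
    labels = pd.Series(model.labels_, index=coeffs.index, name="group")
    return labels, model.linkage_, model.silhouette_by_k_


def coefficient_matrix(
    fits: Mapping[str, object],
    driver_order: Sequence[str] = COEFFICIENT_ORDER,
    taxon_node: str = "taxon",
) -> pd.DataFrame:
    """Taxa x 9 matrix of standardized taxon-equation coefficients from a
    collection of fitted SEMs (rows only for successful fits)."""
    rows = {}
    edges_ref: set | None = None
    for taxon, fit in fits.items():
        std = fit.std_coefs_[taxon_node]
        edges = set(std.index)
        if edges_ref is None:
            edges_ref = edges
        elif edges != edges_ref:
            raise ValueError(f"fit for {taxon!r} has inconsistent topology")
        rows[taxon] = [std[d] for d in driver_order]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(driver_order)
    )
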