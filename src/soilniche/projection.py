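"""Projection of taxon relative abundances under changed drivers.

Fitted structural equations predict each taxon's abundance from a future
driver scenario: supplied exogenous drivers are taken as given, while
unsupplied endogenous drivers (e.g. future vegetation or organic carbon)
are propagated through the structural equations in topological order.
Change is then summarised as ln-fold changes (zeros replaced by half the
lowest positive current value over the analysed taxon set), Bray-Curtis
PCoA displacement of each site between the two periods, a trait-table
(gene copy number) functional projection, and inverse-distance gridding
for maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ENV_COLUMNS, AbundanceTable, EnvTable
from .sem import SemCollection, StructuralEquationModel

__all__ = [
    "ScenarioTable",
    "ChangeResult",
    "PCoA",
    "project_future",
    "lnfold_change",
    "bray_curtis",
    "pcoa",
    "displacement",
    "functional_projection",
    "grid_interpolate",
    "community_change",
]


@dataclass
class ScenarioTable:
    """Future driver values per sample; columns absent from ``data`` are
    propagated through the structural equations instead of supplied."""

    data: pd.DataFrame

    @property
    def supplied(self) -> set[str]:
        return set(self.data.columns)

    def validate_against(self, current: EnvTable, exogenous: Sequence[str]) -> None:
        missing_samples = [s for s in current.sample_ids if s not in self.data.index]
        if missing_samples:
            raise ValueError(
                f"scenario missing {len(missing_samples)} samples, e.g. "
                f"{missing_samples[0]!r}"
            )
        missing_cols = [c for c in exogenous if c not in self.data.columns]
        if missing_cols:
            raise ValueError(f"scenario missing exogenous drivers: {missing_cols}")
        if self.data[list(self.supplied)].isna().any().any():
            raise ValueError("supplied scenario columns contain missing values")


def _driver_predictions(
    fit: StructuralEquationModel, scenario: pd.DataFrame
) -> pd.DataFrame:
    """Propagate the structural equations over the driver sub-network in
    topological order, honouring supplied scenario columns."""
    spec = fit.spec_
    values = scenario.copy()
    for child in spec.endogenous:
        if child not in ENV_COLUMNS:
            continue
        if child in values.columns:
            continue
        beta = fit.coefs_[child]
        pred = np.full(len(values), beta["intercept"], dtype=float)
        for parent in spec.parents(child):
            if parent not in values.columns:
                raise ValueError(
                    f"cannot propagate {child!r}: parent {parent!r} unavailable"
                )
            pred = pred + beta[parent] * values[parent].to_numpy(dtype=float)
        values[child] = pred
    return values


def project_future(
    fits: SemCollection | Mapping[str, StructuralEquationModel],
    current: EnvTable,
    scenario: ScenarioTable | pd.DataFrame,
) -> AbundanceTable:
    """Per-taxon predicted abundances under the scenario.

    Negative linear predictions are truncated to zero; the count is
    recorded in ``meta['n_truncated']``.
    """
    if isinstance(fits, SemCollection):
        taxon_node = fits.taxon_node
        fit_map = fits.fits
    else:
        taxon_node = None
        fit_map = dict(fits)
    if not fit_map:
        raise ValueError("no fitted models supplied")
    if isinstance(scenario, pd.DataFrame):
        scenario = ScenarioTable(scenario)
    ref = next(iter(fit_map.values()))
    scenario.validate_against(current, ref.spec_.exogenous)
    frame = scenario.data.loc[current.sample_ids]
    drivers = _driver_predictions(ref, frame)
    rows, n_trunc = {}, 0
    for taxon, fit in fit_map.items():
        pred = fit.predict(drivers, target=taxon_node).to_numpy()
        n_trunc += int((pred < 0).sum())
        rows[taxon] = np.clip(pred, 0.0, None)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=current.sample_ids)
    return AbundanceTable(out, mode="raw", meta={"n_truncated": n_trunc})


def lnfold_change(
    current: AbundanceTable | pd.DataFrame,
    future: AbundanceTable | pd.DataFrame,
    taxa: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """ln(future / current) with the zero-replacement rule: zeros in
    either matrix are replaced by half the lowest positive *current*
    value over the analysed taxon set."""
    cur = current.data if isinstance(current, AbundanceTable) else current
    fut = future.data if isinstance(future, AbundanceTable) else future
    if taxa is not None:
        cur, fut = cur.loc[list(taxa)], fut.loc[list(taxa)]
    if not cur.index.equals(fut.index) or not cur.columns.equals(fut.columns):
        raise ValueError("current and future matrices must share taxa and samples")
    cmat, fmat = cur.to_numpy(dtype=float), fut.to_numpy(dtype=float)
    positive = cmat[cmat > 0]
    if positive.size == 0:
        raise ValueError("zero replacement undefined: no positive current value")
    repl = 0.5 * float(positive.min())
    cmat = np.where(cmat == 0, repl, cmat)
    fmat = np.where(fmat == 0, repl, fmat)
    ln = pd.DataFrame(np.log(fmat / cmat), index=cur.index, columns=cur.columns)
    return ln, repl


def bray_curtis(matrix: AbundanceTable | pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarities between sample columns:
    BC(u, v) = sum|u - v| / sum(u + v)."""
    df = matrix.data if isinstance(matrix, AbundanceTable) else matrix
    X = df.to_numpy(dtype=float).T
    if np.any(X < 0):
        raise ValueError("Bray-Curtis requires nonnegative abundances")
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        empty = df.columns[int(np.where(totals == 0)[0][0])]
        raise ValueError(f"sample {empty!r} has zero total abundance")
    D = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(D, index=df.columns, columns=df.columns)


class PCoA(BaseEstimator, TransformerMixin):
    """Principal coordinate analysis of a dissimilarity matrix.

    Gower double-centering of -D^2/2 followed by eigendecomposition;
    axes are ordered by eigenvalue and axes with negative eigenvalues
    are dropped (their eigenvalues are still reported).
    """

    def __init__(self, n_axes: int | None = None, atol: float = 1e-8):
        self.n_axes = n_axes
        self.atol = atol

    def fit_transform(self, X, y=None) -> np.ndarray:
        D = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(D, D.T, atol=1e-8):
            raise ValueError("dissimilarity matrix must be symmetric")
        n = D.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        G = -0.5 * J @ (D**2) @ J
        G = (G + G.T) / 2
        eigval, eigvec = np.linalg.eigh(G)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        keep = eigval > self.atol
        coords = eigvec[:, keep] * np.sqrt(eigval[keep])
        if self.n_axes is not None:
            coords = coords[:, : self.n_axes]
        self.eigenvalues_ = eigval
        self.negative_eigenvalues_ = eigval[eigval < -self.atol]
        self.coordinates_ = coords
        return coords

    def fit(self, X, y=None) -> "PCoA":
        self.fit_transform(X)
        return self


def pcoa(D: pd.DataFrame | np.ndarray, n_axes: int | None = None):
    """Coordinates (DataFrame when D is labelled) and all eigenvalues."""
    model = PCoA(n_axes=n_axes)
    coords = model.fit_transform(D)
    if isinstance(D, pd.DataFrame):
        coords = pd.DataFrame(
            coords, index=D.index,
            columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
        )
    return coords, model.eigenvalues_


def displacement(
    coords: pd.DataFrame,
    current_ids: Sequence[str],
    future_ids: Sequence[str],
) -> pd.Series:
    """Per-site Euclidean displacement between the (axis1, axis2)
    positions of the current and future period in a stacked ordination."""
    if len(current_ids) != len(future_ids):
        raise ValueError("current and future id lists must pair up")
    for cid, fid in zip(current_ids, future_ids):
        if cid not in coords.index or fid not in coords.index:
            missing = cid if cid not in coords.index else fid
            raise ValueError(f"unmatched site {missing!r} in ordination")
    axes = coords.iloc[:, :2]
    cur = axes.loc[list(current_ids)].to_numpy()
    fut = axes.loc[list(future_ids)].to_numpy()
    d = np.sqrt(((fut - cur) ** 2).sum(axis=1))
    return pd.Series(d, index=list(current_ids), name="displacement")


def functional_projection(
    abundances: AbundanceTable | pd.DataFrame,
    trait_table: pd.DataFrame,
) -> tuple[pd.DataFrame, float]:
    """Community-weighted gene profiles: genes x samples = trait_table^T
    (taxa x genes) @ abundances (taxa x samples), columns renormalised.
    Returns the profile and the fraction of taxa dropped for lack of a
    trait-table match."""
    df = abundances.data if isinstance(abundances, AbundanceTable) else abundances
    shared = [t for t in df.index if t in trait_table.index]
    if not shared:
        raise ValueError("no overlap between abundance taxa and trait table")
    dropped_fraction = 1.0 - len(shared) / len(df.index)
    genes = trait_table.loc[shared].to_numpy(dtype=float).T @ df.loc[shared].to_numpy(dtype=float)
    out = pd.DataFrame(genes, index=trait_table.columns, columns=df.columns)
    totals = out.sum(axis=0)
    if (totals <= 0).any():
        empty = totals.index[totals <= 0][0]
        raise ValueError(f"sample {empty!r} has zero total gene abundance")
    return out / totals, dropped_fraction


def grid_interpolate(
    lon: np.ndarray,
    lat: np.ndarray,
    values: np.ndarray,
    resolution: float = 0.2,
    power: float = 2.0,
    cutoff: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, np.ma.MaskedArray]:
    """Inverse-distance-weighted square grid over the bounding box.

    Default resolution 0.2 degrees; cells farther than ``cutoff``
    degrees from every data point are masked.  Grid nodes coincident
    with a data point take that point's value exactly.
    """
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    values = np.asarray(values, float)
    if lon.size < 3:
        raise ValueError("need at least 3 points to interpolate")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if lon.max() == lon.min() or lat.max() == lat.min():
        raise ValueError("degenerate bounding box")
    gx = np.arange(lon.min(), lon.max() + resolution / 2, resolution)
    gy = np.arange(lat.min(), lat.max() + resolution / 2, resolution)
    GX, GY = np.meshgrid(gx, gy)
    dist = np.sqrt(
        (GX[..., None] - lon[None, None, :]) ** 2
        + (GY[..., None] - lat[None, None, :]) ** 2
    )
    out = np.empty(GX.shape)
    exact = dist < 1e-12
    has_exact = exact.any(axis=-1)
    with np.errstate(divide="ignore"):
        w = 1.0 / dist**power
    w[dist > cutoff] = 0.0
    w[exact] = 0.0  # exact nodes are assigned directly below
    wsum = w.sum(axis=-1)
    masked = (wsum == 0) & ~has_exact
    wsum[wsum == 0] = 1.0
    out = (w * values[None, None, :]).sum(axis=-1) / wsum
    if has_exact.any():
        idx = np.argmax(exact, axis=-1)
        out[has_exact] = values[idx[has_exact]]
    return gx, gy, np.ma.MaskedArray(out, mask=masked)


@dataclass
class ChangeResult:
    current: pd.DataFrame
    future: pd.DataFrame
    lnfold: pd.DataFrame
    zero_replacement: float
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    displacement: pd.Series
    flags: dict = field(default_factory=dict)


def community_change(
    current: AbundanceTable,
    future: AbundanceTable,
    taxa: Sequence[str] | None = None,
) -> ChangeResult:
    """End-to-end change summary: lnfold matrix, stacked-period PCoA on
    Bray-Curtis, and per-site displacement."""
    ln, repl = lnfold_change(current, future, taxa=taxa)
    cur = current.data if taxa is None else current.data.loc[list(taxa)]
    fut = future.data if taxa is None else future.data.loc[list(taxa)]
    cur_ids = [f"{s}|current" for s in cur.columns]
    fut_ids = [f"{s}|future" for s in fut.columns]
    stacked = pd.concat(
        [cur.set_axis(cur_ids, axis=1), fut.set_axis(fut_ids, axis=1)], axis=1
    )
    D = bray_curtis(stacked)
    coords, eigval = pcoa(D)
    disp = displacement(coords, cur_ids, fut_ids)
    disp.index = list(cur.columns)
    return ChangeResult(
        current=cur,
        future=fut,
        lnfold=ln,
        zero_replacement=repl,
        coordinates=coords,
        eigenvalues=eigval,
        displacement=disp,
    )
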