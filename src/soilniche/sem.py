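"""Recursive observed-variable structural equation models (path analysis).

A :class:`SemSpec` declares a causal DAG over observed variables: a set of
freely correlated exogenous drivers and a list of endogenous variables,
each a linear function of its parents plus an independent normal residual.
For such recursive systems with uncorrelated residuals, maximum-likelihood
estimation decouples into equation-wise least squares; goodness of fit is
nevertheless judged the SEM way, through the maximum-likelihood
discrepancy between the sample covariance matrix S and the model-implied
covariance matrix Sigma:

    F_ML = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p,
    chi2 = (n - 1) F_ML,   df = p(p+1)/2 - t,

with CFI against the independence baseline (variances free, covariances
zero), RMSEA = sqrt(max(chi2 - df, 0) / (df (n-1))) and SRMR the root
mean square of correlation-scale covariance residuals (lower triangle
including the diagonal).  Standardized path coefficients are
unstandardized ones rescaled by sd(parent)/sd(child) of the fitted data,
so one parent standard deviation moves the child's prediction by that
many child standard deviations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy import stats
from sklearn.base import BaseEstimator

from .io import ENV_COLUMNS, AbundanceTable, EnvTable

__all__ = [
    "SemSpec",
    "StructuralEquationModel",
    "SemCollection",
    "build_spec",
    "default_spec",
    "fit_sem",
    "predict_conditional",
    "holdout_validate",
    "fit_many",
    "implied_covariance",
    "fit_indices",
]


class SemSpec:
    """Causal DAG over observed variables.

    Parameters
    ----------
    variables : sequence of str
        All declared variable names.
    edges : sequence of (parent, child)
        Directed structural paths with free coefficients.
    exogenous : sequence of str
        Parentless variables with freely estimated covariances.
    sink : str, optional
        A declared terminal node (e.g. the taxon abundance); it must have
        no children.
    """

    def __init__(
        self,
        variables: Sequence[str],
        edges: Sequence[tuple[str, str]],
        exogenous: Sequence[str],
        sink: str | None = None,
    ) -> None:
        self.variables = list(variables)
        self.edges = [(str(p), str(c)) for p, c in edges]
        self.exogenous = list(exogenous)
        self.sink = sink
        declared = set(self.variables)
        for p, c in self.edges:
            if p not in declared or c not in declared:
                raise ValueError(f"edge ({p!r}, {c!r}) references undeclared variable")
        for x in self.exogenous:
            if x not in declared:
                raise ValueError(f"exogenous variable {x!r} undeclared")
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"cyclic spec: {cycle}")
        self._graph = g
        for x in self.exogenous:
            if g.in_degree(x):
                raise ValueError(f"exogenous variable {x!r} has parents")
        self.endogenous = [
            v for v in nx.topological_sort(g) if v not in self.exogenous
        ]
        for v in self.endogenous:
            if g.in_degree(v) == 0:
                raise ValueError(
                    f"variable {v!r} has no parents but is not declared exogenous"
                )
        if sink is not None:
            if sink not in declared:
                raise ValueError(f"sink {sink!r} undeclared")
            if g.out_degree(sink):
                children = list(g.successors(sink))
                raise ValueError(
                    f"sink {sink!r} must be terminal but has children {children}"
                )

    def parents(self, var: str) -> list[str]:
        return sorted(self._graph.predecessors(var))

    @property
    def n_free_params(self) -> int:
        """Free parameters of the covariance structure: one per edge, one
        residual variance per endogenous variable, q(q+1)/2 exogenous
        (co)variances.  Means are saturated and do not enter df."""
        q = len(self.exogenous)
        return len(self.edges) + len(self.endogenous) + q * (q + 1) // 2

    @property
    def df(self) -> int:
        p = len(self.variables)
        return p * (p + 1) // 2 - self.n_free_params

    # -- serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "edges": [list(e) for e in self.edges],
            "exogenous": list(self.exogenous),
            "sink": self.sink,
        }

    @classmethod
    def from_dict(cls, config: Mapping) -> "SemSpec":
        return cls(
            variables=config["variables"],
            edges=[tuple(e) for e in config["edges"]],
            exogenous=config["exogenous"],
            sink=config.get("sink"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SemSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def build_spec(config: Mapping) -> SemSpec:
    """Validated :class:`SemSpec` from a plain mapping (YAML/JSON shape)."""
    return SemSpec.from_dict(config)


def default_spec(taxon: str = "taxon") -> SemSpec:
    """Default climate-vegetation-soil topology.

    Exogenous, freely correlated: MAT, humidity, precipitation, pH,
    conductivity.  Endogenous: each vegetation coverage depends on the
    three climate drivers; organic carbon (OC) depends on conductivity,
    pH, humidity, precipitation and C3 macrothermal coverage; the taxon
    node depends on all nine drivers.
    """
    climate = ["MAT", "humidity", "precipitation"]
    vegetation = ["C3_macrothermal", "C3_mesothermal", "C4_megathermal"]
    edges: list[tuple[str, str]] = []
    for veg in vegetation:
        edges += [(c, veg) for c in climate]
    edges += [
        ("conductivity", "OC"),
        ("pH", "OC"),
        ("humidity", "OC"),
        ("precipitation", "OC"),
        ("C3_macrothermal", "OC"),
    ]
    edges += [(d, taxon) for d in ENV_COLUMNS]
    return SemSpec(
        variables=list(ENV_COLUMNS) + [taxon],
        edges=edges,
        exogenous=["MAT", "humidity", "precipitation", "pH", "conductivity"],
        sink=taxon,
    )


# ---------------------------------------------------------------------------
# implied covariance
# ---------------------------------------------------------------------------

def implied_covariance(
    spec: SemSpec,
    coeffs: Mapping[str, Mapping[str, float]],
    exog_cov: pd.DataFrame | np.ndarray,
    resid_vars: Mapping[str, float],
) -> pd.DataFrame:
    """Model-implied covariance over all spec variables.

    With y = B y + G x + zeta and A = (I - B)^-1:
    Cov(y) = A (G Phi G' + Psi) A', Cov(y, x) = A G Phi.
    Used both by the fitted model and to derive population truths for
    synthetic worlds.
    """
    exog = spec.exogenous
    endo = spec.endogenous
    q, m = len(exog), len(endo)
    if isinstance(exog_cov, pd.DataFrame):
        phi = exog_cov.loc[exog, exog].to_numpy(dtype=float)
    else:
        phi = np.asarray(exog_cov, dtype=float)
    B = np.zeros((m, m))
    G = np.zeros((m, q))
    psi = np.zeros(m)
    e_idx = {v: i for i, v in enumerate(endo)}
    x_idx = {v: i for i, v in enumerate(exog)}
    for child in endo:
        psi[e_idx[child]] = float(resid_vars[child])
        for parent, beta in coeffs[child].items():
            if parent == "intercept":
                continue
            if parent in x_idx:
                G[e_idx[child], x_idx[parent]] = beta
            else:
                B[e_idx[child], e_idx[parent]] = beta
    A = np.linalg.inv(np.eye(m) - B)
    cov_yy = A @ (G @ phi @ G.T + np.diag(psi)) @ A.T
    cov_yx = A @ G @ phi
    order = exog + endo
    sigma = np.zeros((q + m, q + m))
    sigma[:q, :q] = phi
    sigma[q:, :q] = cov_yx
    sigma[:q, q:] = cov_yx.T
    sigma[q:, q:] = cov_yy
    sigma = (sigma + sigma.T) / 2
    return pd.DataFrame(sigma, index=order, columns=order)


def fit_indices(S: np.ndarray, sigma: np.ndarray, n: int, df_model: int, p: int) -> dict:
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    if sign_s <= 0 or sign_m <= 0:
        raise np.linalg.LinAlgError("sample or implied covariance not positive definite")
    f_ml = float(logdet_m - logdet_s + np.trace(S @ np.linalg.inv(sigma)) - p)
    f_ml = max(f_ml, 0.0)
    chi2 = (n - 1) * f_ml
    p_value = float(stats.chi2.sf(chi2, df_model)) if df_model > 0 else 1.0

    # independence baseline: variances free, covariances zero
    diag = np.diag(S)
    f_base = float(np.sum(np.log(diag)) - logdet_s)
    chi2_base = (n - 1) * max(f_base, 0.0)
    df_base = p * (p + 1) // 2 - p
    num = max(chi2 - df_model, 0.0)
    den = max(chi2_base - df_base, chi2 - df_model, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den

    rmsea = np.sqrt(num / (df_model * (n - 1))) if df_model > 0 else 0.0
    sd = np.sqrt(diag)
    resid = (S - sigma) / np.outer(sd, sd)
    tri = np.tril_indices(p)
    srmr = float(np.sqrt(np.mean(resid[tri] ** 2)))
    return {
        "F_ML": f_ml,
        "chi2": float(chi2),
        "df": int(df_model),
        "p": p_value,
        "CFI": float(cfi),
        "RMSEA": float(rmsea),
        "SRMR": srmr,
    }


class StructuralEquationModel(BaseEstimator):
    """Path-analysis estimator for a recursive observed-variable SEM.

    Fits each structural equation by least squares (the ML estimates for
    recursive models with uncorrelated residuals), assembles the implied
    covariance and ML fit indices, and predicts the ``target`` variable
    conditionally from its parents.

    Parameters
    ----------
    spec : SemSpec
        The causal network; defaults to :func:`default_spec` when None.
    target : str, optional
        Variable predicted by :meth:`predict`; defaults to the spec's
        sink or, failing that, the last endogenous variable.

    Attributes
    ----------
    coefs_ : dict of child -> Series (parents + "intercept")
    std_coefs_ : dict of child -> Series of standardized coefficients
    resid_vars_, exog_cov_, implied_cov_, sample_cov_, r2_, fit_indices_
    n_, n_dropped_
    """

    def __init__(self, spec: SemSpec | None = None, target: str | None = None):
        self.spec = spec
        self.target = target

    def _resolve_spec(self) -> SemSpec:
        return self.spec if self.spec is not None else default_spec()

    def fit(self, X: pd.DataFrame, y=None) -> "StructuralEquationModel":
        spec = self._resolve_spec()
        missing = [v for v in spec.variables if v not in X.columns]
        if missing:
            raise ValueError(f"data missing spec variables: {missing}")
        data = X[spec.variables].astype(float)
        n_before = len(data)
        data = data.dropna()
        self.n_dropped_ = n_before - len(data)
        n, p = len(data), len(spec.variables)
        if n <= p:
            raise ValueError(f"need n > {p} complete rows, got {n}")

        arr = data.to_numpy()
        idx = {v: i for i, v in enumerate(spec.variables)}
        sds = arr.std(axis=0, ddof=1)
        if np.any(sds == 0):
            flat = spec.variables[int(np.where(sds == 0)[0][0])]
            raise ValueError(f"zero-variance variable {flat!r}")
        S = np.cov(arr.T, ddof=1)

        coefs: dict[str, pd.Series] = {}
        std_coefs: dict[str, pd.Series] = {}
        resid_vars: dict[str, float] = {}
        r2: dict[str, float] = {}
        for child in spec.endogenous:
            parents = spec.parents(child)
            Xp = np.column_stack([np.ones(n)] + [arr[:, idx[par]] for par in parents])
            yv = arr[:, idx[child]]
            beta, _, rank, _ = np.linalg.lstsq(Xp, yv, rcond=None)
            if rank < Xp.shape[1]:
                raise np.linalg.LinAlgError(f"singular design for equation of {child!r}")
            resid = yv - Xp @ beta
            psi = float(resid @ resid) / (n - 1)
            resid_vars[child] = psi
            coefs[child] = pd.Series(
                dict(zip(parents, beta[1:])) | {"intercept": beta[0]}
            )
            std_coefs[child] = pd.Series(
                {par: beta[k + 1] * sds[idx[par]] / sds[idx[child]]
                 for k, par in enumerate(parents)}
            )
            r2[child] = 1.0 - psi / S[idx[child], idx[child]]

        exog_cov = pd.DataFrame(
            S, index=spec.variables, columns=spec.variables
        ).loc[spec.exogenous, spec.exogenous]
        sigma = implied_covariance(spec, coefs, exog_cov, resid_vars)
        order = spec.exogenous + spec.endogenous
        S_df = pd.DataFrame(S, index=spec.variables, columns=spec.variables).loc[order, order]

        self.spec_ = spec
        self.coefs_ = coefs
        self.std_coefs_ = std_coefs
        self.resid_vars_ = resid_vars
        self.r2_ = r2
        self.exog_cov_ = exog_cov
        self.implied_cov_ = sigma
        self.sample_cov_ = S_df
        self.sds_ = pd.Series(sds, index=spec.variables)
        self.means_ = pd.Series(arr.mean(axis=0), index=spec.variables)
        self.n_ = n
        try:
            self.fit_indices_ = fit_indices(
                S_df.to_numpy(), sigma.to_numpy(), n, spec.df, p
            )
        except np.linalg.LinAlgError:
            # degenerate (e.g. an exactly noise-free equation): coefficients
            # and predictions remain valid, the ML discrepancy does not
            self.fit_indices_ = {
                "F_ML": np.nan, "chi2": np.nan, "df": spec.df, "p": np.nan,
                "CFI": np.nan, "RMSEA": np.nan, "SRMR": np.nan,
                "degenerate": True,
            }
        return self

    # -- prediction ---------------------------------------------------
    def _target_var(self, target: str | None = None) -> str:
        t = target or self.target or self.spec_.sink or self.spec_.endogenous[-1]
        if t not in self.spec_.endogenous:
            raise ValueError(f"target {t!r} is not an endogenous variable")
        return t

    def predict(self, X: pd.DataFrame, target: str | None = None) -> pd.Series:
        """Conditional fitted values for ``target`` from its observed
        parents; the target column itself is never used."""
        t = self._target_var(target)
        beta = self.coefs_[t]
        parents = self.spec_.parents(t)
        missing = [c for c in parents if c not in X.columns]
        if missing:
            raise ValueError(f"new data missing parent columns {missing} of {t!r}")
        pred = np.full(len(X), beta["intercept"], dtype=float)
        for par in parents:
            pred = pred + beta[par] * X[par].to_numpy(dtype=float)
        return pd.Series(pred, index=X.index, name=t)

    def score(self, X: pd.DataFrame, y=None, target: str | None = None) -> float:
        """R-squared of observed vs conditionally predicted target."""
        t = self._target_var(target)
        obs = X[t].to_numpy(dtype=float)
        pred = self.predict(X, target=t).to_numpy()
        sse = float(np.sum((obs - pred) ** 2))
        sst = float(np.sum((obs - obs.mean()) ** 2))
        return 1.0 - sse / sst

    # -- serialisation ------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "spec": self.spec_.to_dict(),
            "n": self.n_,
            "coefs": {k: v.to_dict() for k, v in self.coefs_.items()},
            "std_coefs": {k: v.to_dict() for k, v in self.std_coefs_.items()},
            "resid_vars": self.resid_vars_,
            "r2": self.r2_,
            "fit_indices": self.fit_indices_,
            "exog_cov": self.exog_cov_.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_sem(spec: SemSpec, data: pd.DataFrame) -> StructuralEquationModel:
    return StructuralEquationModel(spec=spec).fit(data)


def predict_conditional(
    fit: StructuralEquationModel, new_data: pd.DataFrame, target: str | None = None
) -> pd.Series:
    return fit.predict(new_data, target=target)


def holdout_validate(
    spec: SemSpec,
    data: pd.DataFrame,
    n_train: int = 1000,
    seed: int = 0,
    target: str | None = None,
) -> dict:
    """Random train/test split, fit on the training rows, conditionally
    predict the target on the held-out rows.  Default split mirrors the
    1,000-sample calibration / 381-sample validation design."""
    n = len(data)
    if n_train >= n:
        raise ValueError(f"n_train={n_train} must be below n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = data.iloc[perm[:n_train]]
    test = data.iloc[perm[n_train:]]
    model = StructuralEquationModel(spec=spec, target=target).fit(train)
    t = model._target_var(target)
    pred = model.predict(test, target=t)
    obs = test[t].to_numpy(dtype=float)
    r = float(np.corrcoef(obs, pred.to_numpy())[0, 1])
    sse = float(np.sum((obs - pred.to_numpy()) ** 2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    return {
        "pearson_r": r,
        "r2": 1.0 - sse / sst,
        "predictions": pred,
        "n_train": n_train,
        "n_test": n - n_train,
        "model": model,
    }


@dataclass
class SemCollection:
    """Per-taxon SEM fits over a shared spec."""

    spec: SemSpec
    fits: dict[str, StructuralEquationModel]
    failures: dict[str, str]
    summary: pd.DataFrame
    taxon_node: str = "taxon"


def fit_many(
    spec: SemSpec,
    taxa_table: AbundanceTable,
    env: EnvTable,
    taxon_node: str = "taxon",
) -> SemCollection:
    """Fit the spec once per taxon row, joining each row (renamed to the
    spec's taxon node) onto the environment table.  Per-taxon failures are
    recorded, never fatal for the batch."""
    shared = [s for s in env.sample_ids if s in taxa_table.data.columns]
    if not shared:
        raise ValueError("no shared samples between abundance and environment tables")
    env_block = env.data.loc[shared]
    fits: dict[str, StructuralEquationModel] = {}
    failures: dict[str, str] = {}
    rows = []
    for taxon in taxa_table.taxon_ids:
        series = taxa_table.data.loc[taxon, shared].astype(float)
        data = env_block.assign(**{taxon_node: series})
        try:
            model = StructuralEquationModel(spec=spec, target=taxon_node).fit(data)
        except (ValueError, np.linalg.LinAlgError) as exc:
            failures[taxon] = str(exc)
            rows.append({"taxon": taxon, "converged": False, "cfi": np.nan,
                         "r2_taxon": np.nan, "chi2": np.nan})
            continue
        fits[taxon] = model
        rows.append({
            "taxon": taxon,
            "converged": True,
            "cfi": model.fit_indices_["CFI"],
            "r2_taxon": model.r2_[taxon_node],
            "chi2": model.fit_indices_["chi2"],
        })
    summary = pd.DataFrame(rows).set_index("taxon")
    return SemCollection(spec=spec, fits=fits, failures=failures,
                         summary=summary, taxon_node=taxon_node)
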