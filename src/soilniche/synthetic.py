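"""Synthetic worlds with the causal, unimodal and phylogenetic structure
the analysis assumes.

Three generators cover the three downstream model families: a linear
structural-equation world (multivariate-normal exogenous drivers pushed
through a recursive DAG), unimodal/monotone HOF gradients, and Brownian
traits evolved on Yule trees.  A multinomial sampler turns relative
abundances into sequencing-like counts so rarefaction and copy-number
correction are exercisable.  Everything is seeded and deterministic.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .hof import hof_curve
from .io import ENV_COLUMNS, AbundanceTable, EnvTable
from .sem import SemSpec, default_spec

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "default_config",
    "generate_dataset",
    "generate_hof_gradient",
    "generate_tree_and_trait",
    "multinomial_counts",
]


@dataclass
class GeneratorConfig:
    """Parameters of the linear SEM world.

    ``structural_coeffs`` maps every endogenous variable (drivers and
    taxon nodes alike) to ``{parent: coefficient, ..., "intercept": a}``;
    ``residual_sds`` gives the independent normal residual sd per
    endogenous variable.  Taxon nodes are the variables not among the
    nine drivers; their columns become the abundance table.
    """

    n_samples: int
    exogenous_means: pd.Series
    exogenous_cov: pd.DataFrame
    structural_coeffs: dict[str, dict[str, float]]
    residual_sds: dict[str, float]
    n_taxa: int = 1
    seed: int = 0
    truncate_abundances: bool = True

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        cov = self.exogenous_cov.to_numpy(dtype=float)
        if not np.allclose(cov, cov.T):
            raise ValueError("exogenous_cov must be symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() <= 0:
            raise ValueError("exogenous_cov must be positive definite")
        for var, sd in self.residual_sds.items():
            if sd < 0:
                raise ValueError(f"negative residual sd for {var!r}")


@dataclass
class SyntheticDataset:
    env: EnvTable
    abundances: AbundanceTable
    true_coeffs: dict[str, dict[str, float]]
    data: pd.DataFrame = field(repr=False, default=None)
    tree: dendropy.Tree | None = None
    true_traits: pd.Series | None = None


def default_config(
    n_samples: int = 1000, n_taxa: int = 1, seed: int = 0
) -> tuple[GeneratorConfig, SemSpec]:
    """Default world matching :func:`soilniche.sem.default_spec`.

    Drivers live on a standardized (transformed) scale with unit
    variances and moderate correlations; taxon coefficients follow the
    magnitudes typical of standardized climate/vegetation/soil paths
    (tenths of a standard deviation), and a large intercept keeps
    abundances far from the truncation boundary.
    """
    exog = ["MAT", "humidity", "precipitation", "pH", "conductivity"]
    corr = np.eye(5)
    pairs = {("MAT", "humidity"): -0.3, ("MAT", "precipitation"): -0.2,
             ("humidity", "precipitation"): 0.5, ("pH", "conductivity"): 0.3}
    for (a, b), r in pairs.items():
        i, j = exog.index(a), exog.index(b)
        corr[i, j] = corr[j, i] = r
    coeffs: dict[str, dict[str, float]] = {
        "C3_macrothermal": {"MAT": -0.3, "humidity": 0.4, "precipitation": 0.5,
                            "intercept": 0.0},
        "C3_mesothermal": {"MAT": -0.2, "humidity": 0.5, "precipitation": 0.3,
                           "intercept": 0.0},
        "C4_megathermal": {"MAT": 0.5, "humidity": -0.3, "precipitation": 0.2,
                           "intercept": 0.0},
        "OC": {"conductivity": -0.25, "pH": -0.2, "humidity": 0.3,
               "precipitation": 0.35, "C3_macrothermal": 0.3, "intercept": 0.0},
    }
    resid = {"C3_macrothermal": 0.7, "C3_mesothermal": 0.7,
             "C4_megathermal": 0.7, "OC": 0.6}
    base_taxon = {"MAT": -0.22, "humidity": -0.46, "precipitation": -0.21,
                  "C3_macrothermal": 0.03, "C3_mesothermal": 0.06,
                  "C4_megathermal": 0.19, "conductivity": -0.08, "pH": -0.03,
                  "OC": -0.12}
    rng = np.random.default_rng(seed)
    taxa = [f"taxon_{k + 1}" for k in range(n_taxa)]
    variables = list(ENV_COLUMNS) + taxa
    edges = [(p, c) for c, cd in coeffs.items() for p in cd if p != "intercept"]
    for k, taxon in enumerate(taxa):
        jitter = rng.normal(0.0, 0.1, size=9) if k else np.zeros(9)
        coeffs[taxon] = {
            d: base_taxon[d] + jitter[i] for i, d in enumerate(base_taxon)
        } | {"intercept": 10.0}
        resid[taxon] = 0.8
        edges += [(d, taxon) for d in ENV_COLUMNS]
    spec = SemSpec(variables=variables, edges=edges, exogenous=exog,
                   sink=taxa[0] if n_taxa == 1 else None)
    config = GeneratorConfig(
        n_samples=n_samples,
        exogenous_means=pd.Series(0.0, index=exog),
        exogenous_cov=pd.DataFrame(corr, index=exog, columns=exog),
        structural_coeffs=coeffs,
        residual_sds=resid,
        n_taxa=n_taxa,
        seed=seed,
    )
    return config, spec


def generate_dataset(config: GeneratorConfig, spec: SemSpec) -> SyntheticDataset:
    """Draw exogenous drivers from the configured multivariate normal and
    evaluate every endogenous variable in topological order as its linear
    combination of parents plus an independent normal residual."""
    exog = spec.exogenous
    if list(config.exogenous_cov.index) != exog:
        config = GeneratorConfig(
            n_samples=config.n_samples,
            exogenous_means=config.exogenous_means.reindex(exog),
            exogenous_cov=config.exogenous_cov.loc[exog, exog],
            structural_coeffs=config.structural_coeffs,
            residual_sds=config.residual_sds,
            n_taxa=config.n_taxa,
            seed=config.seed,
            truncate_abundances=config.truncate_abundances,
        )
    missing = [v for v in spec.endogenous if v not in config.structural_coeffs]
    if missing:
        raise ValueError(f"structural_coeffs missing endogenous variables: {missing}")
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    X = rng.multivariate_normal(
        config.exogenous_means.to_numpy(dtype=float),
        config.exogenous_cov.to_numpy(dtype=float),
        size=n,
        method="cholesky",
    )
    samples = [f"S{i + 1:05d}" for i in range(n)]
    data = pd.DataFrame(X, columns=exog, index=samples)
    for child in spec.endogenous:
        beta = config.structural_coeffs[child]
        extra = [p for p in beta if p != "intercept" and p not in spec.parents(child)]
        if extra:
            raise ValueError(f"coefficients for {child!r} reference non-parents {extra}")
        value = np.full(n, float(beta.get("intercept", 0.0)))
        for parent in spec.parents(child):
            value = value + float(beta.get(parent, 0.0)) * data[parent].to_numpy()
        sd = float(config.residual_sds.get(child, 0.0))
        if sd > 0:
            value = value + rng.normal(0.0, sd, size=n)
        data[child] = value

    taxa = [v for v in spec.endogenous if v not in ENV_COLUMNS]
    abund = data[taxa].T.copy()
    n_trunc = 0
    if config.truncate_abundances:
        n_trunc = int((abund.to_numpy() < 0).sum())
        abund = abund.clip(lower=0.0)
    env_cols = [c for c in ENV_COLUMNS if c in data.columns]
    env_df = data[env_cols].copy()
    for col in ENV_COLUMNS:
        if col not in env_df.columns:
            env_df[col] = 0.0
    env = EnvTable(env_df)
    table = AbundanceTable(abund, mode="raw", meta={"n_truncated": n_trunc})
    return SyntheticDataset(
        env=env,
        abundances=table,
        true_coeffs={k: dict(v) for k, v in config.structural_coeffs.items()},
        data=data,
    )


def generate_hof_gradient(
    model_type: str,
    params: Mapping[str, float],
    n_points: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Evenly spaced gradient on [0, 1] with on-curve abundances plus
    normal noise, truncated at zero."""
    if n_points <= 0:
        raise ValueError("n_points must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    x = np.linspace(0.0, 1.0, n_points)
    y = hof_curve(model_type, params, x)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=n_points)
    return x, np.clip(y, 0.0, None)


def generate_tree_and_trait(
    n_tips: int, brownian_sd: float, seed: int = 0
) -> tuple[dendropy.Tree, pd.Series]:
    """Unit-depth Yule tree with a Brownian trait evolved from root value
    0; per-branch increments are N(0, brownian_sd^2 * branch_length)."""
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    if brownian_sd < 0:
        raise ValueError("brownian_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=random.Random(int(rng.integers(2**31 - 1))),
    )
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1}"
    traits: dict[str, float] = {}
    values: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        parent_value = values.get(id(node.parent_node), 0.0)
        length = node.edge.length or 0.0
        step = (
            rng.normal(0.0, brownian_sd * np.sqrt(length))
            if brownian_sd > 0 and length > 0
            else 0.0
        )
        values[id(node)] = parent_value + step
        if node.is_leaf():
            traits[node.taxon.label] = values[id(node)]
    return tree, pd.Series(traits, name="trait")


def multinomial_counts(
    relabund: AbundanceTable, depth: int, seed: int = 0
) -> AbundanceTable:
    """One multinomial draw of ``depth`` reads per sample column."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    mat = relabund.data.to_numpy(dtype=float)
    colsums = mat.sum(axis=0)
    if np.any(np.abs(colsums - 1.0) > 1e-8):
        j = int(np.argmax(np.abs(colsums - 1.0)))
        raise ValueError(
            f"column {relabund.sample_ids[j]!r} sums to {colsums[j]:.6g}, not 1"
        )
    rng = np.random.default_rng(seed)
    counts = np.column_stack(
        [rng.multinomial(depth, mat[:, j] / colsums[j]) for j in range(mat.shape[1])]
    )
    out = pd.DataFrame(counts, index=relabund.taxon_ids, columns=relabund.sample_ids)
    return AbundanceTable(out, mode="counts", meta=dict(relabund.meta))
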