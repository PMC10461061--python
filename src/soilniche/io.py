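"""Tables, trees and the standard abundance preprocessing steps.

The in-memory containers are thin, validated wrappers around pandas
DataFrames: an :class:`AbundanceTable` (taxa x samples), an
:class:`EnvTable` (samples x nine environmental drivers, optionally with
coordinates) and a :class:`TaxonomyMap` (taxon -> ordered lineage).
Preprocessing mirrors a standard 16S workflow: rarefaction to a common
read depth, 16S gene-copy-number correction with renormalisation to
relative abundances, aggregation of OTU rows to a taxonomic rank, and
log10 variance-stabilising transforms of selected environmental drivers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "EnvTable",
    "TaxonomyMap",
    "ENV_COLUMNS",
    "LOG10_COLUMNS",
    "RANKS",
    "read_abundance",
    "write_abundance",
    "read_env",
    "write_env",
    "read_taxonomy",
    "write_taxonomy",
    "read_tables",
    "write_tables",
    "read_tree",
    "write_tree",
    "rarefy",
    "copy_number_correct",
    "aggregate_rank",
    "transform_env",
]

#: Canonical driver columns: three climate, three vegetation, three soil.
ENV_COLUMNS = (
    "MAT",
    "humidity",
    "precipitation",
    "C3_macrothermal",
    "C3_mesothermal",
    "C4_megathermal",
    "pH",
    "conductivity",
    "OC",
)

#: Drivers whose variances are stabilised by log10 before SEM fitting:
#: conductivity, OC, humidity, precipitation and C3 vegetation coverage
#: (both C3 columns).  pH and the remaining drivers stay untransformed.
LOG10_COLUMNS = (
    "conductivity",
    "OC",
    "humidity",
    "precipitation",
    "C3_macrothermal",
    "C3_mesothermal",
)

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

_MODES = ("counts", "relative", "raw")


def _check_unique(ids: Iterable[str], kind: str) -> None:
    ids = list(ids)
    seen: set = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {kind} id: {x!r}")
        seen.add(x)


@dataclass
class AbundanceTable:
    """Taxa x samples abundance matrix.

    Parameters
    ----------
    data : DataFrame
        Rows are taxa, columns are samples; values nonnegative.
    mode : str
        ``"counts"`` for integer read counts, ``"relative"`` for
        per-sample proportions summing to 1, ``"raw"`` for linear-scale
        synthetic abundances with no sum constraint.
    meta : dict
        Free-form processing log (dropped samples, truncation counts...).
    """

    data: pd.DataFrame
    mode: str = "counts"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        _check_unique(self.data.index, "taxon")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy(dtype=float)
        if np.any(values < 0):
            raise ValueError("abundances must be nonnegative")
        if self.mode == "relative":
            colsums = values.sum(axis=0)
            bad = np.where(np.abs(colsums - 1.0) > 1e-8)[0]
            if bad.size:
                sample = self.data.columns[bad[0]]
                raise ValueError(
                    f"relative-mode column {sample!r} sums to {colsums[bad[0]]:.6g}, not 1"
                )

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def to_relative(self) -> "AbundanceTable":
        """Normalise every sample column to sum to 1."""
        totals = self.data.sum(axis=0)
        if (totals <= 0).any():
            empty = totals.index[totals <= 0][0]
            raise ValueError(f"sample {empty!r} has zero total abundance")
        return AbundanceTable(self.data / totals, mode="relative", meta=dict(self.meta))


@dataclass
class EnvTable:
    """Samples x environmental-driver table with optional lon/lat."""

    data: pd.DataFrame
    transform_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        missing = [c for c in ENV_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing required environment columns: {missing}")
        for col in ENV_COLUMNS:
            if not np.issubdtype(self.data[col].dtype, np.number):
                raise ValueError(f"non-numeric environment column {col!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def drivers(self) -> pd.DataFrame:
        return self.data[list(ENV_COLUMNS)]

    def copy(self) -> "EnvTable":
        return EnvTable(self.data.copy(), dict(self.transform_flags))


@dataclass
class TaxonomyMap:
    """taxon_id -> ordered lineage (kingdom..genus); '' marks unassigned."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "taxon")
        missing = [r for r in RANKS if r not in self.data.columns]
        if missing:
            raise ValueError(f"taxonomy table missing rank columns: {missing}")
        self.data = self.data[list(RANKS)].fillna("").astype(str)

    def lineage(self, taxon: str) -> tuple[str, ...]:
        return tuple(self.data.loc[taxon, list(RANKS)])


# ---------------------------------------------------------------------------
# readers / writers (plain TSV/CSV; trees as newick via dendropy)
# ---------------------------------------------------------------------------

def write_abundance(table: AbundanceTable, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#mode={table.mode}\n")
        table.data.to_csv(fh, sep="\t", index_label="taxon_id")


def read_abundance(path: str | Path, mode: str | None = None) -> AbundanceTable:
    """Read a taxa x samples TSV; mode comes from the ``#mode=`` header
    line unless overridden by the ``mode`` argument."""
    path = Path(path)
    detected = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#mode="):
            detected = first.strip().split("=", 1)[1]
            df = pd.read_csv(fh, sep="\t", index_col=0)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return AbundanceTable(df, mode=mode or detected or "counts")


def write_env(env: EnvTable, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        logged = sorted(k for k, v in env.transform_flags.items() if v == "log10")
        if logged:
            fh.write("#log10=" + ",".join(logged) + "\n")
        env.data.to_csv(fh, index_label="sample_id")


def read_env(path: str | Path) -> EnvTable:
    path = Path(path)
    flags: dict = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#log10="):
            for col in first.strip().split("=", 1)[1].split(","):
                if col:
                    flags[col] = "log10"
            df = pd.read_csv(fh, index_col=0)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return EnvTable(df, flags)


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    tax.data.to_csv(path, sep="\t", index_label="taxon_id")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    df.index = df.index.astype(str)
    df.index.name = None
    return TaxonomyMap(df)


def read_tables(
    abundance_path: str | Path,
    env_path: str | Path,
    taxonomy_path: str | Path | None = None,
    mode: str | None = None,
) -> tuple[AbundanceTable, EnvTable, TaxonomyMap | None]:
    table = read_abundance(abundance_path, mode=mode)
    env = read_env(env_path)
    tax = read_taxonomy(taxonomy_path) if taxonomy_path is not None else None
    return table, env, tax


def write_tables(
    table: AbundanceTable,
    env: EnvTable,
    abundance_path: str | Path,
    env_path: str | Path,
    taxonomy: TaxonomyMap | None = None,
    taxonomy_path: str | Path | None = None,
) -> None:
    write_abundance(table, abundance_path)
    write_env(env, env_path)
    if taxonomy is not None and taxonomy_path is not None:
        write_taxonomy(taxonomy, taxonomy_path)


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def rarefy(counts: AbundanceTable, depth: int = 22_500, seed: int = 0) -> AbundanceTable:
    """Subsample every sample column to exactly ``depth`` reads without
    replacement (multivariate hypergeometric draw).

    Samples whose total is below ``depth`` are dropped; their ids are
    recorded in ``meta['dropped_samples']``.  Default depth is the 22,500
    reads-per-sample standardisation used for the BASE soils.
    """
    if counts.mode != "counts":
        raise ValueError("rarefy requires a counts-mode table")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    mat = counts.data.to_numpy()
    if not np.allclose(mat, np.round(mat)):
        raise ValueError("counts table contains non-integer values")
    mat = mat.astype(np.int64)
    totals = mat.sum(axis=0)
    keep, dropped, cols = [], [], []
    for j, sample in enumerate(counts.sample_ids):
        if totals[j] < depth:
            dropped.append(sample)
            continue
        if totals[j] == depth:
            cols.append(mat[:, j])
        else:
            cols.append(rng.multivariate_hypergeometric(mat[:, j], depth))
        keep.append(sample)
    if not keep:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    out = pd.DataFrame(np.column_stack(cols), index=counts.taxon_ids, columns=keep)
    meta = dict(counts.meta)
    meta["dropped_samples"] = dropped
    meta["rarefaction_depth"] = depth
    return AbundanceTable(out, mode="counts", meta=meta)


def copy_number_correct(
    table: AbundanceTable, copy_numbers: Mapping[str, float] | pd.Series
) -> AbundanceTable:
    """Divide each taxon row by its 16S gene copy number and renormalise
    columns to relative abundances.  Missing taxa default to copy number 1
    (recorded in ``meta``)."""
    cn = pd.Series(copy_numbers, dtype=float)
    if (cn <= 0).any():
        bad = cn.index[cn <= 0][0]
        raise ValueError(f"nonpositive copy number for taxon {bad!r}")
    missing = [t for t in table.taxon_ids if t not in cn.index]
    full = cn.reindex(table.data.index).fillna(1.0)
    corrected = table.data.div(full, axis=0)
    totals = corrected.sum(axis=0)
    if (totals <= 0).any():
        empty = totals.index[totals <= 0][0]
        raise ValueError(f"sample {empty!r} has zero total after correction")
    meta = dict(table.meta)
    meta["copy_number_defaulted"] = missing
    return AbundanceTable(corrected / totals, mode="relative", meta=meta)


def aggregate_rank(
    table: AbundanceTable, taxonomy: TaxonomyMap, rank: str
) -> AbundanceTable:
    """Sum rows sharing the same lineage prefix up to ``rank``.

    Rows unassigned at ``rank`` are pooled under ``Unclassified_<parent>``
    where parent is the deepest assigned name above the rank.
    """
    if rank not in RANKS[1:]:
        raise ValueError(f"rank must be one of {RANKS[1:]}, got {rank!r}")
    depth = RANKS.index(rank)
    labels = []
    for taxon in table.taxon_ids:
        if taxon not in taxonomy.data.index:
            raise ValueError(f"taxon {taxon!r} missing from taxonomy map")
        lineage = taxonomy.lineage(taxon)
        name = lineage[depth]
        if name:
            labels.append(";".join(lineage[: depth + 1]))
        else:
            parents = [x for x in lineage[:depth] if x]
            parent = parents[-1] if parents else "Root"
            labels.append(f"Unclassified_{parent}")
    grouped = table.data.groupby(pd.Index(labels, name="taxon_id"), sort=True).sum()
    return AbundanceTable(grouped, mode=table.mode, meta=dict(table.meta))


def transform_env(env: EnvTable) -> EnvTable:
    """log10-transform conductivity, OC, humidity, precipitation and the
    two C3 vegetation-coverage columns; refuse to transform twice and
    refuse nonpositive values (no silent pseudo-offsets)."""
    already = [c for c in LOG10_COLUMNS if env.transform_flags.get(c) == "log10"]
    if already:
        raise ValueError(f"columns already log10-transformed: {already}")
    out = env.data.copy()
    flags = dict(env.transform_flags)
    for col in LOG10_COLUMNS:
        values = out[col].to_numpy(dtype=float)
        if np.any(values <= 0):
            sample = out.index[np.where(values <= 0)[0][0]]
            raise ValueError(
                f"nonpositive value in column {col!r} at sample {sample!r}; "
                "supply a pseudo-offset explicitly before transforming"
            )
        out[col] = np.log10(values)
        flags[col] = "log10"
    return EnvTable(out, flags)
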