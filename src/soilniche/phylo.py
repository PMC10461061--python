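"""Global and local phylogenetic signal of trait indicators.

Abouheif's proximity is purely topological: the proximity of two tips is
the product, over the internal nodes on the path between them, of one
over the number of direct descendants of each node.  The global
statistic (Abouheif's Cmean) is Moran's I computed with that proximity,

    C = (n / S0) * sum_{i != j} a_ij z_i z_j / sum_i z_i^2,

with z the centred trait and S0 = sum_{i != j} a_ij, tested one-sided
("greater", trait conservation) by tip permutation.  Local indicators of
phylogenetic association (LIPA) are per-tip local Moran's I values on
the row-normalised proximity matrix, with per-tip permutation p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .io import AbundanceTable

__all__ = [
    "SignalResult",
    "abouheif_proximity",
    "cmean_test",
    "local_moran",
    "filter_taxa_for_signal",
]


@dataclass
class SignalResult:
    cmean: float
    p_value: float
    n_perm: int
    n_tips: int


def abouheif_proximity(tree: dendropy.Tree) -> pd.DataFrame:
    """Topology-only Abouheif proximity matrix (zero diagonal)."""
    leaves = list(tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip labels")
    if len(labels) < 3:
        raise ValueError("need at least 3 tips")
    n_children = {
        id(node): len(node.child_nodes())
        for node in tree.preorder_node_iter()
        if not node.is_leaf()
    }
    # ancestor chains, tip -> [(node id, depth rank), ...] root last
    chains: list[list[int]] = []
    for leaf in leaves:
        chain = []
        node = leaf.parent_node
        while node is not None:
            chain.append(id(node))
            node = node.parent_node
        chains.append(chain)
    n = len(leaves)
    A = np.zeros((n, n))
    chain_sets = [set(c) for c in chains]
    for i in range(n):
        for j in range(i + 1, n):
            # MRCA = first common node walking up from tip i
            common = chain_sets[i] & chain_sets[j]
            mrca = next(nid for nid in chains[i] if nid in common)
            path = (
                chains[i][: chains[i].index(mrca)]
                + chains[j][: chains[j].index(mrca)]
                + [mrca]
            )
            prox = 1.0
            for nid in path:
                prox /= n_children[nid]
            A[i, j] = A[j, i] = prox
    return pd.DataFrame(A, index=labels, columns=labels)


def _align(trait: pd.Series, A: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if set(trait.index) != set(A.index):
        raise ValueError("trait tips do not match proximity matrix tips")
    z = trait.loc[A.index].to_numpy(dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("trait contains non-finite values")
    if np.var(z) == 0:
        raise ValueError("zero-variance trait")
    return z - z.mean(), A.to_numpy(dtype=float)


def _moran(Z: np.ndarray, A: np.ndarray, scale: float) -> np.ndarray:
    # rows of Z are (permuted) centred traits; returns one statistic per row
    quad = np.einsum("pi,ij,pj->p", Z, A, Z)
    return scale * quad / np.einsum("pi,pi->p", Z, Z)


def cmean_test(
    trait: pd.Series,
    A: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> SignalResult:
    """Abouheif's Cmean with a one-sided (greater) permutation test,
    p = (hits + 1) / (n_perm + 1)."""
    z, mat = _align(trait, A)
    n = z.size
    s0 = mat.sum()
    scale = n / s0
    obs = float(_moran(z[None, :], mat, scale)[0])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(z) for _ in range(n_perm)])
    null = _moran(perms, mat, scale)
    p = (int((null >= obs).sum()) + 1) / (n_perm + 1)
    return SignalResult(cmean=obs, p_value=p, n_perm=n_perm, n_tips=n)


def local_moran(
    trait: pd.Series,
    A: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-tip local Moran's I (LIPA) on the row-normalised proximity.

    I_i = z_i * sum_j W_ij z_j / (sum_k z_k^2 / n).  The permutation
    test holds tip i's value fixed and permutes the remaining values to
    build the null lag; p-values are two-sided on |I|.  The mean of the
    local values equals the global Moran statistic under row-normalised
    weights.  Benjamini-Hochberg correction is available but off by
    default (per-tip p < alpha is the reporting rule).
    """
    z, mat = _align(trait, A)
    n = z.size
    rowsums = mat.sum(axis=1)
    if np.any(rowsums == 0):
        raise ValueError("proximity matrix has an isolated tip (zero row sum)")
    W = mat / rowsums[:, None]
    m2 = float(z @ z) / n
    lag = W @ z
    I_obs = z * lag / m2

    rng = np.random.default_rng(seed)
    null_I = np.empty((n_perm, n))
    for r in range(n_perm):
        zp = rng.permutation(z)
        null_I[r] = z * (W @ zp) / m2
    p = (np.sum(np.abs(null_I) >= np.abs(I_obs)[None, :], axis=0) + 1) / (n_perm + 1)
    if bh_correct:
        order = np.argsort(p)
        ranked = p[order] * n / (np.arange(n) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        p_adj = np.empty(n)
        p_adj[order] = np.clip(adj, 0, 1)
    else:
        p_adj = p
    return pd.DataFrame(
        {
            "trait": trait.loc[A.index].to_numpy(dtype=float),
            "I": I_obs,
            "p": p_adj,
            "significant": p_adj < alpha,
        },
        index=A.index,
    )


def filter_taxa_for_signal(
    table: AbundanceTable, min_samples: int = 200
) -> pd.Series:
    """Taxa present (> 0) in strictly more than ``min_samples`` samples;
    returns the per-taxon occupancy of the retained set."""
    occupancy = (table.data > 0).sum(axis=1)
    return occupancy[occupancy > min_samples]
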