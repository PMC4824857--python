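"""Cross-dataset comparison of quantitative proteomes.

Rescaling to parts-per-million of total protein molecules, pairwise Spearman
rank correlation on shared proteins, average-linkage hierarchical clustering
of the datasets with Newick export, and the M-versus-A transform for paired
abundance comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

__all__ = ["CorrelationMatrix", "cpc_to_ppm", "correlation_matrix",
           "cluster_datasets", "ma_transform", "TOTAL_MOLECULES_PER_CELL"]

#: assumed total protein molecules in one yeast cell for ppm rescaling
TOTAL_MOLECULES_PER_CELL = 6.0e7


@dataclass
class CorrelationMatrix:
    dataset_ids: list
    rho: pd.DataFrame        # symmetric Spearman matrix, diagonal 1
    overlap: pd.DataFrame    # per-pair shared-protein counts

    def __post_init__(self) -> None:
        r = self.rho.to_numpy()
        if not np.allclose(np.diag(r), 1.0, equal_nan=True):
            raise ValueError("diagonal must be 1")


def cpc_to_ppm(cpc, total_molecules: float = TOTAL_MOLECULES_PER_CELL):
    """Rescale copies-per-cell to parts-per-million of total protein molecules."""
    if total_molecules <= 0:
        raise ValueError("total molecule count must be > 0")
    arr = np.asarray(cpc, dtype=float)
    if np.nanmin(arr) < 0 if arr.size else False:
        raise ValueError("cpc must be >= 0")
    out = arr / total_molecules * 1.0e6
    return float(out) if np.isscalar(cpc) else out


def correlation_matrix(
    tables: dict[str, pd.Series],
    min_overlap: int = 50,
) -> CorrelationMatrix:
    """Pairwise Spearman correlations between abundance datasets.

    ``tables`` maps dataset id -> Series of abundances indexed by protein id.
    Correlations use pairwise-complete, strictly positive abundances on the
    log scale (rank-based, so any monotone rescaling of a dataset is
    irrelevant); pairs sharing fewer than ``min_overlap`` proteins are left
    as NaN rather than fabricated.
    """
    if len(tables) < 2:
        raise ValueError("need at least two datasets")
    ids = sorted(tables)
    n = len(ids)
    rho = np.eye(n)
    overlap = np.zeros((n, n), dtype=int)
    clean = {}
    for k, s in tables.items():
        s = pd.Series(s).astype(float)
        s = s[s > 0]
        s = s[~s.index.duplicated()]
        clean[k] = s
        overlap[ids.index(k), ids.index(k)] = len(s)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = clean[ids[i]].align(clean[ids[j]], join="inner")
            overlap[i, j] = overlap[j, i] = len(a)
            if len(a) < min_overlap:
                rho[i, j] = rho[j, i] = np.nan
                continue
            r = spearmanr(np.log10(a), np.log10(b)).statistic
            rho[i, j] = rho[j, i] = r
    return CorrelationMatrix(
        dataset_ids=ids,
        rho=pd.DataFrame(rho, index=ids, columns=ids),
        overlap=pd.DataFrame(overlap, index=ids, columns=ids),
    )


def _to_newick(node, labels, parent_height: float) -> str:
    height = node.dist / 2.0  # UPGMA-style: node height is half the merge distance
    length = parent_height - height
    if node.is_leaf():
        return f"{labels[node.id]}:{length:.6g}"
    left = _to_newick(node.left, labels, height)
    right = _to_newick(node.right, labels, height)
    return f"({left},{right}):{length:.6g}"


def cluster_datasets(matrix: CorrelationMatrix, method: str = "average") -> str:
    """Agglomerative clustering of datasets on distance 1 - rho; Newick output.

    The input matrix must be complete (no NaN off-diagonal entries); missing
    pairs should be re-computed with a lower ``min_overlap`` or dropped before
    clustering.
    """
    r = matrix.rho.to_numpy()
    if np.isnan(r).any():
        raise ValueError(
            "correlation matrix has missing pairs; drop those datasets or "
            "recompute with a lower min_overlap before clustering"
        )
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    tree = hierarchy.to_tree(z)
    root_height = tree.dist / 2.0
    left = _to_newick(tree.left, matrix.dataset_ids, root_height)
    right = _to_newick(tree.right, matrix.dataset_ids, root_height)
    return f"({left},{right});"


def ma_transform(x, y) -> pd.DataFrame:
    """M (log2 ratio) and A (mean log2 abundance) for paired positive values.

    Non-positive or missing pairs are excluded; the count of exclusions is in
    ``.attrs['n_excluded']``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    m = np.log2(x[ok] / y[ok])
    a = (np.log2(x[ok]) + np.log2(y[ok])) / 2.0
    out = pd.DataFrame({"M": m, "A": a})
    out.attrs["n_excluded"] = int((~ok).sum())
    return out
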