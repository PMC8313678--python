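"""Hypergeometric over-representation analysis and hierarchical clustering.

ORA asks whether a differential hit list overlaps a predefined protein set
more than chance, given a finite universe: with N universe proteins, K of
them in the set and n hits, the upper-tail probability of observing k or
more overlaps is P(X >= k) for X ~ Hypergeometric(N, K, n). q-values come
from Benjamini-Hochberg across all tested sets. The clustering view
z-scores each row, computes pairwise Euclidean distances and merges
agglomeratively (average linkage by default), returning leaf orders and
merge trees for heatmap rendering.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .differential import bh_adjust
from .genesets import GeneSet, read_gmt, write_gmt  # noqa: F401  (re-exported)


def ora_hypergeometric(
    hits: set[str], universe: set[str], sets: Sequence[GeneSet]
) -> tuple[pd.DataFrame, list[str]]:
    """Upper-tail hypergeometric ORA with BH correction.

    Sets are intersected with the universe before testing; sets with empty
    intersection are skipped and reported in the second return value.
    Results are sorted by p (ties by name). Raises when hits are not a
    subset of the universe, listing the offenders.
    """
    offenders = sorted(hits - universe)
    if offenders:
        raise ValueError(f"hits outside the universe: {offenders[:10]}")
    N, n = len(universe), len(hits)
    rows, skipped = [], []
    for s in sets:
        members = s.members & universe
        K = len(members)
        if K == 0:
            skipped.append(s.name)
            continue
        k = len(members & hits)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_name": s.name, "N": N, "K": K, "n": n, "k": k, "p": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["set_name", "N", "K", "n", "k", "p"])
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
    return df, skipped


def membership_edges(sets: Sequence[GeneSet], proteins: set[str]) -> pd.DataFrame:
    """Set-protein membership edge list (for external network tools)."""
    rows = [
        {"set_name": s.name, "accession": a}
        for s in sets
        for a in sorted(s.members & proteins)
    ]
    return pd.DataFrame(rows, columns=["set_name", "accession"])


# ---------------------------------------------------------------------------
# hierarchical clustering for the heatmap view
# ---------------------------------------------------------------------------

@dataclass
class ClusterLayout:
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray

    def cut_columns(self, k: int) -> dict[str, int]:
        """Column labels -> cluster id when the column tree is cut into k."""
        labels = hierarchy.fcluster(self.col_linkage, k, criterion="maxclust")
        # fcluster labels follow the original (pre-ordered) column sequence
        original = self._original_cols
        return dict(zip(original, (int(x) for x in labels)))

    def to_dict(self) -> dict:
        return {
            "row_order": self.row_order,
            "col_order": self.col_order,
            "row_merges": self.row_linkage.tolist(),
            "col_merges": self.col_linkage.tolist(),
        }


def zscore_rows(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Row-wise z-scores; zero-variance rows map to all-zero rows."""
    mu = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=ddof)
    z = matrix.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0)
    return z.fillna(0.0)


def cluster_rows_cols(
    matrix: pd.DataFrame, normalize_rows: bool = True, method: str = "average"
) -> ClusterLayout:
    """Agglomerative clustering of rows and columns on Euclidean distances,
    optionally after row z-scoring. Merge heights are non-decreasing for
    the supported linkages (average/complete/single)."""
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    if not np.isfinite(matrix.to_numpy()).all():
        raise ValueError("matrix contains non-finite values")
    data = zscore_rows(matrix) if normalize_rows else matrix
    X = data.to_numpy(dtype=float)
    row_Z = hierarchy.linkage(pdist(X), method=method)
    col_Z = hierarchy.linkage(pdist(X.T), method=method)
    row_order = [matrix.index[i] for i in hierarchy.leaves_list(row_Z)]
    col_order = [matrix.columns[i] for i in hierarchy.leaves_list(col_Z)]
    layout = ClusterLayout(
        row_order=list(row_order), col_order=list(col_order), row_linkage=row_Z, col_linkage=col_Z
    )
    layout._original_cols = list(matrix.columns)
    layout._original_rows = list(matrix.index)
    return layout


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = walk(node.left), walk(node.right)
        dl = node.dist - (0 if node.left.is_leaf() else node.left.dist)
        dr = node.dist - (0 if node.right.is_leaf() else node.right.dist)
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return walk(tree) + ";"
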