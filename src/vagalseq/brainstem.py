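"""Brainstem innervation profiling of vagal central projections.

For each tracing pathway (organ), the fluorescence of labelled vagal fibres
is measured per (bregma level, NTS subnucleus) cell.  Background-subtracted
fluorescence FI times subnucleus area A, normalised by the pathway's total
fluorescence TF = sum(FI x A), gives the percentage innervation PI, which
sums to 100 over the pathway's grid.  Pathway pairs are compared by the sum
of squared PI differences, and the resulting variance matrix is summarised
as an average-linkage (UPGMA) tree.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

__all__ = [
    "percentage_innervation",
    "pi_matrix",
    "correlation_variance",
    "variance_matrix",
    "linkage_tree",
]


def percentage_innervation(table: pd.DataFrame, pathway: str) -> pd.Series:
    """PI profile of one pathway over its (bregma, subnucleus) grid.

    ``table`` columns: pathway, bregma, subnucleus, mean_fluorescence,
    background_fluorescence, area.  FI = mean - background, clamped at 0;
    TF = sum(FI x A); PI = FI x A / TF x 100.  The profile sums to 100.
    """
    sub = table.loc[table["pathway"] == pathway]
    if len(sub) == 0:
        raise ValueError(f"pathway {pathway!r} absent from table")
    if (sub["area"] <= 0).any():
        raise ValueError("areas must be positive")
    fi = (sub["mean_fluorescence"] - sub["background_fluorescence"]).clip(lower=0)
    weighted = fi * sub["area"]
    tf = weighted.sum()
    if tf <= 0:
        raise ValueError(f"pathway {pathway!r} has zero total fluorescence")
    pi = weighted / tf * 100.0
    pi.index = pd.MultiIndex.from_frame(sub[["bregma", "subnucleus"]])
    return pi


def pi_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """PI profiles of all pathways on the union grid; missing cells are 0.

    Rows are pathways, columns (bregma, subnucleus) cells; a cell absent
    from a pathway's measurements is treated as carrying no signal.
    """
    profiles = {
        p: percentage_innervation(table, p) for p in table["pathway"].unique()
    }
    return pd.DataFrame(profiles).T.fillna(0.0)


def correlation_variance(profile1: pd.Series, profile2: pd.Series) -> float:
    """Sum of squared PI differences between two pathway profiles.

    Profiles must cover the same (bregma, subnucleus) grid; use
    :func:`pi_matrix` to put pathways on the union grid first.
    """
    if not profile1.index.equals(profile2.index):
        if set(profile1.index) != set(profile2.index):
            raise ValueError("profiles are on different grids")
        profile2 = profile2.reindex(profile1.index)
    return float(((profile1 - profile2) ** 2).sum())


def variance_matrix(pi: pd.DataFrame) -> pd.DataFrame:
    """Pairwise correlation-variance matrix over pathways (zero diagonal)."""
    paths = pi.index
    mat = pd.DataFrame(0.0, index=paths, columns=paths)
    for i, a in enumerate(paths):
        for b in paths[i + 1:]:
            v = correlation_variance(pi.loc[a], pi.loc[b])
            mat.loc[a, b] = mat.loc[b, a] = v
    return mat


def linkage_tree(variance: pd.DataFrame, method: str = "average") -> str:
    """Agglomerative linkage tree over the variance matrix, as newick.

    Average linkage (UPGMA) by default; leaf names are the pathway labels
    and branch lengths are in linkage height units.
    """
    m = variance.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1] or not np.allclose(m, m.T):
        raise ValueError("variance matrix must be square and symmetric")
    z = linkage(squareform(m, checks=False), method=method)
    tree = TreeNode.from_linkage_matrix(z, list(variance.index))
    return str(tree).strip()
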