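"""Projection-barcode (UPB) classification and barcode statistics.

Cells are represented as a pandas DataFrame with one row per cell.  Barcode
expression for organ ``X`` lives in column ``upb_X`` (processed, log-scale
expression); marker genes in ``gene_<name>``; plus ``cell_id``, ``cluster``,
``emb_x``/``emb_y``, ``n_genes`` and ``mito_fraction``.

A cell is UPB-positive for an organ when its barcode expression is strictly
above the detection threshold (default 0.8).  Single-positive cells are
organ-specific; the two sphincter classes are the dual combinations
stomach+oesophagus (oesophageal sphincter) and stomach+duodenum (pyloric
sphincter); other dual combinations stay generic duals; three or more
positives are "multi" and are excluded from organ-specific statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

UPB_THRESHOLD = 0.8
UPB_PREFIX = "upb_"
GENE_PREFIX = "gene_"

DAMAGE_MARKERS = ("Sprr1a", "Ecel1")

__all__ = [
    "ProjectionLabel",
    "qc_filter",
    "flag_damaged",
    "classify_upb",
    "classify_upb_table",
    "organ_correlation_matrix",
    "cluster_upb_percentage",
    "fold_enrichment",
    "upb_columns",
]


@dataclass(frozen=True)
class ProjectionLabel:
    """Projection assignment of one cell.

    category is one of ``single``, ``sphincter_oesophageal``,
    ``sphincter_pyloric``, ``dual``, ``multi``, ``unlabelled``;
    organs holds the UPB-positive organ set.
    """

    category: str
    organs: frozenset[str]

    def __post_init__(self) -> None:
        n = len(self.organs)
        expected = {
            "unlabelled": n == 0,
            "single": n == 1,
            "dual": n == 2,
            "sphincter_oesophageal": n == 2,
            "sphincter_pyloric": n == 2,
            "multi": n >= 3,
        }
        if not expected.get(self.category, False):
            raise ValueError(f"category {self.category!r} inconsistent with {n} organs")


_LABEL_COLS = ("upb_category", "upb_organs")


def upb_columns(cells: pd.DataFrame) -> list[str]:
    return [
        c for c in cells.columns
        if c.startswith(UPB_PREFIX) and c not in _LABEL_COLS
    ]


def qc_filter(
    cells: pd.DataFrame,
    min_genes: int = 500,
    max_genes: int = 8000,
    max_mito: float = 0.10,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Quality-control filter on gene counts and mitochondrial fraction.

    Retains cells with ``min_genes < n_genes < max_genes`` and
    ``mito_fraction < max_mito`` (all strict).  Returns the retained table
    and per-rule removal counts (a cell failing several rules is counted
    under each).
    """
    if len(cells) == 0:
        raise ValueError("empty cell table")
    if min_genes <= 0 or max_genes <= 0 or max_mito <= 0:
        raise ValueError("thresholds must be positive")
    if min_genes >= max_genes:
        raise ValueError("min_genes must be below max_genes")
    low = cells["n_genes"] <= min_genes
    high = cells["n_genes"] >= max_genes
    mito = cells["mito_fraction"] >= max_mito
    keep = ~(low | high | mito)
    removed = {
        "low_genes": int(low.sum()),
        "high_genes": int(high.sum()),
        "high_mito": int(mito.sum()),
    }
    return cells.loc[keep].copy(), removed


def flag_damaged(
    cells: pd.DataFrame,
    markers: tuple[str, ...] = DAMAGE_MARKERS,
    factor: float = 5.0,
) -> pd.Series:
    """Flag clusters of damaged sensory neurons by injury-marker expression.

    A cluster is flagged when its mean expression of the damage markers
    (e.g. Sprr1a, Ecel1) exceeds ``factor`` times the grand mean across all
    cells.  Returns a boolean Series indexed by cluster label; flagged
    clusters are meant to be dropped from downstream analysis.
    """
    if not markers:
        raise ValueError("marker list is empty")
    cols = [GENE_PREFIX + m for m in markers]
    for c in cols:
        if c not in cells.columns:
            raise KeyError(f"marker column {c!r} absent from table")
    score = cells[cols].mean(axis=1)
    grand = score.mean()
    by_cluster = score.groupby(cells["cluster"]).mean()
    return by_cluster > factor * grand


def classify_upb(upb_expr: dict[str, float], threshold: float = UPB_THRESHOLD) -> ProjectionLabel:
    """Classify one cell from its organ -> barcode-expression map.

    Organs with expression strictly above ``threshold`` form the positive
    set; exact ties fall below.  Total function: any input yields a label.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    positive = frozenset(o for o, v in upb_expr.items() if v > threshold)
    n = len(positive)
    if n == 0:
        return ProjectionLabel("unlabelled", positive)
    if n == 1:
        return ProjectionLabel("single", positive)
    if n == 2:
        if positive == frozenset({"stomach", "oesophagus"}):
            return ProjectionLabel("sphincter_oesophageal", positive)
        if positive == frozenset({"stomach", "duodenum"}):
            return ProjectionLabel("sphincter_pyloric", positive)
        return ProjectionLabel("dual", positive)
    return ProjectionLabel("multi", positive)


def classify_upb_table(cells: pd.DataFrame, threshold: float = UPB_THRESHOLD) -> pd.DataFrame:
    """Classify every cell; adds ``upb_category`` and ``upb_organs`` columns.

    ``upb_organs`` is a '+'-joined sorted organ list (empty string when
    unlabelled), convenient for delimited-text round trips.
    """
    cols = upb_columns(cells)
    organs = [c[len(UPB_PREFIX):] for c in cols]
    out = cells.copy()
    cats, orgstrs = [], []
    values = cells[cols].to_numpy()
    for row in values:
        label = classify_upb(dict(zip(organs, row)), threshold)
        cats.append(label.category)
        orgstrs.append("+".join(sorted(label.organs)))
    out["upb_category"] = cats
    out["upb_organs"] = orgstrs
    return out


def _single_mask(cells: pd.DataFrame) -> pd.Series:
    return cells["upb_category"] == "single"


def _dual_mask(cells: pd.DataFrame) -> pd.Series:
    return cells["upb_category"].isin(["dual", "sphincter_oesophageal", "sphincter_pyloric"])


def organ_correlation_matrix(cells: pd.DataFrame) -> pd.DataFrame:
    """Organ-pair correlation from single- and dual-barcode counts.

    Off-diagonal (i, j) = N_dual(i, j) / sqrt(N_single(i) * N_single(j));
    diagonal 1.  Organs with zero single-labelled cells yield NaN entries
    (missing, not zero).  Requires ``classify_upb_table`` output.
    """
    organs = [c[len(UPB_PREFIX):] for c in upb_columns(cells)]
    n_single = {o: 0 for o in organs}
    for orgs in cells.loc[_single_mask(cells), "upb_organs"]:
        n_single[orgs] += 1
    n_dual: dict[frozenset, int] = {}
    for orgs in cells.loc[_dual_mask(cells), "upb_organs"]:
        key = frozenset(orgs.split("+"))
        n_dual[key] = n_dual.get(key, 0) + 1
    mat = pd.DataFrame(np.eye(len(organs)), index=organs, columns=organs)
    for i, a in enumerate(organs):
        for b in organs[i + 1:]:
            denom = n_single[a] * n_single[b]
            if denom == 0:
                val = np.nan
            else:
                val = n_dual.get(frozenset({a, b}), 0) / np.sqrt(denom)
            mat.loc[a, b] = mat.loc[b, a] = val
    return mat


def cluster_upb_percentage(cells: pd.DataFrame, organ: str, cluster: str) -> float:
    """Fraction of all organ-specific (single-UPB) cells found in a cluster.

    P_organ-cluster = (UPB_organ+ cells in cluster) / (all UPB_organ+ cells);
    sums to 1 over clusters for every organ with labelled cells.
    """
    labelled = cells.loc[_single_mask(cells) & (cells["upb_organs"] == organ)]
    if len(labelled) == 0:
        raise ValueError(f"no single-labelled cells for organ {organ!r}")
    return float((labelled["cluster"] == cluster).mean())


def fold_enrichment(
    cells: pd.DataFrame,
    gene: str,
    cluster: str,
    expr_threshold: float = 0.0,
) -> float:
    """Within-cluster enrichment of gene-positive cells over the overall rate.

    (fraction gene+ in cluster) / (fraction gene+ over all cells), with
    positivity defined as expression strictly above ``expr_threshold``.
    """
    col = GENE_PREFIX + gene
    if col not in cells.columns:
        raise KeyError(f"gene {gene!r} absent from table")
    positive = cells[col] > expr_threshold
    overall = positive.mean()
    if overall == 0:
        raise ValueError(f"gene {gene!r} has zero overall positive fraction")
    in_cluster = cells["cluster"] == cluster
    if not in_cluster.any():
        raise ValueError(f"cluster {cluster!r} absent from table")
    return float(positive[in_cluster].mean() / overall)
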