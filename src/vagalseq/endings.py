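"""Anatomical ending quantification and the exhaustive ending-type search.

Each vagal afferent ending type has an innervation intensity per stomach
region (area covered per total sample area for mucosal endings and
intramuscular arrays; terminal count per total area for IGLEs).  The
anatomical fold change AF(type, region) normalises the regional intensity
by the whole-stomach intensity of the same type.  The barcode-derived fold
change SF(type, region) is the ratio of summed regional dual-barcode
percentages to summed stomach single-barcode percentages over the clusters
assigned to the type.  Free clusters are assigned ending types by
exhaustively enumerating all type combinations (4^k for k free clusters)
and picking the assignment minimising the total squared SF-AF discrepancy
over the 4 types x 4 regions grid.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .organs import ENDING_TYPES, STOMACH_REGIONS

__all__ = [
    "innervation_intensity",
    "anatomical_fold_change",
    "projection_fold_change",
    "assignment_variance",
    "enumerate_assignments",
    "best_assignment",
    "identify_enriched_clusters",
    "normalized_innervation",
]

AFGrid = Mapping[tuple[str, int], float]
Assignment = Mapping[str, str]


def innervation_intensity(records: pd.DataFrame) -> pd.Series:
    """Mean innervation intensity per (ending_type, region).

    ``records`` has columns ending_type, region, measure, sample_total_area;
    the per-record intensity is measure / sample_total_area (area fraction
    for ME/pIMA/cIMA, count per area for IGLE) and replicates are averaged.
    """
    if (records["sample_total_area"] <= 0).any():
        raise ValueError("sample_total_area must be positive")
    intensity = records["measure"] / records["sample_total_area"]
    return intensity.groupby([records["ending_type"], records["region"]]).mean()


def anatomical_fold_change(
    intensity: pd.Series, whole_region: str | int = "whole"
) -> dict[tuple[str, int], float]:
    """AF(type, region): regional intensity over whole-stomach intensity.

    ``intensity`` is indexed by (ending_type, region) and must include the
    whole-stomach region (label ``whole_region``) for every type; a type
    with zero whole-stomach intensity yields NaN (missing) AF entries.
    """
    af: dict[tuple[str, int], float] = {}
    for (etype, region), value in intensity.items():
        if region == whole_region:
            continue
        whole = intensity.get((etype, whole_region))
        if whole is None:
            raise KeyError(f"no whole-stomach intensity for ending type {etype!r}")
        af[(etype, region)] = value / whole if whole > 0 else float("nan")
    return af


def projection_fold_change(
    assignment: Assignment,
    labels: pd.DataFrame,
    regions: Sequence[int] = STOMACH_REGIONS,
    types: Sequence[str] = ENDING_TYPES,
) -> dict[tuple[str, int], float]:
    """SF(type, region) from cluster barcode percentages under an assignment.

    ``labels`` is indexed by cluster with column ``single_pct`` (stomach
    single-barcode percentage) and ``dual_pct_<region>`` columns.
    SF = sum(dual percentages over the type's clusters) /
    sum(single percentages over the type's clusters) — a ratio of sums,
    not a sum of ratios.
    """
    clusters_of: dict[str, list[str]] = {t: [] for t in types}
    for cluster, etype in assignment.items():
        if etype not in clusters_of:
            raise KeyError(f"unknown ending type {etype!r}")
        if cluster not in labels.index:
            raise KeyError(f"unknown cluster {cluster!r}")
        clusters_of[etype].append(cluster)
    sf: dict[tuple[str, int], float] = {}
    for etype, members in clusters_of.items():
        if not members:
            continue
        single_sum = labels.loc[members, "single_pct"].sum()
        if single_sum <= 0:
            raise ValueError(f"zero summed single percentage for type {etype!r}")
        for region in regions:
            dual_sum = labels.loc[members, f"dual_pct_{region}"].sum()
            sf[(etype, region)] = float(dual_sum / single_sum)
    return sf


def assignment_variance(
    assignment: Assignment,
    af: AFGrid,
    labels: pd.DataFrame,
    regions: Sequence[int] = STOMACH_REGIONS,
    types: Sequence[str] = ENDING_TYPES,
) -> float:
    """Total squared SF-AF discrepancy over the (type, region) grid."""
    sf = projection_fold_change(assignment, labels, regions, types)
    total = 0.0
    for etype in types:
        for region in regions:
            if (etype, region) not in sf:
                continue  # type without assigned clusters contributes nothing
            if (etype, region) not in af:
                raise KeyError(f"AF grid missing entry {(etype, region)!r}")
            total += (sf[(etype, region)] - af[(etype, region)]) ** 2
    return total


def enumerate_assignments(
    free_clusters: Sequence[str], types: Sequence[str] = ENDING_TYPES
) -> Iterator[dict[str, str]]:
    """All len(types)**len(free_clusters) assignments, lexicographic order.

    Order is lexicographic over the cluster sequence with the type sequence
    defining per-position order (so the first assignment maps every cluster
    to types[0]).
    """
    if len(types) < 1:
        raise ValueError("need at least one ending type")
    for combo in itertools.product(types, repeat=len(free_clusters)):
        yield dict(zip(free_clusters, combo))


def best_assignment(
    af: AFGrid,
    labels: pd.DataFrame,
    free_clusters: Sequence[str],
    fixed_map: Assignment | None = None,
    regions: Sequence[int] = STOMACH_REGIONS,
    types: Sequence[str] = ENDING_TYPES,
) -> tuple[dict[str, str], float]:
    """Exhaustive search for the minimum-variance ending-type assignment.

    Every enumerated assignment of the free clusters is merged with the
    fixed (pre-annotated) map and scored; the lowest-variance trial wins,
    with exact ties broken toward the lexicographically earliest assignment
    (enumeration order).  Returns (full assignment, variance).
    """
    fixed = dict(fixed_map or {})
    # precompute per-cluster percentage vectors so the 4^k inner loop stays
    # free of DataFrame indexing
    single = {c: float(labels.loc[c, "single_pct"]) for c in labels.index}
    dual = {
        c: np.array([labels.loc[c, f"dual_pct_{r}"] for r in regions], dtype=float)
        for c in labels.index
    }
    af_vec = {
        t: np.array([af[(t, r)] for r in regions], dtype=float) for t in types
    }
    fixed_single = {t: 0.0 for t in types}
    fixed_dual = {t: np.zeros(len(regions)) for t in types}
    for c, t in fixed.items():
        fixed_single[t] += single[c]
        fixed_dual[t] = fixed_dual[t] + dual[c]

    best: dict[str, str] | None = None
    best_var = np.inf
    for combo in itertools.product(types, repeat=len(free_clusters)):
        s = dict(fixed_single)
        d = {t: fixed_dual[t].copy() for t in types}
        for c, t in zip(free_clusters, combo):
            s[t] += single[c]
            d[t] += dual[c]
        var = 0.0
        for t in types:
            if s[t] <= 0:
                continue  # type without assigned clusters contributes nothing
            var += float(((d[t] / s[t] - af_vec[t]) ** 2).sum())
        if var < best_var:
            best = {**fixed, **dict(zip(free_clusters, combo))}
            best_var = var
    if best is None:
        raise ValueError("empty enumeration")
    return best, float(best_var)


def identify_enriched_clusters(
    percentages: pd.DataFrame,
    mode: str = "single",
    pct_threshold: float = 4.0,
    margin: float = 5.0,
) -> list[str]:
    """Clusters enriched for an organ, sphincter/region, or stomach fundus.

    Modes (``percentages`` indexed by cluster, values in percent):

    - ``single``: column ``single_pct``; enriched when single share is
      strictly above ``pct_threshold`` (default 4%).
    - ``dual``: columns ``dual_pct``, ``single_pct_a``, ``single_pct_b``;
      enriched when the dual share exceeds 4% AND is at least ``margin``
      percentage points above both organs' single shares.
    - ``region5``: columns ``single_pct`` plus every ``dual_pct_*`` column;
      enriched when the stomach single share exceeds 4% AND is at least
      ``margin`` points above each dual share.
    """
    out = []
    for cluster, row in percentages.iterrows():
        if mode == "single":
            ok = row["single_pct"] > pct_threshold
        elif mode == "dual":
            ok = (
                row["dual_pct"] > pct_threshold
                and row["dual_pct"] >= row["single_pct_a"] + margin
                and row["dual_pct"] >= row["single_pct_b"] + margin
            )
        elif mode == "region5":
            duals = [row[c] for c in percentages.columns if c.startswith("dual_pct")]
            ok = row["single_pct"] > pct_threshold and all(
                row["single_pct"] >= d + margin for d in duals
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if ok:
            out.append(cluster)
    return out


def normalized_innervation(cre_intensity: float, reference_intensity: float) -> float:
    """Cre-line ending intensity normalised to the pan-vagal reference."""
    if reference_intensity <= 0:
        raise ValueError("reference intensity must be positive")
    if cre_intensity < 0:
        raise ValueError("intensity must be nonnegative")
    return cre_intensity / reference_intensity
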