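"""Per-miRNA pathway over-representation by one-sided Fisher/hypergeometric test.

For each miRNA's candidate target gene set (the query) and each pathway
gene set, the p-value is the hypergeometric upper tail
P(X >= k) with overlap k, query size n, pathway size K and background
size N.  The conservative EASE variant (overlap reduced by one, as used
by the DAVID service) is available behind a flag; raw p-values are
thresholded by default (no multiple-testing correction), with an optional
Benjamini-Hochberg flag.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io import GeneSetCollection

__all__ = ["enrich", "enrich_per_mirna"]

_COLUMNS = [
    "mirna_id",
    "pathway_id",
    "pathway_name",
    "overlap_genes",
    "overlap_count",
    "query_size",
    "pathway_size",
    "background_size",
    "p_value",
    "significant",
]


def _hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: set[str],
    collection: GeneSetCollection,
    background: set[str] | None = None,
    alpha: float = 0.05,
    mirna_id: str = "",
    ease: bool = False,
    bh: bool = False,
) -> pd.DataFrame:
    """Enrichment of one gene set against every pathway in the collection.

    Only pathways overlapping the query (k >= 1) are reported; results are
    sorted by ascending p then pathway id.  ``significant`` is inclusive at
    the ``alpha`` boundary.  With ``ease=True`` the overlap is reduced by
    one before taking the upper tail (EASE score); with ``bh=True`` the
    p-values are BH-adjusted before thresholding.
    """
    universe = frozenset(background) if background is not None else collection.universe
    for set_id, (_, members) in collection.sets.items():
        extra = members - universe
        if extra:
            raise ValueError(
                f"background is smaller than gene set {set_id!r}; missing {len(extra)} genes"
            )
    query = set(query) & universe if query else set(query)
    if not query:
        warnings.warn(f"empty query gene set for {mirna_id or 'enrichment'}", stacklevel=2)
        return pd.DataFrame(columns=_COLUMNS)
    n = len(query)
    N = len(universe)
    rows = []
    for pathway_id in sorted(collection.sets):
        name, members = collection.sets[pathway_id]
        overlap = query & members
        k = len(overlap)
        if k == 0:
            continue
        k_eff = max(k - 1, 0) if ease else k
        p = _hypergeom_upper(k_eff, n, len(members), N) if k_eff > 0 else 1.0
        rows.append(
            {
                "mirna_id": mirna_id,
                "pathway_id": pathway_id,
                "pathway_name": name,
                "overlap_genes": tuple(sorted(overlap)),
                "overlap_count": k,
                "query_size": n,
                "pathway_size": len(members),
                "background_size": N,
                "p_value": p,
            }
        )
    result = pd.DataFrame(rows, columns=_COLUMNS[:-1])
    if len(result) == 0:
        result["significant"] = pd.Series(dtype=bool)
        return result
    if bh:
        result["p_value"] = bh_adjust(result["p_value"].to_numpy())
    result["significant"] = result["p_value"] <= alpha
    return result.sort_values(["p_value", "pathway_id"]).reset_index(drop=True)


def enrich_per_mirna(
    targets_by_mirna: Mapping[str, set[str]],
    collection: GeneSetCollection,
    background: set[str] | None = None,
    alpha: float = 0.05,
    ease: bool = False,
    bh: bool = False,
) -> pd.DataFrame:
    """Run :func:`enrich` for every miRNA's candidate target set; concatenated,
    sorted within each miRNA by p-value."""
    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for mirna in sorted(targets_by_mirna):
            frames.append(
                enrich(
                    targets_by_mirna[mirna],
                    collection,
                    background=background,
                    alpha=alpha,
                    mirna_id=mirna,
                    ease=ease,
                    bh=bh,
                )
            )
    if not frames:
        return pd.DataFrame(columns=_COLUMNS)
    return pd.concat(frames, ignore_index=True)
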