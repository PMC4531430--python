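"""Consensus miRNA-target integration and restriction to DE features.

The seven upstream target predictors (MicroCosm, microT, miRanda, miRDB,
PicTar, PITA, TargetScan) are external tools whose output tables are
*inputs*; the computation here is the integration: merge per-source
evidence, keep pairs supported by at least ``min_sources`` sources, then
restrict to differentially expressed miRNAs and genes and annotate each
side's regulation direction.

A published per-miRNA target-count summary table ships as a packaged
fixture (``fixtures/table2.tsv``); :func:`expand_summary_to_interactions`
turns its aggregate counts into an equivalent synthetic interaction list
so the downstream candidate-selection arithmetic can be exercised without
the unreleased raw data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .diffexpr import ConsistentSets
from .io import FormatError, InteractionEvidence

__all__ = [
    "AnnotatedInteraction",
    "merge_evidence",
    "consensus_interactions",
    "restrict_to_de",
    "load_summary_fixture",
    "expand_summary_to_interactions",
]


@dataclass(frozen=True)
class AnnotatedInteraction:
    """A consensus interaction between a DE miRNA and a DE gene."""

    mirna_id: str
    gene_id: str
    mirna_direction: str  # up | down
    gene_direction: str  # up | down
    sources: frozenset[str] = frozenset({"fixture"})


def merge_evidence(per_source: Iterable[InteractionEvidence]) -> list[InteractionEvidence]:
    """Merge evidence rows across sources; one row per (miRNA, gene) pair
    with the union of supporting sources.  Deterministic (sorted) order."""
    merged: dict[tuple[str, str], set[str]] = {}
    for row in per_source:
        merged.setdefault((row.mirna_id, row.gene_id), set()).update(row.sources)
    return [
        InteractionEvidence(m, g, frozenset(sources))
        for (m, g), sources in sorted(merged.items())
    ]


def consensus_interactions(
    evidence: Iterable[InteractionEvidence], min_sources: int = 2
) -> list[InteractionEvidence]:
    """Keep exactly the pairs supported by >= ``min_sources`` sources."""
    if min_sources < 1:
        raise ValueError("min_sources must be >= 1")
    return [row for row in evidence if len(row.sources) >= min_sources]


def restrict_to_de(
    interactions: Iterable[InteractionEvidence],
    de_mirnas: ConsistentSets,
    de_genes: ConsistentSets,
) -> list[AnnotatedInteraction]:
    """Keep interactions whose miRNA and gene are both DE; annotate directions."""
    out: list[AnnotatedInteraction] = []
    for row in interactions:
        m_dir = de_mirnas.direction_of(row.mirna_id)
        g_dir = de_genes.direction_of(row.gene_id)
        if m_dir is None or g_dir is None:
            continue
        out.append(
            AnnotatedInteraction(row.mirna_id, row.gene_id, m_dir, g_dir, row.sources)
        )
    return out


# ---------------------------------------------------------------------------
# Packaged summary fixture
# ---------------------------------------------------------------------------

_FIXTURE_COLUMNS = [
    "mirna",
    "direction",
    "total_predicted",
    "de_targets",
    "up_targets",
    "down_targets",
    "candidates",
]


def load_summary_fixture(path: str | Path | None = None) -> pd.DataFrame:
    """Load the packaged per-miRNA target-count summary table.

    Every row is validated against the invariant
    ``de_targets = up_targets + down_targets``.
    """
    if path is None:
        ref = resources.files("hcscnet").joinpath("fixtures/table2.tsv")
        with resources.as_file(ref) as fixture_path:
            df = pd.read_csv(fixture_path, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns) != _FIXTURE_COLUMNS:
        raise FormatError(f"summary fixture columns must be {_FIXTURE_COLUMNS}")
    bad = df[df["de_targets"] != df["up_targets"] + df["down_targets"]]
    if len(bad):
        raise FormatError(
            "summary fixture violates de_targets = up + down for: "
            + ", ".join(bad["mirna"])
        )
    if not df["direction"].isin(["up", "down"]).all():
        raise FormatError("summary fixture directions must be 'up' or 'down'")
    return df


def expand_summary_to_interactions(
    summary: pd.DataFrame,
) -> tuple[list[AnnotatedInteraction], ConsistentSets, ConsistentSets]:
    """Expand aggregate per-miRNA counts into an equivalent interaction list.

    Synthetic gene identifiers are generated per (miRNA, direction, index);
    gene sharing between miRNAs is not represented (the aggregate table does
    not record it), which leaves per-miRNA and total counts exact while NOD
    values computed from the expansion are not meaningful.  Returns the
    interactions plus the implied DE miRNA and DE gene direction sets.
    """
    interactions: list[AnnotatedInteraction] = []
    up_mirnas, down_mirnas = set(), set()
    up_genes, down_genes = set(), set()
    for row in summary.itertuples(index=False):
        (up_mirnas if row.direction == "up" else down_mirnas).add(row.mirna)
        for gene_dir, n in (("up", row.up_targets), ("down", row.down_targets)):
            for i in range(int(n)):
                gene = f"{row.mirna}:{gene_dir}:{i}"
                (up_genes if gene_dir == "up" else down_genes).add(gene)
                interactions.append(
                    AnnotatedInteraction(row.mirna, gene, row.direction, gene_dir)
                )
    de_mirnas = ConsistentSets(frozenset(up_mirnas), frozenset(down_mirnas))
    de_genes = ConsistentSets(frozenset(up_genes), frozenset(down_genes))
    return interactions, de_mirnas, de_genes
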