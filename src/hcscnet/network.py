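"""Bipartite miRNA->gene regulatory network construction and statistics.

Candidate interactions are the anti-correlated subset of DE-restricted
consensus interactions: an up-regulated miRNA paired with a down-regulated
gene, or vice versa, reflecting miRNA-mediated mRNA repression.  On the
resulting directed bipartite graph we compute per-miRNA degree and NOD
("novel out degree": the number of target genes regulated by that miRNA
alone), connected components, a generic exact 2x2 Fisher test, the
per-miRNA summary table, and the tripartite miRNA-gene-pathway network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .targets import AnnotatedInteraction

__all__ = [
    "CandidateInteraction",
    "candidate_interactions",
    "build_network",
    "split_by_mirna_direction",
    "nod",
    "unique_target_genes",
    "connected_components",
    "fisher_exact_2x2",
    "nod_exclusivity_test",
    "assemble_tripartite",
    "summarize_interaction_table",
    "network_sif_edges",
]

_OPPOSITE = {"up": "down", "down": "up"}


@dataclass(frozen=True)
class CandidateInteraction:
    """Anti-correlated miRNA->gene pair (miRNA and gene directions differ)."""

    mirna_id: str
    gene_id: str
    mirna_direction: str
    gene_direction: str

    def __post_init__(self) -> None:
        if self.mirna_direction not in _OPPOSITE or self.gene_direction not in _OPPOSITE:
            raise ValueError("directions must be 'up' or 'down'")
        if self.mirna_direction == self.gene_direction:
            raise ValueError(
                f"{self.mirna_id}->{self.gene_id}: candidate interactions must be anti-correlated"
            )


def candidate_interactions(
    annotated: Iterable[AnnotatedInteraction],
) -> list[CandidateInteraction]:
    """Retain exactly the opposite-direction (anti-correlated) pairs."""
    out: list[CandidateInteraction] = []
    for row in annotated:
        if row.mirna_direction is None or row.gene_direction is None:
            raise ValueError(f"{row.mirna_id}->{row.gene_id}: missing direction annotation")
        if row.mirna_direction != row.gene_direction:
            out.append(
                CandidateInteraction(
                    row.mirna_id, row.gene_id, row.mirna_direction, row.gene_direction
                )
            )
    return out


def build_network(candidates: Sequence[CandidateInteraction]) -> nx.DiGraph:
    """Directed bipartite graph; miRNA nodes carry their candidate-target count.

    Node attributes: ``kind`` ("miRNA" | "gene") and ``direction``; miRNA
    nodes additionally carry ``candidate_targets`` (their out-degree, the
    node-size attribute of the published network figures).  miRNAs with
    zero candidates never appear (they have no edges to contribute).
    """
    net = nx.DiGraph()
    for cand in candidates:
        net.add_node(cand.mirna_id, kind="miRNA", direction=cand.mirna_direction)
        net.add_node(cand.gene_id, kind="gene", direction=cand.gene_direction)
        net.add_edge(cand.mirna_id, cand.gene_id)
    for node, data in net.nodes(data=True):
        if data["kind"] == "miRNA":
            net.nodes[node]["candidate_targets"] = net.out_degree(node)
    return net


def split_by_mirna_direction(
    candidates: Sequence[CandidateInteraction],
) -> tuple[nx.DiGraph, nx.DiGraph]:
    """(up-miRNA subnetwork, down-miRNA subnetwork)."""
    up = [c for c in candidates if c.mirna_direction == "up"]
    down = [c for c in candidates if c.mirna_direction == "down"]
    return build_network(up), build_network(down)


def _mirna_nodes(net: nx.DiGraph) -> list[str]:
    return [n for n, d in net.nodes(data=True) if d.get("kind") == "miRNA"]


def nod(net: nx.DiGraph) -> dict[str, int]:
    """Per-miRNA NOD: the number of genes regulated by that miRNA alone.

    NOD(m) = |{g : the only edge into g is m->g}|; always <= degree(m).
    """
    out = {m: 0 for m in _mirna_nodes(net)}
    for gene, data in net.nodes(data=True):
        if data.get("kind") != "gene":
            continue
        regulators = list(net.predecessors(gene))
        if len(regulators) == 1:
            out[regulators[0]] += 1
    return out


def unique_target_genes(net: nx.DiGraph) -> frozenset[str]:
    """Genes with exactly one regulator (the genes NOD counts)."""
    return frozenset(
        g
        for g, d in net.nodes(data=True)
        if d.get("kind") == "gene" and net.in_degree(g) == 1
    )


def connected_components(net: nx.DiGraph) -> list[frozenset[str]]:
    """Weakly connected components, ordered by decreasing size then by
    lexicographically smallest member node."""
    comps = [frozenset(c) for c in nx.weakly_connected_components(net)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


# ---------------------------------------------------------------------------
# Exact 2x2 Fisher test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero contingency table")


def fisher_exact_2x2(
    table: ContingencyTable2x2 | Sequence[Sequence[int]],
    alternative: str = "two-sided",
) -> float:
    """Exact conditional (hypergeometric) p-value for a 2x2 table.

    ``two-sided``: sum of probabilities of all tables with the observed
    margins whose point probability is <= the observed table's, with a
    1e-7 relative tolerance so floating-point ties count as ties.
    ``greater``: upper tail P(A >= a) for the (1,1) cell.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    r1 = a + b  # first-row margin
    c1 = a + c  # first-column margin
    # support of the (1,1) cell given the margins
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    observed = pmf[a - lo]
    if alternative == "greater":
        return float(min(1.0, pmf[support >= a].sum()))
    if alternative != "two-sided":
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    return float(min(1.0, pmf[pmf <= observed * (1.0 + 1e-7)].sum()))


def nod_exclusivity_test(up_net: nx.DiGraph, down_net: nx.DiGraph) -> tuple[ContingencyTable2x2, float]:
    """One plausible reconstruction of the subnetwork-exclusivity test.

    Cross-tabulates target genes of the up- and down-miRNA subnetworks by
    whether they are uniquely regulated (exactly one regulator) or shared,
    and applies the two-sided exact test.  The published analysis states
    only that an exact test was applied to the exclusivity feature, not the
    contingency table itself, so this helper is a documented interpretation
    rather than a reproduction.
    """
    def counts(net: nx.DiGraph) -> tuple[int, int]:
        genes = [g for g, d in net.nodes(data=True) if d.get("kind") == "gene"]
        uniq = sum(1 for g in genes if net.in_degree(g) == 1)
        return uniq, len(genes) - uniq

    up_uniq, up_shared = counts(up_net)
    down_uniq, down_shared = counts(down_net)
    table = ContingencyTable2x2(up_uniq, up_shared, down_uniq, down_shared)
    return table, fisher_exact_2x2(table, "two-sided")


# ---------------------------------------------------------------------------
# Tripartite network and summary table
# ---------------------------------------------------------------------------

def assemble_tripartite(
    candidates: Sequence[CandidateInteraction],
    enrichment_results: pd.DataFrame,
) -> nx.DiGraph:
    """Add pathway nodes and gene->pathway membership edges to the bipartite net.

    ``enrichment_results`` must carry columns ``mirna_id``, ``pathway_id``,
    ``pathway_name`` and ``overlap_genes`` (iterables of gene ids); every
    overlap gene must be a candidate target gene, otherwise the reference
    is dangling and an error is raised.  Genes with a single regulator are
    flagged ``unique_regulator=True`` (the asterisked nodes of the
    published figures).
    """
    net = build_network(candidates)
    for gene in unique_target_genes(net):
        net.nodes[gene]["unique_regulator"] = True
    if enrichment_results is None or len(enrichment_results) == 0:
        return net
    gene_nodes = {n for n, d in net.nodes(data=True) if d.get("kind") == "gene"}
    for row in enrichment_results.itertuples(index=False):
        dangling = set(row.overlap_genes) - gene_nodes
        if dangling:
            raise ValueError(
                f"pathway {row.pathway_id!r}: overlap genes not in candidate network: {sorted(dangling)}"
            )
        net.add_node(row.pathway_id, kind="pathway", name=row.pathway_name)
        for gene in row.overlap_genes:
            net.add_edge(gene, row.pathway_id, relation="member_of")
    return net


def summarize_interaction_table(
    de_mirna_directions: Mapping[str, str],
    annotated: Sequence[AnnotatedInteraction],
    candidates: Sequence[CandidateInteraction],
    total_predicted: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-DE-miRNA summary: direction, total predicted, DE / up-DE / down-DE
    targets, candidate targets.

    ``total_predicted`` (consensus-predicted target counts per miRNA,
    before the DE restriction) may be supplied externally when only the
    DE-restricted interactions are available; missing miRNAs get 0.
    One row per DE miRNA, including miRNAs with zero DE targets; the row
    invariant de_targets = up_targets + down_targets holds by construction.
    """
    up_counts: dict[str, int] = {m: 0 for m in de_mirna_directions}
    down_counts: dict[str, int] = {m: 0 for m in de_mirna_directions}
    for row in annotated:
        if row.mirna_id not in de_mirna_directions:
            raise ValueError(f"interaction references non-DE miRNA {row.mirna_id!r}")
        if row.gene_direction == "up":
            up_counts[row.mirna_id] += 1
        else:
            down_counts[row.mirna_id] += 1
    cand_counts: dict[str, int] = {m: 0 for m in de_mirna_directions}
    for cand in candidates:
        cand_counts[cand.mirna_id] += 1
    total = dict(total_predicted or {})
    rows = []
    for mirna in sorted(de_mirna_directions):
        rows.append(
            {
                "mirna": mirna,
                "direction": de_mirna_directions[mirna],
                "total_predicted": int(total.get(mirna, 0)),
                "de_targets": up_counts[mirna] + down_counts[mirna],
                "up_targets": up_counts[mirna],
                "down_targets": down_counts[mirna],
                "candidates": cand_counts[mirna],
            }
        )
    return pd.DataFrame(rows)


def network_sif_edges(net: nx.DiGraph) -> list[tuple[str, str, str]]:
    """SIF triples: ``mirna represses gene`` and ``gene member_of pathway``."""
    out = []
    for u, v, data in net.edges(data=True):
        relation = data.get("relation")
        if relation is None:
            relation = "represses" if net.nodes[u].get("kind") == "miRNA" else "member_of"
        out.append((u, relation, v))
    return out
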