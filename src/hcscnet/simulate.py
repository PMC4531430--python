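"""Synthetic paired stem/parental count data with known ground truth.

The generator emulates the structure of the study design every stage of
the pipeline consumes: two stem/parental cell-line pairs of miRNA and
gene tag counts with planted differential expression, seven noisy
miRNA-target prediction sources over a planted target map, and pathway
gene-set collections with an optionally planted enriched pathway.  All
outputs are pure functions of the configuration (which carries a
mandatory seed), so regenerated files are byte-identical.

Default magnitudes echo the study: library sizes of 1e7 mapped miRNA
tags and 1e6 gene reads per sample, ~5% differentially expressed
features with 4-fold effects, on the order of a hundred targets per
miRNA, and pathway sets of ~50 genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .diffexpr import poisson_tagcount_p
from .io import (
    CountTable,
    GeneSetCollection,
    SamplePairing,
    write_count_table,
    write_gmt,
    write_prediction_source,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_counts",
    "simulate_prediction_sources",
    "simulate_gene_sets",
    "write_simulated_inputs",
    "null_type1_error",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; the defaults are the study-shaped conditions.

    ``expression_cpm_range`` is the log-uniform range of per-feature base
    rates in counts per million mapped reads — the robustly detected
    regime differential-expression candidate lists occupy.  ``effect_log2``
    is the planted |log2 fold change| (condition over reference);
    ``concordance`` is the probability a true DE feature is planted in
    both cell-line pairs.  Count noise is Poisson by default; negative
    binomial with dispersion ``dispersion`` (variance mu + dispersion *
    mu^2) is available to stress-test model misspecification.
    """

    seed: int
    n_genes: int = 2000
    n_mirnas: int = 150
    depth_gene: int = 1_000_000
    depth_mirna: int = 10_000_000
    de_fraction: float = 0.05
    effect_log2: float = 2.0
    noise: str = "poisson"  # "poisson" | "nb"
    dispersion: float = 0.1
    concordance: float = 1.0
    expression_cpm_range: tuple[float, float] = (50.0, 5000.0)
    gene_length_range: tuple[int, int] = (200, 10_000)
    n_sources: int = 7
    source_sensitivity: float = 0.9
    source_fp_rate: float = 1e-4
    mean_targets_per_mirna: float = 100.0
    n_pathways: int = 20
    pathway_size: int = 50
    planting_factor: float = 5.0
    max_pairs_per_source: int = 1_000_000

    def __post_init__(self) -> None:
        for prob, label in (
            (self.de_fraction, "de_fraction"),
            (self.concordance, "concordance"),
            (self.source_sensitivity, "source_sensitivity"),
            (self.source_fp_rate, "source_fp_rate"),
        ):
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"{label} must lie in [0, 1]")
        if self.depth_gene <= 0 or self.depth_mirna <= 0:
            raise ValueError("depths must be positive")
        if self.noise not in ("poisson", "nb"):
            raise ValueError("noise must be 'poisson' or 'nb'")
        if self.noise == "nb" and self.dispersion <= 0:
            raise ValueError("nb noise requires positive dispersion")
        if self.n_genes < 1 or self.n_mirnas < 1 or self.n_pathways < 0:
            raise ValueError("feature and pathway counts must be positive")
        if self.pathway_size > self.n_genes:
            raise ValueError("pathway_size cannot exceed the gene universe")
        if self.planting_factor < 1.0:
            raise ValueError("planting_factor must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth the generator's outputs realize."""

    de_per_pair: Mapping[str, Mapping[str, Mapping[str, frozenset[str]]]]
    # de_per_pair[feature_class][pair_id]["up"|"down"] -> feature ids
    target_map: Mapping[str, frozenset[str]]
    enriched_pairs: tuple[tuple[str, str], ...] = ()

    def consistent(self, feature_class: str) -> tuple[frozenset[str], frozenset[str]]:
        """(up, down) features planted in BOTH pairs."""
        per_pair = self.de_per_pair[feature_class]
        pair_ids = list(per_pair)
        up = frozenset.intersection(*[per_pair[p]["up"] for p in pair_ids])
        down = frozenset.intersection(*[per_pair[p]["down"] for p in pair_ids])
        return up, down


_PAIR_IDS = ("cellline1", "cellline2")


def _sample_ids(pair_id: str) -> tuple[str, str]:
    return f"{pair_id}-stem", f"{pair_id}-cancer"


def _simulate_class(
    rng: np.random.Generator,
    config: SimulationConfig,
    n_features: int,
    depth: int,
    prefix: str,
) -> tuple[np.ndarray, dict[str, dict[str, frozenset[str]]], tuple[str, ...]]:
    """Counts (features x 4 samples: stem1, cancer1, stem2, cancer2) + truth."""
    feature_ids = tuple(f"{prefix}-{i:05d}" for i in range(n_features))
    lo, hi = config.expression_cpm_range
    base_cpm = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_features))
    n_de = int(round(config.de_fraction * n_features))
    de_idx = rng.choice(n_features, size=n_de, replace=False)
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    # per-pair planting honours the concordance probability; pair 1 always planted
    planted = {pid: {"up": set(), "down": set()} for pid in _PAIR_IDS}
    fold = {pid: np.ones(n_features) for pid in _PAIR_IDS}
    for j, idx in enumerate(de_idx):
        direction = "up" if signs[j] > 0 else "down"
        pair_mask = [True, rng.random() < config.concordance]
        for pid, active in zip(_PAIR_IDS, pair_mask):
            if active:
                fold[pid][idx] = 2.0 ** (signs[j] * config.effect_log2)
                planted[pid][direction].add(feature_ids[idx])
    columns = []
    for pid in _PAIR_IDS:
        for is_condition in (True, False):
            mean = base_cpm * (fold[pid] if is_condition else 1.0) * depth / 1e6
            if config.noise == "poisson":
                counts = rng.poisson(mean)
            else:  # gamma-Poisson mixture: variance mu + dispersion * mu^2
                shape = 1.0 / config.dispersion
                counts = rng.poisson(rng.gamma(shape, mean / shape))
            columns.append(counts)
    counts = np.column_stack(columns).astype(np.int64)
    truth = {
        pid: {d: frozenset(members) for d, members in planted[pid].items()}
        for pid in _PAIR_IDS
    }
    return counts, truth, feature_ids


def simulate_counts(
    config: SimulationConfig,
) -> tuple[CountTable, CountTable, SamplePairing, GroundTruth]:
    """Paired miRNA and gene count tables for two cell-line pairs.

    Null features share a base rate drawn log-uniformly from
    ``expression_cpm_range``; planted DE features have the condition
    (stem) mean multiplied by ``2 ** (+/- effect_log2)``.  Also plants the
    miRNA->gene target map used by the prediction-source generator.
    """
    rng = np.random.default_rng(config.seed)
    sample_ids = tuple(s for pid in _PAIR_IDS for s in _sample_ids(pid))
    mirna_counts, mirna_truth, mirna_ids = _simulate_class(
        rng, config, config.n_mirnas, config.depth_mirna, "mir"
    )
    gene_counts, gene_truth, gene_ids = _simulate_class(
        rng, config, config.n_genes, config.depth_gene, "gene"
    )
    gene_lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=config.n_genes
    )
    mirna_table = CountTable(
        feature_ids=mirna_ids,
        sample_ids=sample_ids,
        counts=mirna_counts,
        library_sizes=np.full(4, config.depth_mirna, dtype=np.int64),
        feature_class="miRNA",
    )
    gene_table = CountTable(
        feature_ids=gene_ids,
        sample_ids=sample_ids,
        counts=gene_counts,
        library_sizes=np.full(4, config.depth_gene, dtype=np.int64),
        feature_class="gene",
        feature_lengths=gene_lengths,
    )
    pairing = SamplePairing(pairs=tuple(_sample_ids(pid) for pid in _PAIR_IDS))
    # planted target map: each miRNA regulates ~mean_targets_per_mirna genes
    n_targets = rng.poisson(config.mean_targets_per_mirna, size=config.n_mirnas)
    n_targets = np.clip(n_targets, 1, config.n_genes)
    target_map = {
        mirna_ids[i]: frozenset(
            gene_ids[j] for j in rng.choice(config.n_genes, size=n_targets[i], replace=False)
        )
        for i in range(config.n_mirnas)
    }
    truth = GroundTruth(
        de_per_pair={"miRNA": mirna_truth, "gene": gene_truth},
        target_map=target_map,
    )
    return mirna_table, gene_table, pairing, truth


def simulate_prediction_sources(
    truth: GroundTruth, config: SimulationConfig
) -> dict[str, list[tuple[str, str]]]:
    """K noisy prediction sources over the planted target map.

    Independently per source, each true pair appears with probability
    ``source_sensitivity`` and each non-target pair with probability
    ``source_fp_rate``.  Raises if the expected source size exceeds
    ``max_pairs_per_source``.
    """
    if not truth.target_map:
        raise ValueError("truth target map is empty")
    rng = np.random.default_rng(config.seed + 1_000_003)
    mirnas = sorted(truth.target_map)
    true_pairs = [(m, g) for m in mirnas for g in sorted(truth.target_map[m])]
    n_true = len(true_pairs)
    gene_universe = [f"gene-{i:05d}" for i in range(config.n_genes)]
    n_false_possible = len(mirnas) * len(gene_universe) - n_true
    expected = n_true * config.source_sensitivity + n_false_possible * config.source_fp_rate
    if expected > config.max_pairs_per_source:
        raise ValueError(
            f"expected source size {expected:.0f} exceeds cap {config.max_pairs_per_source}"
        )
    true_set = set(true_pairs)
    sources: dict[str, list[tuple[str, str]]] = {}
    for k in range(config.n_sources):
        name = f"source{k + 1}"
        keep_true = rng.random(n_true) < config.source_sensitivity
        pairs = [p for p, keep in zip(true_pairs, keep_true) if keep]
        if config.source_fp_rate > 0:
            flat = rng.random(len(mirnas) * len(gene_universe)) < config.source_fp_rate
            hits = np.nonzero(flat)[0]
            for idx in hits:
                pair = (mirnas[idx // len(gene_universe)], gene_universe[idx % len(gene_universe)])
                if pair not in true_set:
                    pairs.append(pair)
        sources[name] = sorted(set(pairs))
    return sources


def simulate_gene_sets(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[GeneSetCollection, GroundTruth]:
    """Pathway collection over the simulated gene universe, with one planted
    enriched pathway when ``planting_factor > 1``.

    Background pathways sample genes uniformly.  The planted pathway
    includes each target gene of the chosen miRNA (the one with the most
    targets) with probability ``min(1, planting_factor * K / N)`` — an
    inclusion rate ``planting_factor`` times the uniform rate — and fills
    the remaining slots uniformly from non-targets.  Returns the
    collection and a GroundTruth copy with ``enriched_pairs`` recorded.
    """
    rng = np.random.default_rng(config.seed + 2_000_003)
    universe = [f"gene-{i:05d}" for i in range(config.n_genes)]
    if config.pathway_size > len(universe):
        raise ValueError("pathway size exceeds gene universe")
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for j in range(config.n_pathways):
        members = rng.choice(len(universe), size=config.pathway_size, replace=False)
        sets[f"pw{j + 1:03d}"] = (
            f"background pathway {j + 1}",
            frozenset(universe[i] for i in members),
        )
    enriched: tuple[tuple[str, str], ...] = ()
    if config.planting_factor > 1.0 and truth.target_map:
        chosen = max(sorted(truth.target_map), key=lambda m: len(truth.target_map[m]))
        targets = sorted(truth.target_map[chosen])
        p_incl = min(1.0, config.planting_factor * config.pathway_size / len(universe))
        planted = [g for g in targets if rng.random() < p_incl]
        planted = planted[: config.pathway_size]
        pool = [g for g in universe if g not in set(planted)]
        fill = rng.choice(len(pool), size=config.pathway_size - len(planted), replace=False)
        members = frozenset(planted) | frozenset(pool[i] for i in fill)
        sets["pw_planted"] = ("planted enriched pathway", members)
        enriched = ((chosen, "pw_planted"),)
    collection = GeneSetCollection(sets=sets, background=frozenset(universe))
    truth_out = GroundTruth(
        de_per_pair=truth.de_per_pair,
        target_map=truth.target_map,
        enriched_pairs=enriched,
    )
    return collection, truth_out


def write_simulated_inputs(config: SimulationConfig, out_dir: str | Path) -> GroundTruth:
    """Materialize every pipeline input format under ``out_dir``; returns truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mirna_table, gene_table, pairing, truth = simulate_counts(config)
    write_count_table(mirna_table, out / "mirna_counts.tsv")
    write_count_table(gene_table, out / "gene_counts.tsv")
    sources = simulate_prediction_sources(truth, config)
    source_dir = out / "sources"
    source_dir.mkdir(exist_ok=True)
    for name, pairs in sources.items():
        write_prediction_source(pairs, source_dir / f"{name}.tsv")
    collection, truth = simulate_gene_sets(truth, config)
    write_gmt(collection, out / "pathways.gmt")
    with open(out / "pairs.tsv", "w", encoding="utf-8") as handle:
        handle.write("condition\treference\n")
        for cond, ref in pairing.pairs:
            handle.write(f"{cond}\t{ref}\n")
    return truth


def null_type1_error(
    n_draws: int = 10_000,
    mean: float = 100.0,
    alpha: float = 0.05,
    seed: int = 0,
    ratio: float = 1.0,
) -> float:
    """Empirical rejection rate of the exact Poisson test under the null.

    Draws ``n_draws`` pairs (x, y) with equal underlying rates (x at rate
    ``mean``, y at rate ``mean * ratio`` with matching library sizes) and
    returns the fraction of two-sided p-values <= ``alpha``.
    """
    rng = np.random.default_rng(seed)
    x = rng.poisson(mean, size=n_draws)
    y = rng.poisson(mean * ratio, size=n_draws)
    p = poisson_tagcount_p(x, y, 1e6, 1e6 * ratio)
    return float(np.mean(p <= alpha))
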