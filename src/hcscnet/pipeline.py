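"""Full-pipeline orchestration: counts -> normalization -> DE -> consensus
targets -> anti-correlation network -> NOD -> enrichment -> tripartite net.

A single YAML config drives the run; every stage logs its input/output
row counts into a manifest (`manifest.json`) alongside a config snapshot
and input digests, so two runs over identical inputs are comparable at a
glance.  Stage failures abort with the stage name.  A fixture mode skips
the expression stages and drives candidate selection from the packaged
per-miRNA summary table instead.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .diffexpr import call_de_all_pairs, consistent_features
from .enrichment import enrich_per_mirna
from .io import (
    SamplePairing,
    ThresholdConfig,
    read_count_table,
    read_gmt,
    read_prediction_source,
    write_network_sif,
    write_results_table,
)
from .network import (
    assemble_tripartite,
    build_network,
    candidate_interactions,
    connected_components,
    network_sif_edges,
    nod,
    split_by_mirna_direction,
    summarize_interaction_table,
)
from .normalization import rpkm_normalize, tpm_normalize
from .targets import (
    consensus_interactions,
    expand_summary_to_interactions,
    load_summary_fixture,
    merge_evidence,
    restrict_to_de,
)

__all__ = ["PipelineError", "run_all", "load_config"]

logger = logging.getLogger("hcscnet")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path, encoding="utf-8") as handle:
        return yaml.safe_load(handle)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _thresholds(config: Mapping[str, Any]) -> ThresholdConfig:
    return ThresholdConfig(**config.get("thresholds", {}))


def _read_pairs(path: Path) -> SamplePairing:
    df = pd.read_csv(path, sep="\t", comment="#")
    return SamplePairing(pairs=tuple((str(c), str(r)) for c, r in zip(df["condition"], df["reference"])))


def run_all(config: Mapping[str, Any] | str | Path, out_dir: str | Path) -> Path:
    """Run the whole analysis; returns the output directory.

    In fixture mode (``config["fixture_mode"] = True``) the expression and
    consensus stages are replaced by the packaged summary table and the
    candidate-selection arithmetic runs on its expansion.
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    out = Path(out_dir)
    thresholds = _thresholds(config)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": json.loads(json.dumps(dict(config), default=str)),
        "started": datetime.now(timezone.utc).isoformat(),
        "inputs": {},
        "row_counts": {},
    }
    stage = "validate-inputs"
    try:
        if config.get("fixture_mode"):
            out.mkdir(parents=True, exist_ok=True)
            return _run_fixture_mode(config, out, manifest)
        inputs = config["inputs"]
        paths = {key: Path(val) for key, val in inputs.items() if key.endswith(("counts", "pairs", "gmt")) or key == "sources_dir"}
        for key, path in paths.items():
            if not path.exists():
                raise FileNotFoundError(f"input {key!r} not found: {path}")
        lib_cfg = config.get("library_sizes", {})
        mirna_table = read_count_table(
            paths["mirna_counts"], "miRNA", lib_cfg.get("mirna", "column-sum")
        )
        gene_table = read_count_table(
            paths["gene_counts"], "gene", lib_cfg.get("gene", "column-sum")
        )
        if mirna_table.counts.size == 0 or gene_table.counts.size == 0:
            raise ValueError("count tables must be non-empty")
        pairing = _read_pairs(paths["pairs"])
        for key, path in paths.items():
            files = sorted(path.glob("*.tsv")) if path.is_dir() else [path]
            for f in files:
                manifest["inputs"][str(f)] = _sha256(f)
        logger.info(
            "inputs: %d miRNAs, %d genes, %d sample pairs",
            len(mirna_table.feature_ids), len(gene_table.feature_ids), len(pairing.pairs),
        )
        out.mkdir(parents=True, exist_ok=True)

        stage = "normalize"
        mirna_norm = tpm_normalize(mirna_table)
        gene_norm = rpkm_normalize(gene_table)

        stage = "differential-expression"
        de_sets = {}
        for label, raw, norm in (("mirna", mirna_table, mirna_norm), ("gene", gene_table, gene_norm)):
            calls = call_de_all_pairs(raw, norm, pairing, thresholds)
            for pair_id, frame in calls.items():
                write_results_table(frame, out / f"de_{label}_{pair_id}.tsv")
                manifest["row_counts"][f"de_{label}_{pair_id}"] = int(
                    (frame["direction"] != "none").sum()
                )
            frames = list(calls.values())
            de_sets[label] = consistent_features(frames[0], frames[1])
            manifest["row_counts"][f"consistent_{label}"] = len(de_sets[label].all_features)
            logger.info(
                "%s: %d up, %d down consistently regulated",
                label, len(de_sets[label].up_features), len(de_sets[label].down_features),
            )

        stage = "target-consensus"
        source_dir = paths["sources_dir"]
        evidence = []
        for source_path in sorted(source_dir.glob("*.tsv")):
            evidence.extend(read_prediction_source(source_path, source_path.stem))
        merged = merge_evidence(evidence)
        consensus = consensus_interactions(merged, thresholds.min_sources)
        manifest["row_counts"]["merged_evidence"] = len(merged)
        manifest["row_counts"]["consensus_interactions"] = len(consensus)
        annotated = restrict_to_de(consensus, de_sets["mirna"], de_sets["gene"])
        manifest["row_counts"]["de_restricted_interactions"] = len(annotated)
        logger.info(
            "consensus: %d merged, %d with >=%d sources, %d between DE features",
            len(merged), len(consensus), thresholds.min_sources, len(annotated),
        )

        de_mirna_dirs = {
            m: de_sets["mirna"].direction_of(m) for m in de_sets["mirna"].all_features
        }
        total_predicted: dict[str, int] = {}
        for row in consensus:
            if row.mirna_id in de_mirna_dirs:
                total_predicted[row.mirna_id] = total_predicted.get(row.mirna_id, 0) + 1
        gmt_path = paths.get("gmt")
        return _finish(
            config, out, manifest, annotated, de_mirna_dirs, total_predicted,
            thresholds, gmt_path,
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def _run_fixture_mode(config: Mapping[str, Any], out: Path, manifest: dict[str, Any]) -> Path:
    stage = "fixture-expansion"
    try:
        summary = load_summary_fixture(config.get("fixture_path"))
        annotated, de_mirnas, _ = expand_summary_to_interactions(summary)
        de_mirna_dirs = {m: de_mirnas.direction_of(m) for m in de_mirnas.all_features}
        total_predicted = dict(zip(summary["mirna"], summary["total_predicted"].astype(int)))
        manifest["row_counts"]["de_restricted_interactions"] = len(annotated)
        thresholds = _thresholds(config)
        return _finish(config, out, manifest, annotated, de_mirna_dirs, total_predicted, thresholds, None)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def _finish(
    config: Mapping[str, Any],
    out: Path,
    manifest: dict[str, Any],
    annotated,
    de_mirna_dirs,
    total_predicted,
    thresholds: ThresholdConfig,
    gmt_path: Path | None,
) -> Path:
    stage = "candidate-network"
    try:
        candidates = candidate_interactions(annotated)
        manifest["row_counts"]["candidate_interactions"] = len(candidates)
        net = build_network(candidates)
        up_net, down_net = split_by_mirna_direction(candidates)
        logger.info(
            "network: %d candidates (%d up-miRNA, %d down-miRNA edges)",
            len(candidates), up_net.number_of_edges(), down_net.number_of_edges(),
        )
        write_network_sif(network_sif_edges(net), out / "network.sif")
        edge_rows = pd.DataFrame(
            [
                (c.mirna_id, c.gene_id, c.mirna_direction, c.gene_direction)
                for c in candidates
            ],
            columns=["mirna", "gene", "mirna_direction", "gene_direction"],
        )
        write_results_table(
            edge_rows.sort_values(list(edge_rows.columns)).reset_index(drop=True)
            if len(edge_rows) else edge_rows,
            out / "edges.tsv",
        )
        nod_values = nod(net)
        write_results_table(
            pd.DataFrame(
                sorted(nod_values.items()), columns=["mirna", "nod"]
            ),
            out / "nod.tsv",
        )
        manifest["row_counts"]["components_down_subnetwork"] = len(connected_components(down_net))
        summary_frame = summarize_interaction_table(
            de_mirna_dirs, annotated, candidates, total_predicted
        )
        write_results_table(summary_frame, out / "summary_table.tsv")
        manifest["row_counts"]["summary_rows"] = len(summary_frame)

        stage = "enrichment"
        enrichment_frame = pd.DataFrame()
        if gmt_path is not None:
            collection = read_gmt(gmt_path)
            targets_by_mirna: dict[str, set[str]] = {}
            for cand in candidates:
                targets_by_mirna.setdefault(cand.mirna_id, set()).add(cand.gene_id)
            enrichment_frame = enrich_per_mirna(
                targets_by_mirna, collection, alpha=thresholds.enrichment_alpha,
                ease=bool(config.get("ease", False)), bh=bool(config.get("bh_enrichment", False)),
            )
            table3_style = enrichment_frame[enrichment_frame["significant"]].copy()
            table3_style["Genes"] = table3_style["overlap_genes"].map(lambda g: ", ".join(g))
            write_results_table(
                table3_style[
                    ["mirna_id", "pathway_id", "pathway_name", "overlap_count", "Genes", "p_value"]
                ].rename(
                    columns={
                        "mirna_id": "miRNA", "pathway_id": "Term_ID", "pathway_name": "Term_name",
                        "overlap_count": "Gene_count", "p_value": "P-value",
                    }
                ),
                out / "enrichment.tsv",
            )
            manifest["row_counts"]["enriched_significant"] = int(len(table3_style))
            logger.info("enrichment: %d significant (alpha=%g)", len(table3_style), thresholds.enrichment_alpha)

        stage = "tripartite"
        sig = (
            enrichment_frame[enrichment_frame["significant"]]
            if len(enrichment_frame)
            else pd.DataFrame()
        )
        tri = assemble_tripartite(candidates, sig)
        write_network_sif(network_sif_edges(tri), out / "tripartite.sif")
        manifest["row_counts"]["tripartite_edges"] = tri.number_of_edges()

        stage = "manifest"
        manifest["finished"] = datetime.now(timezone.utc).isoformat()
        with open(out / "manifest.json", "w", encoding="utf-8") as handle:
            json.dump(manifest, handle, indent=2, sort_keys=True)
        return out
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
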