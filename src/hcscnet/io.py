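"""Domain types and tabular I/O.

Every external format the pipeline touches is plain tab-separated UTF-8
text: count tables, miRNA-target prediction tables, GMT gene-set files,
and SIF / edge-table network exports.  ``#``-prefixed lines are comments
everywhere.  Identifiers are whitespace-trimmed but otherwise preserved
verbatim (case-sensitive; miRNA "star" names such as ``hsa-miR-22*`` keep
their suffix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "SamplePairing",
    "ThresholdConfig",
    "GeneSetCollection",
    "InteractionEvidence",
    "FormatError",
    "read_count_table",
    "write_count_table",
    "read_prediction_source",
    "read_gmt",
    "write_gmt",
    "write_network_sif",
    "write_network_edge_table",
    "write_results_table",
]


class FormatError(ValueError):
    """Malformed input file; the message names the offending line/field."""


def _clean(token: str) -> str:
    return token.strip()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountTable:
    """Raw feature-by-sample tag counts plus per-sample library sizes.

    Parameters
    ----------
    feature_ids, sample_ids
        Ordered, unique identifiers.
    counts
        Non-negative integer matrix, shape ``(features, samples)``.
    library_sizes
        Total mapped reads per sample (may exceed the column sum — the
        table need not contain every mapped read).
    feature_lengths
        Feature length in nucleotides; required iff ``feature_class ==
        "gene"`` (RPKM needs it, tag TPM does not).
    feature_class
        ``"miRNA"`` or ``"gene"``.
    """

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray
    library_sizes: np.ndarray
    feature_class: str
    feature_lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.feature_class not in ("miRNA", "gene"):
            raise ValueError(f"feature_class must be 'miRNA' or 'gene', got {self.feature_class!r}")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dupes = _duplicates(self.feature_ids)
            raise FormatError(f"duplicate feature ids: {sorted(dupes)}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError(f"duplicate sample ids: {sorted(_duplicates(self.sample_ids))}")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match feature/sample ids")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise FormatError("counts must be integral")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise FormatError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        lib = np.asarray(self.library_sizes, dtype=np.int64)
        if lib.shape != (len(self.sample_ids),):
            raise ValueError("library_sizes must have one entry per sample")
        if np.any(lib <= 0):
            raise ValueError("library sizes must be positive")
        object.__setattr__(self, "library_sizes", lib)
        if self.feature_class == "gene":
            if self.feature_lengths is None:
                raise FormatError("gene count tables require feature lengths")
            lengths = np.asarray(self.feature_lengths, dtype=np.int64)
            if lengths.shape != (len(self.feature_ids),):
                raise ValueError("feature_lengths must have one entry per feature")
            if np.any(lengths <= 0):
                raise FormatError("feature lengths must be positive")
            object.__setattr__(self, "feature_lengths", lengths)

    # convenience accessors --------------------------------------------------
    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_index(sample_id)]

    def library_size(self, sample_id: str) -> int:
        return int(self.library_sizes[self.sample_index(sample_id)])


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for item in items:
        if item in seen:
            dupes.add(item)
        seen.add(item)
    return dupes


@dataclass(frozen=True)
class SamplePairing:
    """Ordered (condition, reference) sample pairs, e.g. (stem, cancer)."""

    pairs: tuple[tuple[str, str], ...]
    condition_label: str = "stem"
    reference_label: str = "cancer"

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("at least one sample pair is required")
        flat = [s for pair in self.pairs for s in pair]
        if len(set(flat)) != len(flat):
            raise ValueError("each sample may appear in at most one pair")

    @property
    def pair_ids(self) -> tuple[str, ...]:
        return tuple(f"{c}_vs_{r}" for c, r in self.pairs)


@dataclass(frozen=True)
class ThresholdConfig:
    """Analysis thresholds; defaults reproduce the study parameterization."""

    min_abs_log2fc: float = 1.0
    max_fdr: float = 0.01
    min_sources: int = 2
    enrichment_alpha: float = 0.05
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.min_abs_log2fc <= 0 or self.pseudocount <= 0:
            raise ValueError("min_abs_log2fc and pseudocount must be positive")
        if not 0 < self.max_fdr <= 1 or not 0 < self.enrichment_alpha <= 1:
            raise ValueError("max_fdr and enrichment_alpha must lie in (0, 1]")
        if self.min_sources < 1:
            raise ValueError("min_sources must be >= 1")


@dataclass(frozen=True)
class GeneSetCollection:
    """Named pathway gene sets plus an optional explicit background universe."""

    sets: Mapping[str, tuple[str, frozenset[str]]]
    background: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for set_id, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {set_id!r} is empty")

    @property
    def universe(self) -> frozenset[str]:
        """Explicit background if given, else the union of all member genes."""
        if self.background is not None:
            return self.background
        out: set[str] = set()
        for _, members in self.sets.values():
            out |= members
        return frozenset(out)


@dataclass(frozen=True)
class InteractionEvidence:
    """A predicted miRNA->gene pair with its supporting prediction sources."""

    mirna_id: str
    gene_id: str
    sources: frozenset[str]

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError("evidence requires at least one source")


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def read_count_table(
    path: str | Path,
    feature_class: str,
    library_sizes: Mapping[str, int] | str = "column-sum",
) -> CountTable:
    """Read a count TSV: header ``feature_id[<TAB>length]<TAB><samples...>``.

    ``library_sizes`` is either a mapping ``sample_id -> total mapped reads``
    (Table-1 style externally supplied totals) or the string ``"column-sum"``
    to use each sample's column total.
    """
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected feature_id plus at least one sample column")
    cols = [_clean(c) for c in df.columns]
    has_length = feature_class == "gene"
    if has_length and (len(cols) < 3 or cols[1] != "length"):
        raise FormatError(f"{path}: gene tables require a 'length' second column")
    feature_ids = tuple(_clean(v) for v in df.iloc[:, 0])
    dupes = _duplicates(feature_ids)
    if dupes:
        raise FormatError(f"{path}: duplicate feature ids: {sorted(dupes)}")
    first_sample_col = 2 if has_length else 1
    sample_ids = tuple(cols[first_sample_col:])
    raw = df.iloc[:, first_sample_col:].to_numpy()
    counts = np.empty(raw.shape, dtype=np.int64)
    for (i, j), val in np.ndenumerate(raw):
        val = _clean(str(val))
        if not val.lstrip("-").isdigit() or int(val) < 0:
            raise FormatError(
                f"{path}: feature {feature_ids[i]!r}, sample {sample_ids[j]!r}: "
                f"count {val!r} is not a non-negative integer"
            )
        counts[i, j] = int(val)
    lengths = None
    if has_length:
        lengths = np.array([int(_clean(str(v))) for v in df.iloc[:, 1]], dtype=np.int64)
    if library_sizes == "column-sum":
        lib = counts.sum(axis=0)
    else:
        try:
            lib = np.array([library_sizes[s] for s in sample_ids], dtype=np.int64)
        except KeyError as exc:
            raise FormatError(f"{path}: no library size supplied for sample {exc.args[0]!r}") from None
    return CountTable(
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        counts=counts,
        library_sizes=lib,
        feature_class=feature_class,
        feature_lengths=lengths,
    )


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write a count TSV readable by :func:`read_count_table`."""
    data: dict[str, object] = {"feature_id": list(table.feature_ids)}
    if table.feature_class == "gene":
        data["length"] = table.feature_lengths
    for j, sample in enumerate(table.sample_ids):
        data[sample] = table.counts[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Prediction sources
# ---------------------------------------------------------------------------

def read_prediction_source(path: str | Path, source_name: str) -> list[InteractionEvidence]:
    """Read one predictor's output: ``mirna_id<TAB>gene_id`` rows.

    Duplicate pairs within a source collapse to a single evidence row.  An
    empty file yields empty evidence with a warning rather than an error
    (a predictor may legitimately return nothing for a miRNA panel).
    """
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'mirna<TAB>gene', got {line!r}")
            if fields[0].strip().lower() == "mirna_id":  # optional header
                continue
            pair = (_clean(fields[0]), _clean(fields[1]))
            if pair not in seen:
                seen.add(pair)
                pairs.append(pair)
    if not pairs:
        warnings.warn(f"prediction source {source_name!r} ({path}) is empty", stacklevel=2)
    return [InteractionEvidence(m, g, frozenset({source_name})) for m, g in pairs]


def write_prediction_source(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("mirna_id\tgene_id\n")
        for mirna, gene in pairs:
            handle.write(f"{mirna}\t{gene}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``set_id<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >=3 fields, got {len(fields)}")
            set_id = _clean(fields[0])
            if set_id in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set id {set_id!r}")
            members = frozenset(_clean(g) for g in fields[2:] if g.strip())
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {set_id!r} has no members")
            sets[set_id] = (_clean(fields[1]), members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for set_id in sorted(collection.sets):
            name, members = collection.sets[set_id]
            handle.write("\t".join([set_id, name, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Network exports
# ---------------------------------------------------------------------------

def write_network_sif(edges: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write SIF lines ``source<TAB>relation<TAB>target`` in sorted order."""
    lines = sorted(f"{s}\t{rel}\t{t}" for s, rel, t in edges)
    with open(path, "w", encoding="utf-8") as handle:
        for line in lines:
            handle.write(line + "\n")


def write_network_edge_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Typed edge table; deterministic row order (sorted by all columns)."""
    out = rows.sort_values(list(rows.columns)).reset_index(drop=True) if len(rows) else rows
    out.to_csv(path, sep="\t", index=False)


def write_results_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)
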