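"""Tag-count normalization: TPM for miRNAs, RPKM for genes.

miRNA tags are (near-)fixed-length, so "transcripts per million" here is
the tag-count form — counts per million mapped reads with no length term.
Gene reads are length-normalized to reads per kilobase of exon model per
million mapped reads (RPKM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CountTable

__all__ = ["NormalizedTable", "tpm_normalize", "rpkm_normalize"]


@dataclass(frozen=True)
class NormalizedTable:
    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # non-negative reals, shape (features, samples)
    method: str  # "TPM" | "RPKM"

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]


def tpm_normalize(table: CountTable) -> NormalizedTable:
    """value(f, s) = count(f, s) * 1e6 / N(s).

    When the library size equals the column sum, each TPM column sums to
    exactly one million.
    """
    if table.feature_class != "miRNA":
        raise ValueError("tpm_normalize expects a miRNA count table")
    if np.any(table.library_sizes == 0):
        raise ValueError("library sizes must be positive")
    values = table.counts * 1e6 / table.library_sizes[np.newaxis, :]
    return NormalizedTable(table.feature_ids, table.sample_ids, values, "TPM")


def rpkm_normalize(table: CountTable) -> NormalizedTable:
    """value(f, s) = count(f, s) * 1e9 / (N(s) * L(f))."""
    if table.feature_class != "gene":
        raise ValueError("rpkm_normalize expects a gene count table")
    if table.feature_lengths is None or np.any(table.feature_lengths == 0):
        raise ValueError("RPKM requires positive feature lengths")
    values = table.counts * 1e9 / (
        table.library_sizes[np.newaxis, :] * table.feature_lengths[:, np.newaxis].astype(float)
    )
    return NormalizedTable(table.feature_ids, table.sample_ids, values, "RPKM")
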