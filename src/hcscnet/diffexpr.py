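"""Exact Poisson-model differential expression for paired tag counts.

The test compares two tag counts x (condition) and y (reference) under a
Poisson sampling model via the posterior-predictive distribution of y
given x and the library-size ratio r = N2/N1:

    P(Y = k | x) = r^k (x+k)! / (x! k! (1+r)^{x+k+1})

which is a negative binomial with ``x + 1`` successes and success
probability ``1 / (1 + r)``.  The two-sided p-value doubles the smaller
tail and caps at 1.  Multiple testing is handled by Benjamini-Hochberg
step-up FDR; direction calls threshold |log2FC| and FDR inclusively, and
features consistently up- or down-regulated across both cell-line pairs
form the candidate biomarker sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountTable, SamplePairing, ThresholdConfig
from .normalization import NormalizedTable

__all__ = [
    "ConsistentSets",
    "poisson_tagcount_p",
    "bh_adjust",
    "call_de",
    "call_de_all_pairs",
    "consistent_features",
]


def poisson_tagcount_p(x, y, n1, n2):
    """Two-sided exact Poisson-model p-value for tag counts.

    Parameters may be scalars or broadcastable arrays; counts must be
    non-negative integers and library sizes positive.  Returns a float
    (or array) p = min(1, 2 * min(P(Y <= y | x), P(Y >= y | x))).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    for arr, label in ((x, "x"), (y, "y")):
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise ValueError(f"{label} counts must be integers")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise ValueError("library sizes must be positive")
    x = x.astype(np.int64)
    y = y.astype(np.int64)
    r = n2 / n1
    prob = 1.0 / (1.0 + r)  # NB success probability
    lower = stats.nbinom.cdf(y, x + 1, prob)
    upper = stats.nbinom.sf(y - 1, x + 1, prob)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return float(p) if p.ndim == 0 else p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _direction(log2fc: np.ndarray, fdr: np.ndarray, thresholds: ThresholdConfig) -> np.ndarray:
    """Inclusive boundaries: |log2FC| >= t and FDR <= max_fdr are significant."""
    out = np.full(log2fc.shape, "none", dtype=object)
    sig = fdr <= thresholds.max_fdr
    out[sig & (log2fc >= thresholds.min_abs_log2fc)] = "up"
    out[sig & (log2fc <= -thresholds.min_abs_log2fc)] = "down"
    return out


def call_de(
    raw: CountTable,
    normalized: NormalizedTable,
    pair: tuple[str, str],
    thresholds: ThresholdConfig,
    pair_id: str | None = None,
) -> pd.DataFrame:
    """Per-feature differential-expression calls for one (condition, reference) pair.

    Returns one row per feature with columns feature_id, pair_id, x, y,
    N1, N2, log2fc, p, fdr, direction.  FDR is computed across all
    features of this table (i.e. within-pair, per data type).
    """
    condition, reference = pair
    if raw.feature_ids != normalized.feature_ids:
        raise ValueError("raw and normalized tables must be aligned on features")
    for sample in pair:
        if sample not in raw.sample_ids:
            raise ValueError(f"pair references unknown sample {sample!r}")
    x = raw.column(condition)
    y = raw.column(reference)
    n1 = raw.library_size(condition)
    n2 = raw.library_size(reference)
    pc = thresholds.pseudocount
    log2fc = np.log2((normalized.column(condition) + pc) / (normalized.column(reference) + pc))
    p = poisson_tagcount_p(x, y, n1, n2)
    fdr = bh_adjust(p)
    return pd.DataFrame(
        {
            "feature_id": list(raw.feature_ids),
            "pair_id": pair_id or f"{condition}_vs_{reference}",
            "x": x,
            "y": y,
            "N1": n1,
            "N2": n2,
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "direction": _direction(log2fc, fdr, thresholds),
        }
    )


def call_de_all_pairs(
    raw: CountTable,
    normalized: NormalizedTable,
    pairing: SamplePairing,
    thresholds: ThresholdConfig,
) -> dict[str, pd.DataFrame]:
    """DE calls for every pair, keyed by pair id."""
    return {
        pair_id: call_de(raw, normalized, pair, thresholds, pair_id=pair_id)
        for pair, pair_id in zip(pairing.pairs, pairing.pair_ids)
    }


@dataclass(frozen=True)
class ConsistentSets:
    """Features up- or down-regulated in BOTH sample pairs (disjoint sets)."""

    up_features: frozenset[str]
    down_features: frozenset[str]

    def __post_init__(self) -> None:
        if self.up_features & self.down_features:
            raise ValueError("up and down sets must be disjoint")

    @property
    def all_features(self) -> frozenset[str]:
        return self.up_features | self.down_features

    def direction_of(self, feature_id: str) -> str | None:
        if feature_id in self.up_features:
            return "up"
        if feature_id in self.down_features:
            return "down"
        return None


def consistent_features(calls_pair1: pd.DataFrame, calls_pair2: pd.DataFrame) -> ConsistentSets:
    """Intersection of direction calls across the two cell-line pairs.

    A feature enters the up (down) set only if called up (down) in both
    pairs; discordant features are excluded entirely.
    """
    u1 = set(calls_pair1["feature_id"])
    u2 = set(calls_pair2["feature_id"])
    if u1 != u2:
        diff = sorted(u1 ^ u2)
        raise ValueError(f"call tables cover different feature universes; symmetric difference: {diff}")
    d1 = dict(zip(calls_pair1["feature_id"], calls_pair1["direction"]))
    d2 = dict(zip(calls_pair2["feature_id"], calls_pair2["direction"]))
    up = frozenset(f for f in u1 if d1[f] == "up" and d2[f] == "up")
    down = frozenset(f for f in u1 if d1[f] == "down" and d2[f] == "down")
    return ConsistentSets(up_features=up, down_features=down)
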