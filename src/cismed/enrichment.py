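"""Enrichment of eQTLs in SNP sets via Fisher's exact test and matched resampling.

The resampling route matches random SNP sets to the target set on MAF
and distance-to-nearest-TSS, using decile bins computed on the non-target
pool, so every replicate reproduces the joint (MAF bin x distance bin)
histogram of the targets exactly. The empirical P-value uses the add-one
permutation estimator (1 + #{replicates >= observed}) / (n_reps + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "FisherResult",
    "EnrichmentResult",
    "fisher_enrichment",
    "bin_features",
    "matched_resampling_enrichment",
]

FEATURE_COLUMNS = ["id", "maf", "tss_distance", "is_target", "is_eqtl"]


class FisherResult(NamedTuple):
    odds_ratio: float
    p_value: float
    continuity_corrected: bool


@dataclass(frozen=True)
class EnrichmentResult:
    observed_count: int
    expected_mean: float
    empirical_p: float
    n_reps: int


def fisher_enrichment(counts_2x2: Sequence[Sequence[int]]) -> FisherResult:
    """Fisher's exact test of a 2x2 enrichment table.

    Returns the cross-product odds ratio and the exact two-sided
    hypergeometric P. When any cell is zero, the odds ratio gets a 0.5
    (Haldane-Anscombe) continuity correction and the result is flagged.
    """
    table = np.asarray(counts_2x2, dtype=float)
    if table.shape != (2, 2) or (table < 0).any() or not np.allclose(table, table.round()):
        raise ValueError("expected a 2x2 table of non-negative integer counts")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise ValueError("a table margin is entirely zero")
    _, p = stats.fisher_exact(table.astype(int), alternative="two-sided")
    corrected = bool((table == 0).any())
    t = table + 0.5 if corrected else table
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return FisherResult(float(odds), float(p), corrected)


def bin_features(values: Sequence[float], n_bins: int = 10) -> np.ndarray:
    """Quantile-bin values; boundary values go to the lower bin.

    Edges are the interior quantiles of ``values``; duplicate edges (ties
    or few distinct values) collapse bins, which is logged.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values to bin")
    edges = np.quantile(v, np.linspace(0, 1, n_bins + 1)[1:-1])
    uniq = np.unique(edges)
    if uniq.size < edges.size:
        logger.warning(
            "collapsed %d bins due to tied quantile edges", edges.size - uniq.size
        )
    return np.searchsorted(uniq, v, side="left")


def assign_bins(
    values: Sequence[float], reference: Sequence[float], n_bins: int = 10
) -> np.ndarray:
    """Bin ``values`` using quantile edges computed on ``reference``."""
    ref = np.asarray(reference, dtype=float)
    edges = np.unique(np.quantile(ref, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, np.asarray(values, dtype=float), side="left")


def matched_resampling_enrichment(
    features: pd.DataFrame,
    n_maf_bins: int = 10,
    n_dist_bins: int = 10,
    n_reps: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Empirical eQTL enrichment of a target SNP set via matched resampling.

    ``features`` needs columns ``maf``, ``tss_distance``, ``is_target``
    and ``is_eqtl``. Each replicate draws, within every joint
    (MAF decile x distance decile) bin occupied by targets, as many
    non-target SNPs as there are targets, without replacement, and
    counts eQTLs among the draw.
    """
    for col in ("maf", "tss_distance", "is_target", "is_eqtl"):
        if col not in features.columns:
            raise ValueError(f"feature table lacks column {col!r}")
    if (features["tss_distance"] < 0).any():
        raise ValueError("TSS distances must be non-negative")
    targets = features[features["is_target"].astype(bool)]
    pool = features[~features["is_target"].astype(bool)]
    if targets.empty:
        raise ValueError("no target SNPs flagged")

    maf_bins_pool = bin_features(pool["maf"], n_maf_bins)
    dist_bins_pool = bin_features(pool["tss_distance"], n_dist_bins)
    maf_bins_tgt = assign_bins(targets["maf"], pool["maf"], n_maf_bins)
    dist_bins_tgt = assign_bins(targets["tss_distance"], pool["tss_distance"], n_dist_bins)

    pool_eqtl = pool["is_eqtl"].astype(bool).to_numpy()
    pool_key = maf_bins_pool * (n_dist_bins + 1) + dist_bins_pool
    tgt_key = maf_bins_tgt * (n_dist_bins + 1) + dist_bins_tgt
    need = pd.Series(tgt_key).value_counts()
    pool_by_bin = {}
    for key, count in need.items():
        members = np.flatnonzero(pool_key == key)
        if members.size < count:
            raise ValueError(
                f"bin {key} holds {members.size} pool SNPs but {count} targets; "
                "cannot match without replacement"
            )
        pool_by_bin[key] = members

    observed = int(targets["is_eqtl"].astype(bool).sum())
    rng = np.random.default_rng(seed)
    rep_counts = np.empty(n_reps, dtype=int)
    for i in range(n_reps):
        total = 0
        for key, count in need.items():
            draw = rng.choice(pool_by_bin[key], size=count, replace=False)
            total += int(pool_eqtl[draw].sum())
        rep_counts[i] = total
    empirical_p = (1 + int((rep_counts >= observed).sum())) / (n_reps + 1)
    return EnrichmentResult(
        observed_count=observed,
        expected_mean=float(rep_counts.mean()),
        empirical_p=float(empirical_p),
        n_reps=n_reps,
    )
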