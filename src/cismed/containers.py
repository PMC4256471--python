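"""Core in-memory containers shared across the pipeline.

Genotypes and expression are held as pandas DataFrames (samples in rows)
alongside per-feature metadata. All genomic coordinates are 1-based
inclusive; BED inputs are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "ExpressionMatrix",
    "AssociationRecord",
    "EqtlSignal",
    "MediationRecord",
    "ScenarioDataset",
]


def _folded_maf(mean_dosage: pd.Series) -> pd.Series:
    af = mean_dosage / 2.0
    return np.minimum(af, 1.0 - af)


@dataclass
class GenotypeMatrix:
    """Sample x variant dosage matrix with per-variant metadata.

    Parameters
    ----------
    dosages
        DataFrame of allele dosages in [0, 2] (imputed values allowed),
        samples in rows, variant ids in columns.
    variants
        DataFrame indexed by variant id with columns ``chrom`` (str),
        ``pos`` (1-based bp, int) and optionally ``maf``. A missing
        ``maf`` column is filled from the observed dosage means.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if set(self.dosages.columns) != set(self.variants.index):
            raise ValueError("variant metadata does not match dosage columns")
        self.variants = self.variants.loc[self.dosages.columns].copy()
        self.variants.index.name = "variant_id"
        self.dosages.columns.name = None
        vals = self.dosages.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        if "maf" not in self.variants.columns or self.variants["maf"].isna().any():
            maf = _folded_maf(self.dosages.mean(axis=0))
            if "maf" not in self.variants.columns:
                self.variants["maf"] = maf
            else:
                self.variants["maf"] = self.variants["maf"].fillna(maf)
        for chrom, grp in self.variants.groupby("chrom"):
            if grp["pos"].duplicated().any():
                raise ValueError(f"duplicate variant positions on {chrom}")

    @property
    def samples(self) -> pd.Index:
        return self.dosages.index

    @property
    def variant_ids(self) -> pd.Index:
        return self.dosages.columns

    def dosage(self, variant_id: str) -> np.ndarray:
        return self.dosages[variant_id].to_numpy(dtype=float)


@dataclass
class ExpressionMatrix:
    """Sample x probe expression matrix (log scale) with probe annotation.

    ``probes`` is indexed by probe id with columns ``chrom``, ``start``,
    ``end`` (1-based inclusive) and ``gene``.
    """

    values: pd.DataFrame
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        missing = self.values.columns.difference(self.probes.index)
        if len(missing):
            raise ValueError(f"probes without annotation: {list(missing)[:5]}")
        self.probes = self.probes.loc[self.values.columns].copy()
        self.probes.index.name = "probe_id"
        self.values.columns.name = None
        if (self.probes["end"] < self.probes["start"]).any():
            raise ValueError("probe end precedes start")

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.columns

    def expression(self, probe_id: str) -> np.ndarray:
        return self.values[probe_id].to_numpy(dtype=float)


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP-probe linear-regression result."""

    variant_id: str
    probe_id: str
    beta: float
    se: float
    t_stat: float
    p_value: float
    n_used: int
    scan_class: str = "cis"


@dataclass(frozen=True)
class EqtlSignal:
    """An independent eQTL signal: the lead SNP plus the region it absorbs."""

    lead_variant_id: str
    probe_id: str
    lead_p: float
    lead_beta: float
    chrom: str
    start: int
    end: int
    scan_class: str
    n_variants: int = 1


@dataclass(frozen=True)
class MediationRecord:
    """Result of one trans-signal x cis-mediator analysis.

    ``beta_unadj`` is the total effect of the SNP on the trans transcript,
    ``beta_adj`` the direct effect after adjusting for the mediator,
    ``beta1`` the mediator->trans coefficient in the adjusted model and
    ``beta2`` the SNP->mediator coefficient. ``mediation_proportion`` is
    (beta_unadj - beta_adj) / beta_unadj, NaN when beta_unadj == 0.
    """

    trans_variant_id: str
    trans_probe_id: str
    mediator_probe_id: str
    beta_unadj: float
    beta_adj: float
    beta1: float
    var1: float
    beta2: float
    var2: float
    se_pooled: float
    sobel_z: float
    sobel_p: float
    mediation_proportion: float
    ld_r2_leads: float = float("nan")


@dataclass
class ScenarioDataset:
    """One simulated replicate of a structural scenario.

    ``dosages`` maps variant labels (e.g. ``"causal"``, ``"tag"``) to
    dosage vectors. ``true_mediator`` is the latent mediator;
    ``measured_cis`` is the transcript an analyst would use (equal to the
    truth only under perfect measurement and correct selection).
    ``truth`` echoes the generating parameters.
    """

    dosages: Dict[str, np.ndarray]
    true_mediator: np.ndarray
    measured_cis: np.ndarray
    measured_trans: np.ndarray
    confounder: Optional[np.ndarray] = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.true_mediator)
        vecs = list(self.dosages.values()) + [self.measured_cis, self.measured_trans]
        if self.confounder is not None:
            vecs.append(self.confounder)
        if any(len(v) != n for v in vecs):
            raise ValueError("scenario vectors have inconsistent lengths")

    @property
    def n_samples(self) -> int:
        return len(self.true_mediator)
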