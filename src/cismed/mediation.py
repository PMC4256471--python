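"""Cis-mediation analysis of trans-eQTL signals.

For a trans signal (lead SNP, distant probe) and a candidate local
mediator transcript, three OLS fits are run with a shared covariate set:

1. trans ~ SNP + covariates             -> beta_unadj (total effect)
2. trans ~ SNP + mediator + covariates  -> beta_adj (direct effect),
   beta1 (mediator coefficient) and its variance
3. mediator ~ SNP + covariates          -> beta2 and its variance

The mediation proportion is (beta_unadj - beta_adj) / beta_unadj and the
indirect effect beta1*beta2 is tested with the Sobel statistic
z = beta1*beta2 / sqrt(beta1^2 var2 + beta2^2 var1) against a standard
normal. A signal is classified as mediated when the proportion is
positive and the Sobel P falls below the cutoff (default 1e-5).

Mediator selection mirrors eQTL practice: among cis probes within the
window around the lead trans-eSNP whose cis association passes the cis
threshold, pick the probe whose lead cis-eSNP is in strongest LD with
the lead trans-eSNP.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GenotypeMatrix, MediationRecord
from .scan import P_FLOOR, pair_distance

__all__ = [
    "sobel_test",
    "mediate_vectors",
    "mediate_single",
    "select_cis_mediator",
    "classify_mediation",
    "multi_mediator_adjust",
]


def sobel_test(
    beta1: float,
    var1: float,
    beta2: float,
    var2: float,
    aroian: bool = False,
) -> Tuple[float, float]:
    """Normal-theory test of the indirect effect beta1*beta2.

    ``var1``/``var2`` are the squared standard errors of the two
    coefficients. The pooled SE is the first-order (Sobel) form
    sqrt(beta1^2 var2 + beta2^2 var1); ``aroian=True`` adds the
    second-order var1*var2 term. Returns (z, two-sided P).
    """
    if var1 < 0 or var2 < 0:
        raise ValueError("coefficient variances must be non-negative")
    se2 = beta1**2 * var2 + beta2**2 * var1
    if aroian:
        se2 += var1 * var2
    product = beta1 * beta2
    if se2 == 0.0:
        if product == 0.0:
            return 0.0, 1.0
        raise ValueError("zero pooled SE with a nonzero indirect effect")
    z = product / np.sqrt(se2)
    p = max(2.0 * stats.norm.sf(abs(z)), P_FLOOR)
    return float(z), float(p)


def _ols(y: np.ndarray, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Coefficients and their variances for OLS with design X (incl. intercept)."""
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = n - k
    if df < 1:
        raise ValueError("not enough samples for the model")
    sigma2 = float(resid @ resid) / df
    var = sigma2 * np.diag(np.linalg.inv(X.T @ X))
    return coef, var


def mediate_vectors(
    dosage: np.ndarray,
    trans: np.ndarray,
    mediator: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    aroian: bool = False,
    trans_variant_id: str = "",
    trans_probe_id: str = "",
    mediator_probe_id: str = "",
    ld_r2_leads: float = float("nan"),
) -> MediationRecord:
    """Run the three-regression mediation procedure on raw vectors."""
    g = np.asarray(dosage, dtype=float)
    t = np.asarray(trans, dtype=float)
    m = np.asarray(mediator, dtype=float)
    n = len(g)
    if len(t) != n or len(m) != n:
        raise ValueError("vectors not sample-aligned")
    c = (
        np.empty((n, 0))
        if covariates is None
        else np.asarray(covariates, dtype=float).reshape(n, -1)
    )
    mask = (
        np.isfinite(g) & np.isfinite(t) & np.isfinite(m) & np.all(np.isfinite(c), axis=1)
    )
    g, t, m, c = g[mask], t[mask], m[mask], c[mask]
    ones = np.ones(mask.sum())

    coef_tot, _ = _ols(t, np.column_stack([ones, g, c]))
    beta_unadj = float(coef_tot[1])
    coef_adj, var_adj = _ols(t, np.column_stack([ones, g, m, c]))
    beta_adj, beta1, var1 = float(coef_adj[1]), float(coef_adj[2]), float(var_adj[2])
    coef_med, var_med = _ols(m, np.column_stack([ones, g, c]))
    beta2, var2 = float(coef_med[1]), float(var_med[1])

    z, p = sobel_test(beta1, var1, beta2, var2, aroian=aroian)
    se_pooled = abs(beta1 * beta2 / z) if z != 0 else float(
        np.sqrt(beta1**2 * var2 + beta2**2 * var1 + (var1 * var2 if aroian else 0.0))
    )
    if beta_unadj == 0.0:
        warnings.warn(
            "total effect is exactly zero; mediation proportion undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        proportion = float("nan")
    else:
        proportion = (beta_unadj - beta_adj) / beta_unadj
    return MediationRecord(
        trans_variant_id=trans_variant_id,
        trans_probe_id=trans_probe_id,
        mediator_probe_id=mediator_probe_id,
        beta_unadj=beta_unadj,
        beta_adj=beta_adj,
        beta1=beta1,
        var1=var1,
        beta2=beta2,
        var2=var2,
        se_pooled=float(se_pooled),
        sobel_z=z,
        sobel_p=p,
        mediation_proportion=float(proportion),
        ld_r2_leads=ld_r2_leads,
    )


def mediate_single(
    trans_signal: pd.Series,
    mediator_probe_id: str,
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    covariates: Optional[pd.DataFrame] = None,
    ld_r2_leads: float = float("nan"),
    aroian: bool = False,
) -> MediationRecord:
    """Mediation analysis of one trans signal with a chosen cis mediator.

    ``trans_signal`` is a row from :func:`cismed.scan.select_lead_signals`
    (needs ``lead_variant_id`` and ``probe_id``).
    """
    g = geno.dosage(trans_signal["lead_variant_id"])
    t = expr.expression(trans_signal["probe_id"])
    m = expr.expression(mediator_probe_id)
    c = None if covariates is None else covariates.to_numpy(dtype=float)
    return mediate_vectors(
        g,
        t,
        m,
        c,
        aroian=aroian,
        trans_variant_id=trans_signal["lead_variant_id"],
        trans_probe_id=trans_signal["probe_id"],
        mediator_probe_id=mediator_probe_id,
        ld_r2_leads=ld_r2_leads,
    )


def select_cis_mediator(
    trans_signal: pd.Series,
    cis_signals: pd.DataFrame,
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    window_bp: int = 1_000_000,
    cis_p_cut: float = 1.0,
) -> Optional[Tuple[str, float]]:
    """Pick the candidate cis mediator for a trans signal.

    ``cis_signals`` carries one row per cis signal with the per-probe
    lead cis-eSNP (output of ``select_lead_signals`` on the cis scan).
    Candidates are probes within ``window_bp`` of the lead trans-eSNP
    with lead cis P below ``cis_p_cut``; among them the probe whose lead
    cis-eSNP has the highest LD r2 with the lead trans-eSNP wins.
    Returns (probe_id, ld_r2) or ``None`` when nothing qualifies.
    """
    from .scan import compute_ld_r2

    lead_snp = trans_signal["lead_variant_id"]
    snp_chrom = geno.variants.loc[lead_snp, "chrom"]
    snp_pos = int(geno.variants.loc[lead_snp, "pos"])
    g_trans = geno.dosage(lead_snp)
    best: Optional[Tuple[str, float]] = None
    for _, row in cis_signals.iterrows():
        if row["lead_p"] >= cis_p_cut:
            continue
        probe = row["probe_id"]
        ann = expr.probes.loc[probe]
        if ann["chrom"] != snp_chrom:
            continue
        if pair_distance(snp_pos, int(ann["start"]), int(ann["end"])) >= window_bp:
            continue
        r2 = compute_ld_r2(g_trans, geno.dosage(row["lead_variant_id"]))
        if best is None or r2 > best[1]:
            best = (probe, r2)
    return best


def classify_mediation(record: MediationRecord, p_cut: float = 1e-5) -> str:
    """Table-style call: 'mediated' iff proportion > 0 and Sobel P < p_cut."""
    if (
        np.isfinite(record.mediation_proportion)
        and record.mediation_proportion > 0
        and record.sobel_p < p_cut
    ):
        return "mediated"
    return "not_mediated"


def multi_mediator_adjust(
    trans_signal: pd.Series,
    candidate_probes: Sequence[str],
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    covariates: Optional[pd.DataFrame] = None,
) -> Tuple[float, pd.DataFrame]:
    """Jointly adjust a trans association for several cis transcripts.

    Fits trans ~ SNP + all candidates + covariates in a single
    regression; collinear candidate probes are pruned greedily (kept
    probes logged in the returned table). Returns the adjusted SNP
    coefficient and a per-probe coefficient table.
    """
    if len(candidate_probes) == 0:
        raise ValueError("candidate mediator set is empty")
    g = geno.dosage(trans_signal["lead_variant_id"])
    t = expr.expression(trans_signal["probe_id"])
    n = len(g)
    c = np.empty((n, 0)) if covariates is None else covariates.to_numpy(dtype=float)
    base = np.column_stack([np.ones(n), g, c])
    kept: list = []
    X = base
    for probe in candidate_probes:
        cand = np.column_stack([X, expr.expression(probe)])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            X = cand
            kept.append(probe)
    if not kept:
        raise ValueError("all candidate mediators collinear with the base design")
    coef, var = _ols(t, X)
    first = base.shape[1]  # probe columns sit after [1, g, covariates]
    table = pd.DataFrame(
        {
            "probe_id": kept,
            "beta": coef[first : first + len(kept)],
            "se": np.sqrt(var[first : first + len(kept)]),
        }
    )
    return float(coef[1]), table
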