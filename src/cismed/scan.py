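"""Genome-wide cis/trans eQTL scanning by per-pair linear regression.

Each SNP-probe pair is tested by ordinary least squares of expression on
dosage plus an intercept and shared covariates. For speed the scan
residualizes both expression and dosage against the covariates once and
regresses residuals pair-by-pair; by the Frisch-Waugh-Lovell theorem the
slope, standard error and t statistic are identical to the full model,
with degrees of freedom n - k - 2 (k covariates).

Cis pairs are SNP/probe on the same chromosome less than ``window_bp``
apart (distance measured from the SNP to the nearest probe coordinate,
zero if the SNP lies inside the probe). Trans pairs are
inter-chromosomal, or intra-chromosomal more than ``min_dist_bp`` apart.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AssociationRecord, EqtlSignal, ExpressionMatrix, GenotypeMatrix

__all__ = [
    "fit_marginal_association",
    "scan_cis",
    "scan_trans",
    "bh_threshold",
    "select_lead_signals",
    "compute_ld_r2",
    "filter_covariates_by_genotype",
    "pair_distance",
]

P_FLOOR = np.nextafter(0.0, 1.0)  # underflowed P-values are reported as <= this

ASSOC_COLUMNS = [
    "variant_id",
    "probe_id",
    "beta",
    "se",
    "t_stat",
    "p_value",
    "n_used",
    "scan_class",
]


def _covariate_array(
    covariates: Optional[pd.DataFrame], n: int
) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] != n:
        raise ValueError("covariates not sample-aligned")
    return arr


def fit_marginal_association(
    dosage: np.ndarray,
    expression: np.ndarray,
    covariates: Optional[pd.DataFrame] = None,
    variant_id: str = "",
    probe_id: str = "",
    scan_class: str = "cis",
) -> AssociationRecord:
    """OLS of expression on dosage + intercept + covariates.

    Missing values are handled by complete-case analysis. The two-sided
    P-value comes from the t distribution with n - k - 2 degrees of
    freedom (k covariates); underflow is floored at the smallest positive
    float and reported as an upper bound.
    """
    g = np.asarray(dosage, dtype=float)
    y = np.asarray(expression, dtype=float)
    if g.shape != y.shape:
        raise ValueError("dosage and expression lengths differ")
    c = _covariate_array(covariates, len(g))
    mask = np.isfinite(g) & np.isfinite(y) & np.all(np.isfinite(c), axis=1)
    g, y, c = g[mask], y[mask], c[mask]
    k = c.shape[1]
    n = len(g)
    if n < k + 3:
        raise ValueError(f"only {n} complete cases for {k} covariates; need >= {k + 3}")
    x = np.column_stack([np.ones(n), g, c])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is rank deficient")
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    df = n - k - 2
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(x.T @ x)
    se = float(np.sqrt(max(sigma2 * xtx_inv[1, 1], 0.0)))
    beta = float(coef[1])
    if se == 0.0:
        t_stat = np.inf * np.sign(beta) if beta != 0 else 0.0
    else:
        t_stat = beta / se
    p = max(2.0 * stats.t.sf(abs(t_stat), df), P_FLOOR)
    return AssociationRecord(
        variant_id=variant_id,
        probe_id=probe_id,
        beta=beta,
        se=se,
        t_stat=float(t_stat),
        p_value=float(p),
        n_used=n,
        scan_class=scan_class,
    )


def pair_distance(pos: int, start: int, end: int) -> int:
    """SNP-to-probe distance: 0 inside the probe, else bp to the nearest end."""
    if start <= pos <= end:
        return 0
    return min(abs(pos - start), abs(pos - end))


def _residualize(y: np.ndarray, covariates: Optional[pd.DataFrame]) -> Tuple[np.ndarray, int]:
    """Residualize columns of y against [1, covariates]; returns (resid, k)."""
    n = y.shape[0]
    c = _covariate_array(covariates, n)
    x = np.column_stack([np.ones(n), c])
    q, r = np.linalg.qr(x)
    if np.abs(np.diag(r)).min() < 1e-10 * np.abs(np.diag(r)).max():
        raise ValueError("covariate matrix is rank deficient after adding intercept")
    return y - q @ (q.T @ y), c.shape[1]


def _scan_pairs(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    pairs: List[Tuple[str, str]],
    covariates: Optional[pd.DataFrame],
    scan_class: str,
) -> pd.DataFrame:
    if not pairs:
        return pd.DataFrame(columns=ASSOC_COLUMNS)
    G = geno.dosages.to_numpy(dtype=float)
    Y = expr.values.to_numpy(dtype=float)
    has_missing = not (np.all(np.isfinite(G)) and np.all(np.isfinite(Y)))
    if has_missing:
        # complete-case per pair; slower, semantics identical
        records = [
            fit_marginal_association(
                geno.dosage(v), expr.expression(p), covariates, v, p, scan_class
            )
            for v, p in pairs
        ]
        return pd.DataFrame([r.__dict__ for r in records], columns=ASSOC_COLUMNS)

    n = G.shape[0]
    Gr, k = _residualize(G, covariates)
    Yr, _ = _residualize(Y, covariates)
    vidx = {v: i for i, v in enumerate(geno.variant_ids)}
    pidx = {p: i for i, p in enumerate(expr.probe_ids)}
    df = n - k - 2
    if df < 1:
        raise ValueError("not enough samples for the covariate count")
    vi = np.array([vidx[v] for v, _ in pairs])
    pi = np.array([pidx[p] for _, p in pairs])
    sxx = np.einsum("ij,ij->j", Gr, Gr)[vi]
    syy = np.einsum("ij,ij->j", Yr, Yr)[pi]
    sxy = np.einsum("ij,ij->i", Gr[:, vi].T, Yr[:, pi].T)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        sse = np.maximum(syy - beta * sxy, 0.0)
        se = np.sqrt(sse / df / sxx)
        t = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf * np.sign(beta)))
    bad = sxx <= 0
    if bad.any():
        names = [pairs[i][0] for i in np.flatnonzero(bad)[:3]]
        raise ValueError(f"constant dosage after covariate adjustment: {names}")
    p = np.maximum(2.0 * stats.t.sf(np.abs(t), df), P_FLOOR)
    return pd.DataFrame(
        {
            "variant_id": [v for v, _ in pairs],
            "probe_id": [q for _, q in pairs],
            "beta": beta,
            "se": se,
            "t_stat": t,
            "p_value": p,
            "n_used": n,
            "scan_class": scan_class,
        },
        columns=ASSOC_COLUMNS,
    )


def _enumerate_pairs(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    cis: bool,
    window_bp: int,
    min_dist_bp: int,
) -> List[Tuple[str, str]]:
    pairs = []
    probes = expr.probes
    for v, vrow in geno.variants.iterrows():
        for p, prow in probes.iterrows():
            same = vrow["chrom"] == prow["chrom"]
            if same:
                d = pair_distance(int(vrow["pos"]), int(prow["start"]), int(prow["end"]))
            if cis:
                if same and d < window_bp:
                    pairs.append((v, p))
            else:
                if (not same) or d > min_dist_bp:
                    pairs.append((v, p))
    return pairs


def scan_cis(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    covariates: Optional[pd.DataFrame] = None,
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Test every SNP-probe pair on the same chromosome < window_bp apart."""
    if expr.probes[["chrom", "start", "end"]].isna().any().any():
        raise ValueError("probe annotation incomplete")
    pairs = _enumerate_pairs(geno, expr, True, window_bp, 0)
    return _scan_pairs(geno, expr, pairs, covariates, "cis")


def scan_trans(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    covariates: Optional[pd.DataFrame] = None,
    min_dist_bp: int = 10_000_000,
) -> pd.DataFrame:
    """Test inter-chromosomal pairs and same-chromosome pairs > min_dist_bp."""
    if expr.probes[["chrom", "start", "end"]].isna().any().any():
        raise ValueError("probe annotation incomplete")
    pairs = _enumerate_pairs(geno, expr, False, 0, min_dist_bp)
    return _scan_pairs(geno, expr, pairs, covariates, "trans")


def bh_threshold(p_values: Sequence[float], fdr: float = 0.05) -> Optional[float]:
    """Benjamini-Hochberg step-up P-value cutoff at the given FDR.

    Returns the largest p_(k) with p_(k) <= k * fdr / m, or ``None`` when
    nothing is discovered.
    """
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    p = np.sort(p)
    m = p.size
    crit = fdr * np.arange(1, m + 1) / m
    ok = np.flatnonzero(p <= crit)
    if ok.size == 0:
        return None
    return float(p[ok[-1]])


def compute_ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("cannot compute LD with a constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def select_lead_signals(
    records: pd.DataFrame,
    variant_meta: pd.DataFrame,
    independence_bp: int = 5_000_000,
) -> pd.DataFrame:
    """Greedy per-probe clumping of significant records into signals.

    Per probe: seed a signal at the smallest-P record (ties broken by
    largest |beta| then smallest position), absorb records within
    ``independence_bp`` on the same chromosome, repeat on the remainder.
    Signals for the same probe are therefore > independence_bp apart or
    on different chromosomes.
    """
    cols = [
        "lead_variant_id",
        "probe_id",
        "lead_p",
        "lead_beta",
        "chrom",
        "start",
        "end",
        "scan_class",
        "n_variants",
    ]
    if records.empty:
        return pd.DataFrame(columns=cols)
    rec = records.merge(
        variant_meta[["chrom", "pos"]], left_on="variant_id", right_index=True
    )
    signals = []
    for probe_id, grp in rec.groupby("probe_id", sort=True):
        grp = grp.assign(_absbeta=grp["beta"].abs()).sort_values(
            ["p_value", "_absbeta", "pos"], ascending=[True, False, True], kind="mergesort"
        )
        remaining = grp
        while len(remaining):
            lead = remaining.iloc[0]
            near = (remaining["chrom"] == lead["chrom"]) & (
                (remaining["pos"] - lead["pos"]).abs() <= independence_bp
            )
            cluster = remaining[near]
            signals.append(
                EqtlSignal(
                    lead_variant_id=lead["variant_id"],
                    probe_id=probe_id,
                    lead_p=float(lead["p_value"]),
                    lead_beta=float(lead["beta"]),
                    chrom=lead["chrom"],
                    start=int(cluster["pos"].min()),
                    end=int(cluster["pos"].max()),
                    scan_class=lead["scan_class"],
                    n_variants=int(len(cluster)),
                )
            )
            remaining = remaining[~near]
    out = pd.DataFrame([s.__dict__ for s in signals], columns=cols)
    return out.sort_values(["probe_id", "lead_p"], kind="mergesort").reset_index(drop=True)


def filter_covariates_by_genotype(
    covariates: pd.DataFrame,
    geno: GenotypeMatrix,
    p_cut: float = 5e-8,
) -> pd.DataFrame:
    """Drop covariates associated with any SNP at P < p_cut.

    Used to keep genetically driven components (e.g. expression PCs that
    tag an eQTL) out of the trans-scan covariate set, which would
    otherwise absorb real signals.
    """
    if covariates.shape[1] == 0:
        return covariates.copy()
    if covariates.shape[0] != geno.dosages.shape[0]:
        raise ValueError("covariates not sample-aligned with genotypes")
    G = geno.dosages.to_numpy(dtype=float)
    C = covariates.to_numpy(dtype=float)
    n = G.shape[0]
    Gs = (G - G.mean(0)) / np.where(G.std(0) > 0, G.std(0), np.inf)
    Cs = (C - C.mean(0)) / np.where(C.std(0) > 0, C.std(0), np.inf)
    r = (Gs.T @ Cs) / n  # variants x covariates correlation
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    keep = p.min(axis=0) >= p_cut
    return covariates.loc[:, keep].copy()
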