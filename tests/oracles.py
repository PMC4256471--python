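"""Independent oracles used by the test suite.

Everything here is deliberately naive — explicit normal-equation solves,
nested-loop enumeration, closed-form covariance algebra — and never
calls into the code paths it is used to check.
"""

import numpy as np
from scipy import stats


def ols_oracle(y, X):
    """Explicit (X'X)^-1 X'y solve with coefficient variances and t/P."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / df
    var = sigma2 * np.diag(xtx_inv)
    se = np.sqrt(var)
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p, var


def enumerate_cis_pairs(variants, probes, window_bp):
    """Nested-loop enumeration of the cis distance rule."""
    pairs = set()
    for v, vrow in variants.iterrows():
        for q, prow in probes.iterrows():
            if vrow["chrom"] != prow["chrom"]:
                continue
            if prow["start"] <= vrow["pos"] <= prow["end"]:
                d = 0
            else:
                d = min(abs(vrow["pos"] - prow["start"]), abs(vrow["pos"] - prow["end"]))
            if d < window_bp:
                pairs.add((v, q))
    return pairs


def enumerate_trans_pairs(variants, probes, min_dist_bp):
    pairs = set()
    for v, vrow in variants.iterrows():
        for q, prow in probes.iterrows():
            if vrow["chrom"] != prow["chrom"]:
                pairs.add((v, q))
                continue
            if prow["start"] <= vrow["pos"] <= prow["end"]:
                d = 0
            else:
                d = min(abs(vrow["pos"] - prow["start"]), abs(vrow["pos"] - prow["end"]))
            if d > min_dist_bp:
                pairs.add((v, q))
    return pairs


def bh_cutoff_oracle(pvals, fdr):
    """Brute-force BH over the sorted list."""
    p = sorted(pvals)
    m = len(p)
    best = None
    for k, pk in enumerate(p, start=1):
        if pk <= k * fdr / m:
            best = pk
    return best


def cluster_signals_oracle(rows, independence_bp):
    """Greedy clumping on (p, |beta|, pos)-ordered records for one probe.

    rows: list of dicts with variant_id, p_value, beta, chrom, pos.
    Returns list of (lead_variant_id, member_variant_ids).
    """
    remaining = sorted(
        rows, key=lambda r: (r["p_value"], -abs(r["beta"]), r["pos"])
    )
    out = []
    while remaining:
        lead = remaining[0]
        members = [
            r
            for r in remaining
            if r["chrom"] == lead["chrom"]
            and abs(r["pos"] - lead["pos"]) <= independence_bp
        ]
        out.append((lead["variant_id"], {m["variant_id"] for m in members}))
        remaining = [r for r in remaining if r not in members]
    return out


def sobel_oracle(beta1, se1, beta2, se2):
    """Direct evaluation of the pooled-SE formula + high-precision normal CDF."""
    import mpmath

    se = (beta1**2 * se2**2 + beta2**2 * se1**2) ** 0.5
    z = beta1 * beta2 / se
    p = float(2 * (1 - mpmath.ncdf(abs(z))))
    return se, z, p


def fisher_two_sided_oracle(a, b, c, d):
    """Exact two-sided hypergeometric P by full enumeration of tables."""
    from math import comb

    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return comb(col1, x) * comb(n - col1, row1 - x) / comb(n, row1)

    p_obs = prob(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def confounding_population_mediation(
    r2_cis, beta_ct, beta_u_cis, beta_u_trans, maf, allele_sign=+1
):
    """Population mediation proportion under the confounded complete-mediation
    model, from the structural covariances (collider-adjustment algebra).

    ``allele_sign`` is the sign of the SNP -> cis effect (the counted
    allele increases the cis transcript when +1)."""
    var_g = 2 * maf * (1 - maf)
    b = allele_sign * np.sqrt(r2_cis / var_g)
    cov_gm = b * var_g
    cov_tm = beta_ct + beta_u_trans * beta_u_cis  # var(M)=1
    cov_tg = beta_ct * cov_gm
    beta_unadj = cov_tg / var_g
    denom = var_g * 1.0 - cov_gm**2
    beta_adj = (cov_tg * 1.0 - cov_tm * cov_gm) / denom
    return (beta_unadj - beta_adj) / beta_unadj


def wrong_mediator_gene_correlation(scenario, ld_r2, r2_cis, confounder_effects,
                                    cross_effect, cross_direction="m_to_s"):
    """Population corr(gene_s, gene_m) by path-analysis covariance algebra.

    Both transcripts have unit variance by construction; the LD path
    contributes r2_cis * r (r the signed dosage correlation).
    """
    r = np.sqrt(ld_r2)
    cov = r2_cis * r
    if scenario == "confounded_mediators":
        cov += confounder_effects[0] * confounder_effects[1]
    elif scenario == "causal_between_mediators":
        # gene_s = b*Gs + k*gene_m + e (or the symmetric reverse):
        # cov gains k * var(gene_x) = k on top of the LD path.
        cov += cross_effect
    return cov
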