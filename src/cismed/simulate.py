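"""Structural simulators for eQTL mediation analysis.

Three scenario families probe distinct threats to cis-mediation
inference:

* **measurement error** — a causal variant drives a latent cis
  transcript which drives a trans transcript; the analyst observes a
  noisy measure of the mediator and may analyse a tag variant in
  imperfect LD with the causal one. Attenuation of both the mediation
  proportion and the Sobel statistic follows.
* **cis/trans confounding** — an unobserved variable U affects both the
  mediator and the trans transcript. Adjusting for the mediator (a
  collider on the path SNP -> cis <- U -> trans) biases the direct
  effect, so the estimated proportion over- or under-shoots 1 depending
  on sign(beta_u_cis * beta_u_trans).
* **wrong mediator** — the transcript selected for mediation is not the
  true mediator but a neighbour driven by a variant in LD with the
  causal one, optionally correlated with the true mediator through a
  shared confounder or a direct transcript-transcript effect.

All transcripts are marginally standard normal: each structural term is
added and the residual noise variance chosen so the total is 1, so
effect sizes read as SD units. Genotypes are drawn as two independent
haplotypes under Hardy-Weinberg equilibrium; pairwise LD is controlled
through the two-locus haplotype distribution.

A fourth generator, :func:`simulate_study`, plants a full multi-gene
study (cis-eQTLs, mediated and direct trans-eQTLs) with a truth table,
giving the scan/mediation pipeline an end-to-end fixture.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GenotypeMatrix, ScenarioDataset

__all__ = [
    "InfeasibleLDError",
    "LDPairSpec",
    "VariantSpec",
    "MeasurementErrorConfig",
    "ConfoundingConfig",
    "WrongMediatorConfig",
    "CisEffect",
    "TransEffect",
    "StudyConfig",
    "StudyDataset",
    "max_feasible_r2",
    "haplotype_frequencies",
    "simulate_genotype_pair",
    "simulate_measurement_error_dataset",
    "simulate_confounding_dataset",
    "simulate_wrong_mediator_dataset",
    "simulate_study",
]

WRONG_MEDIATOR_SCENARIOS = (
    "ld_only",
    "confounded_mediators",
    "causal_between_mediators",
    "cis_trans_confounded",
)


class InfeasibleLDError(ValueError):
    """Requested LD r2 exceeds the maximum attainable for the given MAFs."""


@dataclass(frozen=True)
class VariantSpec:
    id: str
    chrom: str
    pos: int
    maf: float

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")


@dataclass(frozen=True)
class LDPairSpec:
    """Target squared correlation between two dosage vectors.

    ``d_sign`` is the sign of the disequilibrium coefficient D between
    the two minor alleles (+1: minor alleles co-occur on haplotypes).
    """

    target_r2: float
    d_sign: int = +1

    def __post_init__(self) -> None:
        if not 0 <= self.target_r2 <= 1:
            raise ValueError("target_r2 must be in [0, 1]")
        if self.d_sign not in (+1, -1):
            raise ValueError("d_sign must be +1 or -1")


def _check_maf(maf: float, label: str = "maf") -> None:
    if not 0 < maf <= 0.5:
        raise ValueError(f"{label} must be in (0, 0.5], got {maf}")


def max_feasible_r2(maf_a: float, maf_b: float, d_sign: int = +1) -> float:
    """Largest LD r2 attainable between two loci with the given MAFs.

    With minor-allele frequencies ``p_a``, ``p_b`` the disequilibrium
    coefficient D is bounded by the haplotype-frequency constraints;
    r2 = D^2 / (p_a q_a p_b q_b) inherits the bound.
    """
    _check_maf(maf_a, "maf_a")
    _check_maf(maf_b, "maf_b")
    pa, qa, pb, qb = maf_a, 1 - maf_a, maf_b, 1 - maf_b
    if d_sign > 0:
        d_max = min(pa * qb, qa * pb)
    else:
        d_max = min(pa * pb, qa * qb)
    return d_max**2 / (pa * qa * pb * qb)


def haplotype_frequencies(
    maf_a: float, maf_b: float, ld: LDPairSpec
) -> np.ndarray:
    """Two-locus haplotype frequencies [AB, Ab, aB, ab] (A, B minor).

    D = d_sign * sqrt(r2 * p_a q_a p_b q_b). Raises
    :class:`InfeasibleLDError` when the implied frequencies leave [0, 1].
    """
    _check_maf(maf_a, "maf_a")
    _check_maf(maf_b, "maf_b")
    pa, qa, pb, qb = maf_a, 1 - maf_a, maf_b, 1 - maf_b
    r2max = max_feasible_r2(maf_a, maf_b, ld.d_sign)
    if ld.target_r2 > r2max + 1e-12:
        raise InfeasibleLDError(
            f"target r2={ld.target_r2:g} infeasible for MAFs "
            f"({maf_a:g}, {maf_b:g}) with d_sign={ld.d_sign:+d}; "
            f"maximum attainable r2 is {r2max:.6g}"
        )
    d = ld.d_sign * np.sqrt(ld.target_r2 * pa * qa * pb * qb)
    freqs = np.array([pa * pb + d, pa * qb - d, qa * pb - d, qa * qb + d])
    freqs = np.clip(freqs, 0.0, 1.0)
    return freqs / freqs.sum()


def _as_rng(seed: Union[int, Sequence[int], np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_genotype_pair(
    n_samples: int,
    maf_a: float,
    maf_b: float,
    ld: LDPairSpec,
    seed: Union[int, Sequence[int], np.random.Generator, None] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw dosages at two biallelic loci with a target pairwise LD r2.

    Each individual receives two haplotypes sampled from the two-locus
    haplotype distribution; dosages count minor alleles (0/1/2). The
    empirical squared dosage correlation converges to ``ld.target_r2``.
    """
    rng = _as_rng(seed)
    freqs = haplotype_frequencies(maf_a, maf_b, ld)
    # haplotype index 0=AB 1=Ab 2=aB 3=ab; two draws per individual
    hap = rng.choice(4, size=(n_samples, 2), p=freqs)
    carries_a = (hap <= 1).sum(axis=1)  # haplotypes 0,1 carry minor A
    carries_b = ((hap == 0) | (hap == 2)).sum(axis=1)
    return carries_a.astype(float), carries_b.astype(float)


def _dosage_single(n: int, maf: float, rng: np.random.Generator) -> np.ndarray:
    return rng.binomial(2, maf, size=n).astype(float)


def _centered(g: np.ndarray, maf: float) -> np.ndarray:
    return g - 2.0 * maf


# ---------------------------------------------------------------------------
# scenario configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeasurementErrorConfig:
    """Mediation chain with mediator measurement error and a tag variant.

    The latent mediator M satisfies var explained by the causal variant
    = ``r2_cis``; the trans transcript T = beta_cis_trans * M + noise,
    both marginally N(0, 1). The measured mediator has squared
    correlation ``r2_measure`` with M (``r2_measure_trans`` analogously
    for T, default noise-free). ``tag_ld_r2`` is the LD r2 of the
    analysed variant with the causal one.
    """

    n_samples: int = 1799
    causal_maf: float = 0.3
    r2_cis: float = 0.1
    beta_cis_trans: float = 0.2
    r2_measure: float = 1.0
    tag_ld_r2: float = 1.0
    r2_measure_trans: float = 1.0
    d_sign: int = +1
    n_reps: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("r2_cis", "r2_measure", "tag_ld_r2", "r2_measure_trans"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.r2_measure == 0 or self.r2_measure_trans == 0:
            raise ValueError("r2_measure of 0 implies infinite noise variance")
        _check_maf(self.causal_maf, "causal_maf")
        if abs(self.beta_cis_trans) > 1:
            raise ValueError("beta_cis_trans is in SD units; |beta| must be <= 1")


@dataclass(frozen=True)
class ConfoundingConfig:
    """Complete mediation plus an unobserved confounder U of cis and trans.

    U ~ N(0,1) loads on the mediator with ``beta_u_cis`` and on the
    trans transcript with ``beta_u_trans``; the magnitudes must match
    (only the signs vary across the published grid). The SNP is coded so
    the counted allele increases the cis transcript unless
    ``allele_coding="cis-decreasing"``.
    """

    n_samples: int = 1799
    causal_maf: float = 0.3
    r2_cis: float = 0.1
    beta_cis_trans: float = 0.2
    beta_u_cis: float = 0.0
    beta_u_trans: float = 0.0
    allele_coding: str = "cis-increasing"
    n_reps: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        _check_maf(self.causal_maf, "causal_maf")
        if not 0 <= self.r2_cis <= 1:
            raise ValueError("r2_cis must be in [0, 1]")
        if abs(abs(self.beta_u_cis) - abs(self.beta_u_trans)) > 1e-12:
            raise ValueError("|beta_u_trans| must equal |beta_u_cis|")
        if self.allele_coding not in ("cis-increasing", "cis-decreasing"):
            raise ValueError("allele_coding must be cis-increasing or cis-decreasing")
        if self.r2_cis + self.beta_u_cis**2 > 1:
            raise ValueError("r2_cis + beta_u_cis^2 exceeds unit variance")


@dataclass(frozen=True)
class WrongMediatorConfig:
    """Mediation analysed with a neighbouring transcript, not the mediator.

    Two causal variants in LD ``ld_r2_causal_pair`` drive the true
    mediator (gene_m) and the selected transcript (gene_s). The scenario
    adds one extra dependency:

    * ``ld_only`` — none; any gene_s/gene_m correlation is via LD.
    * ``confounded_mediators`` — U loads on gene_m and gene_s with the
      signed ``confounder_effects`` pair.
    * ``causal_between_mediators`` — signed ``cross_effect`` from gene_m
      to gene_s (``cross_direction="m_to_s"``) or the reverse.
    * ``cis_trans_confounded`` — U loads on gene_s and on the trans
      transcript (``confounder_effects`` = (on gene_s, on trans)).
    """

    scenario: str = "ld_only"
    ld_r2_causal_pair: float = 0.9
    confounder_effects: Tuple[float, float] = (0.5, 0.5)
    cross_effect: float = 0.25
    cross_direction: str = "m_to_s"
    n_samples: int = 1799
    causal_maf: float = 0.3
    r2_cis: float = 0.1
    beta_cis_trans: float = 0.2
    d_sign: int = +1
    n_reps: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in WRONG_MEDIATOR_SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; "
                f"expected one of {WRONG_MEDIATOR_SCENARIOS}"
            )
        if not 0 <= self.ld_r2_causal_pair <= 1:
            raise ValueError("ld_r2_causal_pair must be in [0, 1]")
        if self.cross_direction not in ("m_to_s", "s_to_m"):
            raise ValueError("cross_direction must be m_to_s or s_to_m")
        _check_maf(self.causal_maf, "causal_maf")


def _rep_rng(seed: int, rep_index: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % 2**31, int(rep_index) % 2**31])


def _noise_sd(explained_var: float, context: str) -> float:
    resid = 1.0 - explained_var
    if resid < -1e-9:
        raise ValueError(
            f"structural terms explain variance {explained_var:.4f} > 1 in {context}"
        )
    return float(np.sqrt(max(resid, 0.0)))


def simulate_measurement_error_dataset(
    config: MeasurementErrorConfig, rep_index: int = 0
) -> ScenarioDataset:
    """One replicate of the measurement-error scenario.

    Emits the causal and tag dosage vectors, the latent mediator, and
    the measured cis/trans transcripts. With ``r2_measure == 1`` the
    measured mediator equals the latent one exactly.
    """
    rng = _rep_rng(config.seed, rep_index)
    p = config.causal_maf
    g_causal, g_tag = simulate_genotype_pair(
        config.n_samples,
        p,
        p,
        LDPairSpec(config.tag_ld_r2, config.d_sign),
        rng,
    )
    var_g = 2 * p * (1 - p)
    b = np.sqrt(config.r2_cis / var_g)
    mediator = b * _centered(g_causal, p) + rng.normal(
        0.0, _noise_sd(config.r2_cis, "cis transcript"), config.n_samples
    )
    trans = config.beta_cis_trans * mediator + rng.normal(
        0.0, _noise_sd(config.beta_cis_trans**2, "trans transcript"), config.n_samples
    )
    measured_cis = _add_measurement_noise(mediator, config.r2_measure, rng)
    measured_trans = _add_measurement_noise(trans, config.r2_measure_trans, rng)
    return ScenarioDataset(
        dosages={"causal": g_causal, "tag": g_tag},
        true_mediator=mediator,
        measured_cis=measured_cis,
        measured_trans=measured_trans,
        confounder=None,
        truth={**asdict(config), "rep_index": rep_index, "scenario": "measurement_error"},
    )


def _add_measurement_noise(
    x: np.ndarray, r2_measure: float, rng: np.random.Generator
) -> np.ndarray:
    """Additive Gaussian error calibrated so corr(x, x+e)^2 = r2_measure."""
    if r2_measure >= 1.0:
        return x.copy()
    noise_var = np.var(x, ddof=0) * (1.0 - r2_measure) / r2_measure
    return x + rng.normal(0.0, np.sqrt(noise_var), x.shape)


def simulate_confounding_dataset(
    config: ConfoundingConfig, rep_index: int = 0
) -> ScenarioDataset:
    """One replicate with an unobserved cis/trans confounder U.

    The generating model is complete mediation (no direct SNP->trans
    path); any departure of the estimated proportion from 1 downstream
    is collider bias from adjusting for the confounded mediator.
    """
    rng = _rep_rng(config.seed, rep_index)
    p = config.causal_maf
    g = _dosage_single(config.n_samples, p, rng)
    u = rng.standard_normal(config.n_samples)
    var_g = 2 * p * (1 - p)
    b = np.sqrt(config.r2_cis / var_g)
    if config.allele_coding == "cis-decreasing":
        b = -b
    cis = (
        b * _centered(g, p)
        + config.beta_u_cis * u
        + rng.normal(
            0.0,
            _noise_sd(config.r2_cis + config.beta_u_cis**2, "cis transcript"),
            config.n_samples,
        )
    )
    bct, but = config.beta_cis_trans, config.beta_u_trans
    # var(bct*cis + but*U) with cov(cis, U) = beta_u_cis
    struct_var = bct**2 + but**2 + 2 * bct * but * config.beta_u_cis
    trans = (
        bct * cis
        + but * u
        + rng.normal(0.0, _noise_sd(struct_var, "trans transcript"), config.n_samples)
    )
    return ScenarioDataset(
        dosages={"causal": g},
        true_mediator=cis,
        measured_cis=cis.copy(),
        measured_trans=trans,
        confounder=u,
        truth={**asdict(config), "rep_index": rep_index, "scenario": "confounding"},
    )


def simulate_wrong_mediator_dataset(
    config: WrongMediatorConfig, rep_index: int = 0
) -> ScenarioDataset:
    """One replicate of a wrong-mediator scenario.

    ``measured_cis`` holds the *selected* transcript (gene_s) — the one
    the analyst would wrongly use — while ``true_mediator`` holds gene_m.
    The trans transcript depends on gene_m only (plus U in the
    ``cis_trans_confounded`` scenario).
    """
    rng = _rep_rng(config.seed, rep_index)
    p = config.causal_maf
    n = config.n_samples
    g_m, g_s = simulate_genotype_pair(
        n, p, p, LDPairSpec(config.ld_r2_causal_pair, config.d_sign), rng
    )
    var_g = 2 * p * (1 - p)
    b = np.sqrt(config.r2_cis / var_g)
    r_g = config.d_sign * np.sqrt(config.ld_r2_causal_pair)  # dosage correlation
    u = rng.standard_normal(n)
    c_m = c_s = c_t = 0.0
    if config.scenario == "confounded_mediators":
        c_m, c_s = config.confounder_effects
    elif config.scenario == "cis_trans_confounded":
        c_s, c_t = config.confounder_effects

    gene_m = (
        b * _centered(g_m, p)
        + c_m * u
        + rng.normal(0.0, _noise_sd(config.r2_cis + c_m**2, "gene_m"), n)
    )
    if config.scenario == "causal_between_mediators" and config.cross_direction == "s_to_m":
        # build gene_s first, then let it feed gene_m
        gene_s = b * _centered(g_s, p) + rng.normal(
            0.0, _noise_sd(config.r2_cis, "gene_s"), n
        )
        k = config.cross_effect
        # var(b*Gm~ + k*gene_s): cov(Gm, gene_s) = b * r_g * var_g
        struct = config.r2_cis + k**2 + 2 * k * b * (b * r_g * var_g)
        gene_m = (
            b * _centered(g_m, p)
            + k * gene_s
            + rng.normal(0.0, _noise_sd(struct, "gene_m"), n)
        )
    elif config.scenario == "causal_between_mediators":
        k = config.cross_effect
        struct = config.r2_cis + k**2 + 2 * k * b * (b * r_g * var_g)
        gene_s = (
            b * _centered(g_s, p)
            + k * gene_m
            + rng.normal(0.0, _noise_sd(struct, "gene_s"), n)
        )
    else:
        gene_s = (
            b * _centered(g_s, p)
            + c_s * u
            + rng.normal(0.0, _noise_sd(config.r2_cis + c_s**2, "gene_s"), n)
        )

    bct = config.beta_cis_trans
    # gene_m carries no U loading in the only scenario with c_t != 0, so the
    # structural variance of the trans transcript has no cross term.
    struct_t = bct**2 + c_t**2
    trans = (
        bct * gene_m
        + c_t * u
        + rng.normal(0.0, _noise_sd(struct_t, "trans transcript"), n)
    )
    return ScenarioDataset(
        dosages={"snp_m": g_m, "snp_s": g_s},
        true_mediator=gene_m,
        measured_cis=gene_s,
        measured_trans=trans,
        confounder=u,
        truth={**asdict(config), "rep_index": rep_index},
    )


# ---------------------------------------------------------------------------
# full planted-truth study
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CisEffect:
    variant_id: str
    probe_id: str
    r2: float


@dataclass(frozen=True)
class TransEffect:
    """A planted trans-eQTL.

    ``mechanism`` is ``"mediated"`` (variant -> mediator probe -> trans
    probe; requires a planted cis effect of the same variant on
    ``mediator_probe_id``) or ``"direct"`` (variant -> trans probe with
    no expression intermediary). ``beta`` is in SD units: for mediated
    effects it is the mediator->trans slope, for direct effects the
    variance explained is beta^2 * var(G) after standardisation.
    """

    variant_id: str
    probe_id: str
    mechanism: str
    beta: float
    mediator_probe_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mechanism not in ("mediated", "direct"):
            raise ValueError("mechanism must be 'mediated' or 'direct'")
        if self.mechanism == "mediated" and self.mediator_probe_id is None:
            raise ValueError("mediated effects require mediator_probe_id")


@dataclass(frozen=True)
class StudyConfig:
    """Layout and planted truth for a synthetic multi-gene eQTL study.

    Variants and probes are spread evenly over ``n_chroms`` chromosomes
    at ``variant_spacing_bp`` / ``probe_spacing_bp`` intervals; MAFs are
    drawn uniformly from ``maf_range`` unless fixed via ``maf``.
    """

    n_samples: int = 200
    n_variants: int = 40
    n_probes: int = 20
    n_chroms: int = 2
    variant_spacing_bp: int = 200_000
    probe_spacing_bp: int = 400_000
    probe_length_bp: int = 50
    maf_range: Tuple[float, float] = (0.1, 0.5)
    maf: Optional[float] = None
    planted_cis: Tuple[CisEffect, ...] = ()
    planted_trans: Tuple[TransEffect, ...] = ()
    seed: int = 0


@dataclass
class StudyDataset:
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    truth: pd.DataFrame  # one row per planted effect


def _study_layout(config: StudyConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    v_rows = []
    for i in range(config.n_variants):
        chrom = chroms[i % config.n_chroms]
        rank = i // config.n_chroms
        v_rows.append(
            {
                "id": f"snp{i + 1}",
                "chrom": chrom,
                "pos": 1_000_000 + rank * config.variant_spacing_bp,
            }
        )
    variants = pd.DataFrame(v_rows).set_index("id")
    p_rows = []
    for j in range(config.n_probes):
        chrom = chroms[j % config.n_chroms]
        rank = j // config.n_chroms
        start = 1_000_000 + rank * config.probe_spacing_bp
        p_rows.append(
            {
                "id": f"probe{j + 1}",
                "chrom": chrom,
                "start": start,
                "end": start + config.probe_length_bp,
                "gene": f"GENE{j + 1}",
            }
        )
    probes = pd.DataFrame(p_rows).set_index("id")
    return variants, probes


def simulate_study(config: StudyConfig) -> StudyDataset:
    """Simulate a full study with planted cis and trans eQTLs.

    Expression is built probe by probe: a cis-linked probe gets variance
    fraction ``r2`` from its variant; a mediated trans probe inherits
    ``beta * mediator``; a direct trans probe gets a standardized
    genotype term of slope ``beta``. All probes are marginally ~N(0, 1).
    """
    rng = np.random.default_rng(config.seed)
    variants, probes = _study_layout(config)
    for eff in config.planted_cis:
        if eff.variant_id not in variants.index or eff.probe_id not in probes.index:
            raise ValueError(f"planted cis effect references unknown ids: {eff}")
    cis_by_probe = {e.probe_id: e for e in config.planted_cis}
    for eff in config.planted_trans:
        if eff.variant_id not in variants.index or eff.probe_id not in probes.index:
            raise ValueError(f"planted trans effect references unknown ids: {eff}")
        if eff.mechanism == "mediated":
            med = cis_by_probe.get(eff.mediator_probe_id)
            if med is None or med.variant_id != eff.variant_id:
                raise ValueError(
                    "mediated trans effect requires a planted cis effect of the "
                    f"same variant on {eff.mediator_probe_id}"
                )

    if config.maf is not None:
        mafs = np.full(config.n_variants, config.maf)
    else:
        mafs = rng.uniform(*config.maf_range, size=config.n_variants)
    dosage = rng.binomial(2, mafs, size=(config.n_samples, config.n_variants)).astype(float)
    variants["maf"] = mafs
    samples = [f"S{i + 1}" for i in range(config.n_samples)]
    geno = GenotypeMatrix(
        pd.DataFrame(dosage, index=samples, columns=variants.index), variants
    )

    # two passes so a mediated probe can reference its (cis) mediator probe
    # regardless of probe ordering
    expr: Dict[str, np.ndarray] = {}
    trans_by_probe = {e.probe_id: e for e in config.planted_trans}
    n = config.n_samples
    for probe_id in probes.index:
        if probe_id in cis_by_probe:
            eff = cis_by_probe[probe_id]
            p = float(variants.loc[eff.variant_id, "maf"])
            g = geno.dosage(eff.variant_id)
            b = np.sqrt(eff.r2 / (2 * p * (1 - p)))
            expr[probe_id] = b * (g - 2 * p) + rng.normal(
                0.0, _noise_sd(eff.r2, probe_id), n
            )
        elif probe_id in trans_by_probe and trans_by_probe[probe_id].mechanism == "direct":
            eff = trans_by_probe[probe_id]
            p = float(variants.loc[eff.variant_id, "maf"])
            g = geno.dosage(eff.variant_id)
            var_term = eff.beta**2 * 2 * p * (1 - p)
            expr[probe_id] = eff.beta * (g - 2 * p) + rng.normal(
                0.0, _noise_sd(var_term, probe_id), n
            )
        elif probe_id not in trans_by_probe:
            expr[probe_id] = rng.standard_normal(n)
    for probe_id in probes.index:
        if probe_id in trans_by_probe and trans_by_probe[probe_id].mechanism == "mediated":
            eff = trans_by_probe[probe_id]
            mediator = expr[eff.mediator_probe_id]
            expr[probe_id] = eff.beta * mediator + rng.normal(
                0.0, _noise_sd(eff.beta**2, probe_id), n
            )
    expression = ExpressionMatrix(
        pd.DataFrame(expr, index=samples, columns=probes.index), probes
    )

    rows = []
    for eff in config.planted_cis:
        rows.append(
            {
                "variant_id": eff.variant_id,
                "probe_id": eff.probe_id,
                "kind": "cis",
                "mechanism": "cis",
                "effect": eff.r2,
                "mediator_probe_id": "",
            }
        )
    for eff in config.planted_trans:
        rows.append(
            {
                "variant_id": eff.variant_id,
                "probe_id": eff.probe_id,
                "kind": "trans",
                "mechanism": eff.mechanism,
                "effect": eff.beta,
                "mediator_probe_id": eff.mediator_probe_id or "",
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=["variant_id", "probe_id", "kind", "mechanism", "effect", "mediator_probe_id"],
    )
    return StudyDataset(genotypes=geno, expression=expression, truth=truth)
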