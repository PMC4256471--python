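"""Drivers for the structural simulation experiments.

Each driver sweeps a parameter grid, simulates ``n_reps`` replicates per
cell, runs the three-regression mediation procedure on each replicate
(always at the variant and transcript an analyst would actually use),
and summarizes the distribution of the mediation proportion and Sobel P
per cell. Medians are used as the central summary: the ratio estimator
(beta_unadj - beta_adj)/beta_unadj is heavy-tailed and routinely throws
individual replicates above 1 or below 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import MediationRecord
from .mediation import classify_mediation, mediate_vectors
from .simulate import (
    ConfoundingConfig,
    MeasurementErrorConfig,
    WrongMediatorConfig,
    simulate_confounding_dataset,
    simulate_measurement_error_dataset,
    simulate_wrong_mediator_dataset,
)

__all__ = [
    "ScenarioSummary",
    "summarize_scenario",
    "summaries_frame",
    "run_measurement_error_grid",
    "run_confounding_grid",
    "run_wrong_mediator_suite",
    "DEFAULT_R2_MEASURE_GRID",
    "DEFAULT_TAG_LD_GRID",
]

DEFAULT_R2_MEASURE_GRID = (1.00, 0.75, 0.50, 0.25, 0.10)
DEFAULT_TAG_LD_GRID = (1.0, 0.9, 0.7, 0.5, 0.3, 0.1)


@dataclass(frozen=True)
class ScenarioSummary:
    """Distributional summary of mediation results for one grid cell."""

    scenario: str
    params: Tuple[Tuple[str, float], ...]
    n_reps: int
    mean_proportion: float
    median_proportion: float
    q02_5: float
    q25: float
    q75: float
    q97_5: float
    median_neglog10_sobel_p: float
    frac_mediated: float

    def __post_init__(self) -> None:
        qs = (self.q02_5, self.q25, self.median_proportion, self.q75, self.q97_5)
        if any(b < a - 1e-12 for a, b in zip(qs, qs[1:])):
            raise ValueError("quantiles out of order")
        if not 0 <= self.frac_mediated <= 1:
            raise ValueError("frac_mediated outside [0, 1]")


def summarize_scenario(
    records: Sequence[MediationRecord],
    scenario: str = "",
    params: Optional[Dict[str, float]] = None,
    sobel_p_cut: float = 1e-5,
) -> ScenarioSummary:
    """Order-invariant summary of per-replicate mediation records."""
    if len(records) == 0:
        raise ValueError("no records to summarize")
    prop = np.array([r.mediation_proportion for r in records], dtype=float)
    logs = -np.log10(np.array([r.sobel_p for r in records], dtype=float))
    q = np.quantile(prop, [0.025, 0.25, 0.5, 0.75, 0.975])
    frac = float(
        np.mean([classify_mediation(r, sobel_p_cut) == "mediated" for r in records])
    )
    return ScenarioSummary(
        scenario=scenario,
        params=tuple(sorted((params or {}).items())),
        n_reps=len(records),
        mean_proportion=float(prop.mean()),
        median_proportion=float(q[2]),
        q02_5=float(q[0]),
        q25=float(q[1]),
        q75=float(q[3]),
        q97_5=float(q[4]),
        median_neglog10_sobel_p=float(np.median(logs)),
        frac_mediated=frac,
    )


def summaries_frame(summaries: Sequence[ScenarioSummary]) -> pd.DataFrame:
    """Flatten summaries to a table (one column per grid parameter)."""
    rows = []
    for s in summaries:
        row = {"scenario": s.scenario, **dict(s.params)}
        for f in (
            "n_reps",
            "mean_proportion",
            "median_proportion",
            "q02_5",
            "q25",
            "q75",
            "q97_5",
            "median_neglog10_sobel_p",
            "frac_mediated",
        ):
            row[f] = getattr(s, f)
        rows.append(row)
    return pd.DataFrame(rows)


def _cell_seed(seed: int, cell_index: int) -> int:
    return (int(seed) * 100_003 + 7919 * cell_index) % (2**31 - 1)


def run_measurement_error_grid(
    base: MeasurementErrorConfig = MeasurementErrorConfig(),
    r2_measure_grid: Sequence[float] = DEFAULT_R2_MEASURE_GRID,
    ld_grid: Sequence[float] = DEFAULT_TAG_LD_GRID,
    seed: int = 0,
    n_reps: Optional[int] = None,
    sobel_p_cut: float = 1e-5,
    common_random_numbers: bool = False,
) -> List[ScenarioSummary]:
    """Sweep mediator measurement error x tag-variant LD.

    Mediation is run at the *tag* variant with the *measured* mediator,
    emulating an analyst who holds neither the causal variant nor a
    noise-free transcript measure.

    With ``common_random_numbers`` every cell reuses the same underlying
    random draws (same per-replicate seed), a paired design that sharply
    reduces the variance of *between-cell comparisons* (e.g. checking
    that attenuation is monotone along the grid) without changing any
    cell's marginal distribution.
    """
    summaries = []
    for idx, (r2m, ld) in enumerate(product(r2_measure_grid, ld_grid)):
        cfg = replace(
            base,
            r2_measure=r2m,
            tag_ld_r2=ld,
            seed=seed if common_random_numbers else _cell_seed(seed, idx),
            n_reps=n_reps or base.n_reps,
        )
        records = []
        for rep in range(cfg.n_reps):
            ds = simulate_measurement_error_dataset(cfg, rep)
            records.append(
                mediate_vectors(ds.dosages["tag"], ds.measured_trans, ds.measured_cis)
            )
        summaries.append(
            summarize_scenario(
                records,
                scenario="measurement_error",
                params={"r2_measure": r2m, "tag_ld_r2": ld},
                sobel_p_cut=sobel_p_cut,
            )
        )
    return summaries


def run_confounding_grid(
    base: ConfoundingConfig = ConfoundingConfig(),
    r2_cis_grid: Sequence[float] = (0.05, 0.1, 0.2, 0.4),
    beta_ct_grid: Sequence[float] = (0.1, 0.2, 0.3),
    beta_u_pairs: Sequence[Tuple[float, float]] = (
        (0.2, 0.2),
        (0.2, -0.2),
        (-0.2, 0.2),
        (-0.2, -0.2),
    ),
    seed: int = 0,
    n_reps: Optional[int] = None,
    sobel_p_cut: float = 1e-5,
) -> List[ScenarioSummary]:
    """Sweep cis strength x cis->trans effect x signed confounder loadings.

    The generating model is complete mediation, so every departure of
    the per-cell median proportion from 1 is collider bias with sign
    determined by sign(beta_u_cis * beta_u_trans).
    """
    summaries = []
    cells = list(product(r2_cis_grid, beta_ct_grid, beta_u_pairs))
    for idx, (r2c, bct, (buc, but)) in enumerate(cells):
        cfg = replace(
            base,
            r2_cis=r2c,
            beta_cis_trans=bct,
            beta_u_cis=buc,
            beta_u_trans=but,
            seed=_cell_seed(seed, idx),
            n_reps=n_reps or base.n_reps,
        )
        records = []
        for rep in range(cfg.n_reps):
            ds = simulate_confounding_dataset(cfg, rep)
            records.append(
                mediate_vectors(ds.dosages["causal"], ds.measured_trans, ds.measured_cis)
            )
        summaries.append(
            summarize_scenario(
                records,
                scenario="confounding",
                params={
                    "r2_cis": r2c,
                    "beta_cis_trans": bct,
                    "beta_u_cis": buc,
                    "beta_u_trans": but,
                },
                sobel_p_cut=sobel_p_cut,
            )
        )
    return summaries


def run_wrong_mediator_suite(
    configs: Sequence[WrongMediatorConfig],
    seed: int = 0,
    n_reps: Optional[int] = None,
    sobel_p_cut: float = 1e-5,
) -> List[ScenarioSummary]:
    """Run each wrong-mediator configuration, always analysing gene_s.

    The mediator handed to the procedure is the *selected* transcript,
    never the true mediator, at the causal variant for the trans effect.
    """
    summaries = []
    for idx, base in enumerate(configs):
        cfg = replace(base, seed=_cell_seed(seed, idx), n_reps=n_reps or base.n_reps)
        records = []
        for rep in range(cfg.n_reps):
            ds = simulate_wrong_mediator_dataset(cfg, rep)
            records.append(
                mediate_vectors(ds.dosages["snp_m"], ds.measured_trans, ds.measured_cis)
            )
        params = {
            "ld_r2_causal_pair": cfg.ld_r2_causal_pair,
            "confounder_effect_1": cfg.confounder_effects[0],
            "confounder_effect_2": cfg.confounder_effects[1],
            "cross_effect": cfg.cross_effect,
        }
        summaries.append(
            summarize_scenario(
                records, scenario=cfg.scenario, params=params, sobel_p_cut=sobel_p_cut
            )
        )
    return summaries
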