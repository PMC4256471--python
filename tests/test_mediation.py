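"""Sobel test, three-regression mediation, mediator selection, joint adjustment."""

import numpy as np
import pandas as pd
import pytest

import cismed as cm
from cismed.mediation import (
    classify_mediation,
    mediate_single,
    mediate_vectors,
    multi_mediator_adjust,
    select_cis_mediator,
    sobel_test,
)
from cismed.scan import bh_threshold, scan_cis, scan_trans, select_lead_signals

import oracles


class TestSobel:
    def test_worked_example_against_high_precision_oracle(self):
        se_o, z_o, p_o = oracles.sobel_oracle(0.5, 0.1, 0.4, 0.05)
        z, p = sobel_test(0.5, 0.1**2, 0.4, 0.05**2)
        assert se_o == pytest.approx(0.047170, abs=1e-6)
        assert z == pytest.approx(z_o, abs=1e-12)
        assert z == pytest.approx(4.23999, abs=1e-5)
        assert p == pytest.approx(p_o, rel=1e-9)
        assert p == pytest.approx(2.235e-5, rel=1e-3)

    def test_null_indirect_effect(self):
        z, p = sobel_test(0.0, 0.01, 0.7, 0.02)
        assert z == 0.0 and p == 1.0

    def test_sign_flip_negates_z_keeps_p(self):
        z1, p1 = sobel_test(0.5, 0.01, 0.4, 0.01)
        z2, p2 = sobel_test(0.5, 0.01, -0.4, 0.01)
        assert z2 == pytest.approx(-z1)
        assert p2 == pytest.approx(p1)

    def test_degenerate_inputs(self):
        assert sobel_test(0.0, 0.0, 0.0, 0.0) == (0.0, 1.0)
        with pytest.raises(ValueError, match="zero pooled SE"):
            sobel_test(0.5, 0.0, 0.4, 0.0)
        with pytest.raises(ValueError, match="non-negative"):
            sobel_test(0.5, -0.1, 0.4, 0.01)

    def test_aroian_variant_is_more_conservative(self):
        z_s, p_s = sobel_test(0.3, 0.01, 0.3, 0.01)
        z_a, p_a = sobel_test(0.3, 0.01, 0.3, 0.01, aroian=True)
        assert abs(z_a) < abs(z_s) and p_a > p_s


class TestMediateVectors:
    def test_inert_mediator_leaves_total_effect(self, rng):
        n = 2000
        g = rng.binomial(2, 0.3, n).astype(float)
        trans = 0.4 * g + rng.standard_normal(n)
        mediator = rng.standard_normal(n)  # unrelated to both
        rec = mediate_vectors(g, trans, mediator)
        assert rec.beta_adj == pytest.approx(rec.beta_unadj, abs=0.05)
        assert abs(rec.mediation_proportion) < 0.1

    def test_noiseless_complete_mediation(self, rng):
        # trans is an exact multiple of cis (no noise on the trans equation)
        n = 500
        g = rng.binomial(2, 0.3, n).astype(float)
        cis = 0.7 * g + rng.standard_normal(n)
        trans = 0.2 * cis
        rec = mediate_vectors(g, trans, cis)
        assert rec.beta_adj == pytest.approx(0.0, abs=1e-10)
        assert rec.mediation_proportion == pytest.approx(1.0, abs=1e-10)

    def test_matches_three_regression_oracle(self):
        cfg = cm.MeasurementErrorConfig(n_samples=300, r2_measure=0.5, seed=21)
        ds = cm.simulate_measurement_error_dataset(cfg, 0)
        g, t, m = ds.dosages["tag"], ds.measured_trans, ds.measured_cis
        rec = mediate_vectors(g, t, m)
        n = len(g)
        ones = np.ones(n)
        b_tot, *_ = oracles.ols_oracle(t, np.column_stack([ones, g]))
        b_adj, _, _, _, v_adj = oracles.ols_oracle(t, np.column_stack([ones, g, m]))
        b_med, _, _, _, v_med = oracles.ols_oracle(m, np.column_stack([ones, g]))
        assert rec.beta_unadj == pytest.approx(b_tot[1], abs=1e-10)
        assert rec.beta_adj == pytest.approx(b_adj[1], abs=1e-10)
        assert rec.beta1 == pytest.approx(b_adj[2], abs=1e-10)
        assert rec.var1 == pytest.approx(v_adj[2], abs=1e-12)
        assert rec.beta2 == pytest.approx(b_med[1], abs=1e-10)
        assert rec.var2 == pytest.approx(v_med[1], abs=1e-12)
        prop = (b_tot[1] - b_adj[1]) / b_tot[1]
        assert rec.mediation_proportion == pytest.approx(prop, abs=1e-12)

    def test_product_equals_difference_identity(self, rng):
        # with one mediator and shared covariates, beta1*beta2 == bu - ba for OLS
        n = 400
        g = rng.binomial(2, 0.3, n).astype(float)
        m = 0.5 * g + rng.standard_normal(n)
        t = 0.3 * m + 0.1 * g + rng.standard_normal(n)
        rec = mediate_vectors(g, t, m)
        assert rec.beta1 * rec.beta2 == pytest.approx(
            rec.beta_unadj - rec.beta_adj, abs=1e-10
        )

    def test_proportion_invariant_to_mediator_rescaling(self, rng):
        n = 300
        g = rng.binomial(2, 0.3, n).astype(float)
        m = 0.5 * g + rng.standard_normal(n)
        t = 0.3 * m + rng.standard_normal(n)
        r1 = mediate_vectors(g, t, m)
        r2 = mediate_vectors(g, t, 100.0 * m)
        assert r2.mediation_proportion == pytest.approx(
            r1.mediation_proportion, abs=1e-10
        )
        assert r2.sobel_p == pytest.approx(r1.sobel_p, rel=1e-9)
        r3 = mediate_vectors(g, t, -m)  # sign flip
        assert r3.sobel_p == pytest.approx(r1.sobel_p, rel=1e-9)

    def test_zero_total_effect_warns_and_yields_nan(self):
        g = np.array([0.0, 1.0, 2.0] * 4)
        t = np.zeros(12)  # total effect exactly zero
        m = np.arange(12.0)
        with pytest.warns(RuntimeWarning, match="total effect"):
            rec = mediate_vectors(g, t, m)
        assert np.isnan(rec.mediation_proportion)


class TestClassification:
    @pytest.mark.parametrize(
        "prop, p, label",
        [
            (0.8, 1e-8, "mediated"),
            (-0.3, 1e-12, "not_mediated"),
            (0.9, 1e-3, "not_mediated"),
        ],
    )
    def test_rule(self, prop, p, label):
        rec = cm.MediationRecord(
            "v", "pt", "pm", 1.0, 1.0 - prop, 0.5, 0.01, 0.5, 0.01,
            0.05, 3.0, p, prop,
        )
        assert classify_mediation(rec) == label

    def test_configurable_cutoff(self):
        rec = cm.MediationRecord(
            "v", "pt", "pm", 1.0, 0.2, 0.5, 0.01, 0.5, 0.01, 0.05, 3.0, 1e-3, 0.8
        )
        assert classify_mediation(rec, p_cut=1e-2) == "mediated"


@pytest.fixture(scope="module")
def scanned(planted_study):
    geno, expr = planted_study.genotypes, planted_study.expression
    cis = scan_cis(geno, expr)
    trans = scan_trans(geno, expr)
    ccut = bh_threshold(cis["p_value"], 0.05)
    tcut = bh_threshold(trans["p_value"], 0.05)
    csig = select_lead_signals(cis[cis["p_value"] <= ccut], geno.variants)
    tsig = select_lead_signals(trans[trans["p_value"] <= tcut], geno.variants)
    return csig, tsig


class TestSelectionAndPipeline:
    def test_planted_mediator_selected_with_unit_ld(self, planted_study, scanned):
        csig, tsig = scanned
        sig = tsig[tsig["probe_id"] == "probe2"].iloc[0]
        pick = select_cis_mediator(
            sig, csig, planted_study.genotypes, planted_study.expression
        )
        assert pick is not None
        probe, ld = pick
        assert probe == "probe1"
        if sig["lead_variant_id"] == "snp1":
            assert ld == pytest.approx(1.0)

    def test_no_candidate_returns_none(self, planted_study, scanned):
        csig, tsig = scanned
        rows = tsig[tsig["probe_id"] == "probe3"]
        if rows.empty:
            pytest.skip("direct trans effect not significant in this draw")
        pick = select_cis_mediator(
            rows.iloc[0], csig, planted_study.genotypes, planted_study.expression
        )
        assert pick is None  # no cis probe near snp2

    def test_argmax_ld_among_candidates(self, planted_study):
        geno, expr = planted_study.genotypes, planted_study.expression
        sig = pd.Series({"lead_variant_id": "snp1", "probe_id": "probe2"})
        csig = pd.DataFrame(
            {
                "lead_variant_id": ["snp1", "snp3"],
                "probe_id": ["probe1", "probe5"],
                "lead_p": [1e-10, 1e-8],
            }
        )
        pick = select_cis_mediator(sig, csig, geno, expr)
        assert pick[0] == "probe1"  # lead cis-eSNP == lead trans-eSNP, r2 = 1

    def test_mediated_signal_recovered_end_to_end(self, planted_study, scanned):
        csig, tsig = scanned
        sig = tsig[tsig["probe_id"] == "probe2"].iloc[0]
        probe, ld = select_cis_mediator(
            sig, csig, planted_study.genotypes, planted_study.expression
        )
        rec = mediate_single(
            sig, probe, planted_study.genotypes, planted_study.expression,
            ld_r2_leads=ld,
        )
        assert classify_mediation(rec) == "mediated"
        assert rec.mediation_proportion == pytest.approx(1.0, abs=0.35)
        assert rec.ld_r2_leads == pytest.approx(ld)


class TestMultiMediator:
    def test_single_candidate_reduces_to_mediate_single(self, planted_study):
        geno, expr = planted_study.genotypes, planted_study.expression
        sig = pd.Series({"lead_variant_id": "snp1", "probe_id": "probe2"})
        beta_adj, table = multi_mediator_adjust(sig, ["probe1"], geno, expr)
        rec = mediate_single(sig, "probe1", geno, expr)
        assert beta_adj == pytest.approx(rec.beta_adj, abs=1e-12)
        assert table.iloc[0]["beta"] == pytest.approx(rec.beta1, abs=1e-12)

    def test_two_mediator_structure_needs_both(self, rng):
        # trans driven through two cis transcripts of the same variant
        n = 4000
        g = rng.binomial(2, 0.4, n).astype(float)
        m1 = 0.6 * g + rng.standard_normal(n)
        m2 = 0.6 * g + rng.standard_normal(n)
        t = 0.4 * m1 + 0.4 * m2 + 0.3 * rng.standard_normal(n)
        samples = [f"S{i}" for i in range(n)]
        geno = cm.GenotypeMatrix(
            pd.DataFrame({"snpA": g}, index=samples),
            pd.DataFrame({"chrom": ["chr1"], "pos": [100]}, index=["snpA"]),
        )
        probes = pd.DataFrame(
            {
                "chrom": ["chr1"] * 2 + ["chr2"],
                "start": [100, 200, 100],
                "end": [150, 250, 150],
                "gene": list("abc"),
            },
            index=["m1", "m2", "t"],
        )
        expr = cm.ExpressionMatrix(
            pd.DataFrame({"m1": m1, "m2": m2, "t": t}, index=samples), probes
        )
        sig = pd.Series({"lead_variant_id": "snpA", "probe_id": "t"})
        adj_one, _ = multi_mediator_adjust(sig, ["m1"], geno, expr)
        adj_both, _ = multi_mediator_adjust(sig, ["m1", "m2"], geno, expr)
        assert abs(adj_both) < 0.05
        assert abs(adj_one) > abs(adj_both) + 0.1

    def test_empty_candidate_set_errors(self, planted_study):
        sig = pd.Series({"lead_variant_id": "snp1", "probe_id": "probe2"})
        with pytest.raises(ValueError, match="empty"):
            multi_mediator_adjust(
                sig, [], planted_study.genotypes, planted_study.expression
            )

    def test_collinear_candidates_pruned(self, planted_study):
        geno, expr = planted_study.genotypes, planted_study.expression
        vals = expr.values.copy()
        vals["probe_dup"] = vals["probe1"]
        probes = expr.probes.copy()
        probes.loc["probe_dup"] = probes.loc["probe1"]
        expr2 = cm.ExpressionMatrix(vals, probes)
        sig = pd.Series({"lead_variant_id": "snp1", "probe_id": "probe2"})
        _, table = multi_mediator_adjust(sig, ["probe1", "probe_dup"], geno, expr2)
        assert list(table["probe_id"]) == ["probe1"]
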