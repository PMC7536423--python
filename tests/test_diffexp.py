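import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surfdyn import diffexp
from surfdyn.diffexp import (
    ThresholdConfig,
    adjust_bh,
    call_significant,
    condition_level_abundance,
    differential_analysis,
    exclude_contaminants,
    fit_protein_model,
)
from surfdyn.diffexp import test_contrast as contrast_test  # avoid pytest collection
from surfdyn.simulate import SimulationConfig, simulate_feature_table, simulate_trajectories

from conftest import toy_quant


def bh_bruteforce(p: np.ndarray) -> np.ndarray:
    """Literal step-up definition: adj(i) = min over p(j)>=p(i) of p(j)*m/rank(j)."""
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_i, i in enumerate(order, start=1):
        candidates = [p[order[k - 1]] * m / k for k in range(rank_i, m + 1)]
        adj[i] = min(1.0, min(candidates))
    return adj


class TestProteinModel:
    def test_single_feature_exact_means(self):
        qm = toy_quant({"f1": {"A": [10, 10, 10], "B": [11, 11, 11]}})
        fit = fit_protein_model(qm.annotated(), "P1")
        assert fit.effects["B"] - fit.effects["A"] == pytest.approx(1.0, abs=1e-12)
        assert fit.sigma2 == 0.0

    def test_feature_offsets_cancel_in_contrast(self):
        # balanced two-feature design, offsets {0, +2}, condition effect +1
        qm = toy_quant({
            "f1": {"A": [10, 10, 10], "B": [11, 11, 11]},
            "f2": {"A": [12, 12, 12], "B": [13, 13, 13]},
        })
        fit = fit_protein_model(qm.annotated(), "P1")
        res = contrast_test(fit, "B", "A")
        assert res["log2fc"] == pytest.approx(1.0, abs=1e-9)

    def test_offset_invariance_random_balanced(self):
        rng = np.random.default_rng(0)
        base = {"A": rng.normal(10, 1, 3).tolist(), "B": rng.normal(11, 1, 3).tolist()}
        qm1 = toy_quant({"f1": base, "f2": base})
        shifted = {c: [v + 5.0 for v in vals] for c, vals in base.items()}
        qm2 = toy_quant({"f1": base, "f2": shifted})
        fc1 = contrast_test(fit_protein_model(qm1.annotated()), "B", "A")["log2fc"]
        fc2 = contrast_test(fit_protein_model(qm2.annotated()), "B", "A")["log2fc"]
        assert fc1 == pytest.approx(fc2, abs=1e-9)

    def test_single_condition_errors(self):
        qm = toy_quant({"f1": {"A": [10, 10]}})
        with pytest.raises(ValueError, match=">= 2 conditions"):
            fit_protein_model(qm.annotated(), "P1")

    def test_noise_free_simulation_recovers_trajectory_differences(self):
        cfg = SimulationConfig(n_proteins=5, peptides_per_protein=2,
                               replicate_sd=0.0, seed=4)
        _, _, truth = simulate_trajectories(cfg)
        qm = simulate_feature_table(truth, cfg).subset_pool("surface")
        long = qm.annotated()
        for protein in truth.proteins:
            fit = fit_protein_model(long[long["protein_group"] == protein], protein)
            est = contrast_test(fit, "DIV20", "DIV02")["log2fc"]
            planted = truth.surface_mean.loc[protein, 20.0] - truth.surface_mean.loc[protein, 2.0]
            assert est == pytest.approx(planted, abs=1e-9)


class TestContrast:
    def test_zero_variance_gives_missing_p(self):
        qm = toy_quant({"f1": {"A": [10, 10, 10], "B": [11, 11, 11]}})
        res = contrast_test(fit_protein_model(qm.annotated()), "B", "A")
        assert res["log2fc"] == pytest.approx(1.0) and np.isnan(res["p"])

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        qm = toy_quant({"f1": {
            "A": rng.normal(10, 0.3, 3).tolist(), "B": rng.normal(11, 0.3, 3).tolist()
        }})
        fit = fit_protein_model(qm.annotated())
        ab, ba = contrast_test(fit, "A", "B"), contrast_test(fit, "B", "A")
        assert ab["log2fc"] == pytest.approx(-ba["log2fc"], abs=1e-12)
        assert ab["p"] == pytest.approx(ba["p"], abs=1e-12)

    def test_missing_condition_flagged_not_error(self):
        qm = toy_quant({"f1": {"A": [10, 10], "B": [11, 11]}})
        res = contrast_test(fit_protein_model(qm.annotated()), "A", "C")
        assert np.isnan(res["log2fc"]) and "not estimable" in res["reason"]

    def test_null_contrast_unbiased(self):
        # identical groups with noise: mean log2fc over simulations near zero
        rng = np.random.default_rng(2)
        fcs = []
        for _ in range(500):
            vals = rng.normal(10, 0.3, 6)
            qm = toy_quant({"f1": {"A": vals[:3].tolist(), "B": vals[3:].tolist()}})
            fcs.append(contrast_test(fit_protein_model(qm.annotated()), "B", "A")["log2fc"])
        fcs = np.asarray(fcs)
        se_mean = 0.3 * np.sqrt(2 / 3) / np.sqrt(500)
        assert abs(fcs.mean()) < 3 * se_mean


class TestBH:
    def test_hand_computed_stepup(self):
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_value_identity(self):
        assert adjust_bh([0.05]) == pytest.approx([0.05])

    def test_out_of_range_errors(self):
        for bad in ([0.0, 0.5], [0.5, 1.5]):
            with pytest.raises(ValueError):
                adjust_bh(bad)

    def test_nan_passthrough_excluded_from_family(self):
        out = adjust_bh([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], adjust_bh([0.01, 0.02]))

    def test_matches_bruteforce_definition(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(1e-6, 1, 100)
            assert np.array_equal(adjust_bh(p), bh_bruteforce(p))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        p = rng.uniform(1e-6, 1, 200)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(adjust_bh(p), ref, atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0,
                              allow_nan=False), min_size=1, max_size=40))
    def test_bounds_and_order_preserved(self, pvals):
        p = np.asarray(pvals)
        adj = adjust_bh(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
        # monotone: sorting by p sorts adj
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestSignificanceCalling:
    def make_table(self, fcs, ps, contrast="B_vs_A"):
        return pd.DataFrame({
            "protein_group": [f"P{i}" for i in range(len(fcs))],
            "contrast": contrast, "condition_a": "B", "condition_b": "A",
            "log2fc": fcs, "se": 0.1, "df": 4, "p": ps,
        })

    def test_prefilter_excludes_small_fc_from_family(self):
        table = self.make_table([0.3, 1.0, 1.2], [0.001, 0.01, 0.02])
        out = call_significant(table, ThresholdConfig(prefilter_fc=True))
        row = out[out["log2fc"] == 0.3].iloc[0]
        assert not row["significant"] and np.isnan(row["adj_p"])
        # family size shrinks to 2 for the remaining entries
        assert out[out["log2fc"] == 1.0].iloc[0]["adj_p"] == pytest.approx(0.02)

    def test_threshold_limits_call_everything(self):
        table = self.make_table([0.8, -0.9, 1.5], [0.9, 0.5, 0.99])
        cfg = ThresholdConfig(fc_threshold=1.0 + 1e-9, alpha=0.999999)
        out = call_significant(table, cfg)
        assert out["significant"].all()

    def test_adj_p_at_least_p(self):
        rng = np.random.default_rng(5)
        table = self.make_table(rng.normal(0, 1, 50), rng.uniform(1e-4, 1, 50))
        out = call_significant(table)
        ok = out["adj_p"].notna()
        assert np.all(out.loc[ok, "adj_p"] >= out.loc[ok, "p"] - 1e-15)

    def test_families_are_per_contrast(self):
        t1 = self.make_table([1.0], [0.04], contrast="B_vs_A")
        t2 = self.make_table([1.0] * 10, np.linspace(0.04, 0.5, 10), contrast="C_vs_B")
        out = call_significant(pd.concat([t1, t2], ignore_index=True))
        # the singleton family keeps its raw p; the 10-test family inflates it
        assert out.iloc[0]["adj_p"] == pytest.approx(0.04)
        assert out.iloc[1]["adj_p"] > 0.04


class TestConditionAbundance:
    def test_single_feature_no_noise_equals_value(self):
        qm = toy_quant({"f1": {"A": [10, 10], "B": [12, 12]}})
        cond, sample = condition_level_abundance(qm)
        assert set(cond["abundance"]) == {10.0, 12.0}
        assert len(cond) == 2 and len(sample) == 4

    def test_offsets_shift_level_not_shape(self):
        qm = toy_quant({
            "f1": {"A": [10.0], "B": [11.0], "C": [12.5]},
            "f2": {"A": [12.0], "B": [13.0], "C": [14.5]},
        })
        cond, _ = condition_level_abundance(qm)
        prof = cond.set_index("condition")["abundance"]
        diffs = prof[["B", "C"]].to_numpy() - prof["A"]
        assert np.allclose(diffs, [1.0, 2.5], atol=1e-12)

    def test_one_row_per_protein_condition(self):
        cfg = SimulationConfig(n_proteins=4, peptides_per_protein=2, seed=6,
                               missing_rate=0.1)
        _, _, truth = simulate_trajectories(cfg)
        qm = simulate_feature_table(truth, cfg).subset_pool("surface")
        cond, _ = condition_level_abundance(qm)
        present = qm.annotated()[["protein_group", "condition"]].drop_duplicates()
        assert len(cond) == len(present)


def test_exclude_contaminants_drops_blocklisted_groups():
    cfg = SimulationConfig(n_proteins=4, peptides_per_protein=1, seed=7)
    _, _, truth = simulate_trajectories(cfg)
    qm = simulate_feature_table(truth, cfg)
    out = exclude_contaminants(qm, {"PROT0001"})
    assert "PROT0001" not in set(out.data["protein_group"])
    assert len(set(out.data["protein_group"])) == 3


def test_differential_analysis_end_to_end_structure():
    cfg = SimulationConfig(n_proteins=6, peptides_per_protein=2,
                           replicate_sd=0.2, seed=8)
    _, _, truth = simulate_trajectories(cfg)
    qm = simulate_feature_table(truth, cfg).subset_pool("surface")
    pairs = diffexp.preceding_contrasts(qm.design)
    assert pairs[0] == ("DIV04", "DIV02") and len(pairs) == 9
    table = differential_analysis(qm, pairs)
    assert len(table) == 6 * 9
    assert {"protein_group", "contrast", "log2fc", "p", "adj_p", "significant"} <= set(table.columns)
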