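import numpy as np
import pandas as pd
import pytest
from scipy import stats

from surfdyn.compare import (
    complex_pair_correlation,
    interval_fc_correlation,
    match_protein_groups,
    per_protein_spearman,
    quadrant_directionality,
    significant_overlap,
)
from surfdyn.io import ComplexCatalog, ProfileMatrix


def make_profiles(arr, proteins=None, pool="surface"):
    proteins = proteins or [f"P{i}" for i in range(arr.shape[0])]
    cols = [float(t) for t in range(2, 2 * arr.shape[1] + 1, 2)]
    return ProfileMatrix(pd.DataFrame(arr, index=proteins, columns=cols), pool)


def make_diff(contrast_fc: dict, cond_pairs: dict, significant=None):
    """Build a differential table {contrast: {protein: fc}}."""
    rows = []
    for contrast, fcs in contrast_fc.items():
        a, b = cond_pairs[contrast]
        for protein, fc in fcs.items():
            rows.append({
                "protein_group": protein, "contrast": contrast,
                "condition_a": a, "condition_b": b, "log2fc": fc,
                "p": 0.5, "adj_p": 0.5,
                "significant": bool(significant and protein in significant.get(contrast, ())),
            })
    return pd.DataFrame(rows)


class TestMatching:
    def test_shared_accession_matches(self):
        matched, us, ut = match_protein_groups(["P1;P2"], ["P2;P3"])
        assert matched.iloc[0]["match_key"] == "P2" and not us and not ut

    def test_tiebreak_smallest_total_key(self):
        matched, _, _ = match_protein_groups(["P1"], ["P1;P9", "P1"])
        assert matched.iloc[0]["total_group"] == "P1"

    def test_largest_intersection_wins(self):
        matched, _, _ = match_protein_groups(["P1;P2;P3"], ["P1", "P1;P2"])
        assert matched.iloc[0]["total_group"] == "P1;P2"

    def test_disjoint_universes_all_unmatched(self):
        matched, us, ut = match_protein_groups(["P1", "P2"], ["Q1", "Q2"])
        assert matched.empty and us == ["P1", "P2"] and ut == ["Q1", "Q2"]

    def test_one_to_one_output(self):
        matched, _, _ = match_protein_groups(["P1", "P1;P2"], ["P1;P2;P3"])
        assert len(matched) == 1

    def test_symmetric_outcome(self):
        rng = np.random.default_rng(0)
        accs = [f"A{i}" for i in range(12)]
        def random_groups(n):
            return [";".join(sorted(rng.choice(accs, size=rng.integers(1, 4),
                                                replace=False))) for _ in range(n)]
        for _ in range(10):
            s, t = random_groups(6), random_groups(6)
            fwd, _, _ = match_protein_groups(s, t)
            rev, _, _ = match_protein_groups(t, s)
            pairs_fwd = set(zip(fwd["surface_group"], fwd["total_group"]))
            pairs_rev = set(zip(rev["total_group"], rev["surface_group"]))
            assert pairs_fwd == pairs_rev


class TestPerProteinSpearman:
    def test_identical_series(self):
        arr = np.random.default_rng(1).normal(10, 1, (3, 8))
        table, summary = per_protein_spearman(make_profiles(arr), make_profiles(arr, pool="total"))
        assert np.allclose(table["rho"], 1.0)
        assert summary["fraction_positive"] == 1.0

    def test_reversed_series(self):
        arr = np.tile(np.arange(8.0), (2, 1))
        table, _ = per_protein_spearman(make_profiles(arr), make_profiles(arr[:, ::-1], pool="total"))
        assert np.allclose(table["rho"], -1.0)

    def test_matches_rank_formula(self):
        x = np.array([[1, 2, 3, 4, 5.0]])
        y = np.array([[2, 1, 4, 3, 5.0]])
        table, _ = per_protein_spearman(make_profiles(x), make_profiles(y, pool="total"))
        # no ties: rho = 1 - 6*sum(d^2)/(n(n^2-1)) with d = rank differences
        d2 = np.sum((np.arange(1, 6) - np.array([2, 1, 4, 3, 5])) ** 2)
        assert table.iloc[0]["rho"] == pytest.approx(1 - 6 * d2 / (5 * 24))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.normal(10, 1, (4, 9))
        t1, _ = per_protein_spearman(make_profiles(a), make_profiles(a * 3 - 1, pool="total"))
        t2, _ = per_protein_spearman(make_profiles(a), make_profiles(np.exp(a / 4), pool="total"))
        assert np.allclose(t1["rho"], 1.0) and np.allclose(t2["rho"], 1.0)

    def test_few_shared_points_skipped(self):
        a = np.full((1, 8), 10.0)
        b = a.copy()
        b[0, :6] = np.nan
        _, summary = per_protein_spearman(make_profiles(a), make_profiles(b, pool="total"))
        assert summary["n_skipped"] == 1


COND_PAIRS = {"DIV04_vs_DIV02": ("DIV04", "DIV02"), "DIV20_vs_DIV02": ("DIV20", "DIV02")}
COND_TIMES = pd.Series({"DIV02": 2.0, "DIV04": 4.0, "DIV20": 20.0})


class TestIntervalStats:
    def test_identical_tables_give_rho_one(self):
        rng = np.random.default_rng(3)
        fcs = {c: {f"P{i}": rng.normal() for i in range(10)} for c in COND_PAIRS}
        sdiff = make_diff(fcs, COND_PAIRS)
        stats_table = interval_fc_correlation(sdiff, sdiff.copy(), COND_TIMES)
        assert np.allclose(stats_table["rho"], 1.0)
        assert set(stats_table["interval"]) == {2.0, 18.0}

    def test_missing_contrast_skipped(self):
        rng = np.random.default_rng(4)
        fcs = {c: {f"P{i}": rng.normal() for i in range(5)} for c in COND_PAIRS}
        sdiff = make_diff(fcs, COND_PAIRS)
        tdiff = sdiff[sdiff["contrast"] == "DIV04_vs_DIV02"]
        out = interval_fc_correlation(sdiff, tdiff, COND_TIMES)
        assert list(out["contrast"]) == ["DIV04_vs_DIV02"]


class TestOverlap:
    def overlap_for(self, s_set, t_set, method="jaccard"):
        fcs = {"DIV04_vs_DIV02": {p: 1.0 for p in set(s_set) | set(t_set) | {"Pz"}}}
        sdiff = make_diff(fcs, COND_PAIRS, significant={"DIV04_vs_DIV02": s_set})
        tdiff = make_diff(fcs, COND_PAIRS, significant={"DIV04_vs_DIV02": t_set})
        out = significant_overlap(sdiff, tdiff, COND_TIMES, method=method)
        return out.iloc[0]["overlap_pct"]

    def test_identical_sets_full_overlap(self):
        assert self.overlap_for({"a", "b"}, {"a", "b"}) == 100.0

    def test_disjoint_sets_zero(self):
        assert self.overlap_for({"a"}, {"b"}) == 0.0

    def test_jaccard_formula(self):
        assert self.overlap_for({"a", "b", "c"}, {"b", "c", "d"}) == 50.0

    def test_min_denominator_variant(self):
        assert self.overlap_for({"a", "b", "c"}, {"b", "c"}, method="min") == 100.0

    def test_empty_union_missing(self):
        assert np.isnan(self.overlap_for(set(), set()))


class TestQuadrants:
    def test_all_agreeing(self):
        fc = pd.Series({"P1": 1.0, "P2": -2.0})
        sig = pd.Series({"P1": True, "P2": True})
        assert quadrant_directionality(fc, fc * 2, sig) == 1.0

    def test_half_agreeing_by_construction(self):
        s = pd.Series({f"P{i}": v for i, v in enumerate([1, 1, 1, -1, -1, -1.0])})
        t = pd.Series({f"P{i}": v for i, v in enumerate([1, 1, 1, 1, 1, 1.0])})
        sig = pd.Series(True, index=s.index)
        assert quadrant_directionality(s, t, sig) == 0.5

    def test_sign_flip_complements(self):
        rng = np.random.default_rng(5)
        s = pd.Series(rng.normal(0, 1, 20), index=[f"P{i}" for i in range(20)])
        t = pd.Series(rng.normal(0, 1, 20), index=s.index)
        sig = pd.Series(True, index=s.index)
        frac = quadrant_directionality(s, t, sig)
        assert quadrant_directionality(s, -t, sig) == pytest.approx(1 - frac)

    def test_only_significant_counted(self):
        s = pd.Series({"P1": 1.0, "P2": -1.0})
        t = pd.Series({"P1": 1.0, "P2": -1.0})
        sig = pd.Series({"P1": True, "P2": False})
        assert quadrant_directionality(s, t, sig) == 1.0


class TestComplexCorrelation:
    def test_pair_count(self):
        arr = np.random.default_rng(6).normal(10, 1, (3, 8))
        catalog = ComplexCatalog({"C1": {"P0", "P1"}})
        all_r, within_r, summary = complex_pair_correlation(make_profiles(arr), catalog)
        assert summary["n_all_pairs"] == 3 and summary["n_complex_pairs"] == 1

    def test_coregulated_complex_exceeds_background(self):
        rng = np.random.default_rng(7)
        shape = np.linspace(0, 3, 10)
        co = shape + rng.normal(0, 0.1, (5, 10))           # one co-regulated block
        bg = rng.normal(10, 1, (15, 10))                   # unrelated background
        profiles = make_profiles(np.vstack([co, bg]))
        catalog = ComplexCatalog({"C1": {f"P{i}" for i in range(5)}})
        _, _, summary = complex_pair_correlation(profiles, catalog)
        assert summary["median_within_complex"] > summary["median_all"] + 0.3

    def test_random_complexes_match_background(self):
        rng = np.random.default_rng(8)
        arr = rng.normal(10, 1, (30, 10))
        members = {f"P{i}" for i in rng.choice(30, 10, replace=False)}
        _, _, summary = complex_pair_correlation(make_profiles(arr),
                                                 ComplexCatalog({"C1": members}))
        assert abs(summary["median_within_complex"] - summary["median_all"]) < 0.25

    def test_complex_with_one_measured_member_skipped(self):
        arr = np.random.default_rng(9).normal(10, 1, (3, 8))
        catalog = ComplexCatalog({"C1": {"P0", "ZZZ"}})
        _, within_r, summary = complex_pair_correlation(make_profiles(arr), catalog)
        assert summary["n_complex_pairs"] == 0
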