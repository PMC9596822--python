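"""Normalization, fold changes, control-null p-values, alpha-RRA and FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import phosbe as pb
from phosbe.screen_analysis import CountMatrix

from _oracles import stepup_bh


def _matrix(counts: dict, roles: dict, controls: list) -> CountMatrix:
    df = pd.DataFrame(counts)
    return CountMatrix(
        counts=df,
        roles=pd.Series(roles),
        is_control=pd.Series([i in controls for i in df.index], index=df.index),
    )


@pytest.fixture
def small_matrix():
    # 12 controls so the control-median path engages
    rng = np.random.default_rng(0)
    base = rng.integers(50, 150, size=20)
    df = pd.DataFrame(
        {"b1": base, "t1": base, "t2": base},
        index=[f"g{i}" for i in range(20)],
    )
    return CountMatrix(
        counts=df,
        roles=pd.Series({"b1": "baseline", "t1": "treated", "t2": "treated"}),
        is_control=pd.Series([i >= 8 for i in range(20)], index=df.index),
    )


class TestNormalizeCounts:
    def test_identical_samples_identical_factors(self, small_matrix):
        norm, factors = pb.normalize_counts(small_matrix, "control_median")
        assert factors["b1"] == pytest.approx(factors["t1"])
        pd.testing.assert_frame_equal(norm[["b1"]], norm[["t1"]].set_axis(["b1"], axis=1))

    def test_scale_invariance_of_lfc(self, small_matrix):
        """Multiplying a raw sample by a constant (sequencing-depth drift)
        leaves control-median-normalized fold changes unchanged."""
        doubled = small_matrix.counts.copy()
        doubled["t1"] = 2 * doubled["t1"]
        m2 = CountMatrix(doubled, small_matrix.roles, small_matrix.is_control)
        norm1, _ = pb.normalize_counts(small_matrix, "control_median")
        norm2, _ = pb.normalize_counts(m2, "control_median")
        lfc1 = pb.guide_log2fc(norm1, ["t1", "t2"], ["b1"], pseudocount=1e-9)
        lfc2 = pb.guide_log2fc(norm2, ["t1", "t2"], ["b1"], pseudocount=1e-9)
        assert np.allclose(lfc1, lfc2, atol=1e-6)

    def test_total_is_cpm(self):
        m = _matrix(
            {"b1": [100, 300], "t1": [10, 30]},
            {"b1": "baseline", "t1": "treated"}, [],
        )
        norm, factors = pb.normalize_counts(m, "total")
        assert norm.loc[0, "b1"] == pytest.approx(0.25e6)
        assert norm.loc[0, "t1"] == pytest.approx(0.25e6)

    def test_worked_control_median_example(self):
        # 12 control guides, sample B = 2x sample A exactly:
        # each control's ratio pair is (x/gm, 2x/gm) with gm = x*sqrt(2),
        # so factors are (1/sqrt(2), 2/sqrt(2)) -> ratio exactly 2
        x = np.arange(10, 22)
        m = _matrix(
            {"A": x, "B": 2 * x},
            {"A": "baseline", "B": "treated"},
            list(range(12)),
        )
        _, factors = pb.normalize_counts(m, "control_median")
        assert factors["B"] / factors["A"] == pytest.approx(2.0)
        assert factors["A"] == pytest.approx(1 / np.sqrt(2))

    def test_all_zero_sample_rejected(self):
        m = _matrix({"b1": [1, 2], "t1": [0, 0]}, {"b1": "baseline", "t1": "treated"}, [])
        with pytest.raises(ValueError):
            pb.normalize_counts(m, "total")

    def test_few_controls_falls_back_to_total(self, caplog):
        m = _matrix({"b1": [100, 300], "t1": [100, 300]},
                    {"b1": "baseline", "t1": "treated"}, [0])
        norm, factors = pb.normalize_counts(m, "control_median")
        assert factors["b1"] == pytest.approx(400 / 1e6)


class TestGuideLog2FC:
    def test_identical_gives_zero(self, small_matrix):
        norm, _ = pb.normalize_counts(small_matrix, "total")
        lfc = pb.guide_log2fc(norm, ["t1", "t2"], ["b1"])
        assert np.allclose(lfc, 0.0)

    def test_worked_arithmetic(self):
        norm = pd.DataFrame({"b": [100.0], "t": [400.0]})
        lfc = pb.guide_log2fc(norm, ["t"], ["b"], pseudocount=1.0)
        assert lfc.iloc[0] == pytest.approx(np.log2(401 / 101), abs=1e-9)
        assert lfc.iloc[0] == pytest.approx(1.989, abs=0.001)

    def test_missing_sample_rejected(self):
        norm = pd.DataFrame({"b": [1.0]})
        with pytest.raises(KeyError):
            pb.guide_log2fc(norm, ["t"], ["b"])

    def test_invalid_pseudocount(self):
        norm = pd.DataFrame({"b": [1.0], "t": [1.0]})
        with pytest.raises(ValueError):
            pb.guide_log2fc(norm, ["t"], ["b"], pseudocount=0)


class TestEnrichmentAndCalls:
    def test_control_centering_median_zero(self, small_matrix):
        table = pb.enrichment_table(small_matrix)
        assert table.loc[table["is_control"], "centered_lfc"].median() == pytest.approx(0.0)

    def test_all_equal_to_controls_no_hits(self, small_matrix):
        table = pb.enrichment_table(small_matrix)
        assert pb.call_enriched(table) == []

    def test_single_strong_guide_called(self, small_matrix):
        counts = small_matrix.counts.copy()
        counts.loc["g0", ["t1", "t2"]] *= 64
        m = CountMatrix(counts, small_matrix.roles, small_matrix.is_control)
        table = pb.enrichment_table(m)
        assert pb.call_enriched(table) == ["g0"]

    def test_no_controls_rejected(self):
        m = _matrix({"b1": [100, 100], "t1": [100, 100]},
                    {"b1": "baseline", "t1": "treated"}, [])
        with pytest.raises(ValueError):
            pb.enrichment_table(m)

    def test_twofold_recall_on_simulation(self, screen_library):
        eff = pb.plant_effects(screen_library, frac_enriched=0.025, effect_size=2.0, seed=8)
        m = pb.simulate_screen(
            screen_library,
            pb.SimParams(coverage=500, depth=5_000_000, dispersion=0.05, seed=8,
                         effect_map=eff),
        )
        table = pb.enrichment_table(m)
        hits = set(pb.call_enriched(table, 2.0))
        recall = len(hits & set(eff)) / len(eff)
        assert recall >= 0.9


class TestEmpiricalPvalues:
    def test_formula_extremes(self):
        lfc = pd.DataFrame({
            "centered_lfc": np.r_[10.0, np.linspace(-1, 1, 20)],
            "is_control": [False] + [True] * 20,
        })
        p = pb.empirical_pvalues(lfc, "enriched")
        assert p.iloc[0] == pytest.approx(1 / 21)
        p_dep = pb.empirical_pvalues(lfc, "depleted")
        assert p_dep.iloc[0] == pytest.approx(1.0)

    def test_guide_at_control_median(self):
        lfc = pd.DataFrame({
            "centered_lfc": np.r_[0.0, np.linspace(-1, 1, 21)],
            "is_control": [False] + [True] * 21,
        })
        p = pb.empirical_pvalues(lfc, "enriched")
        assert p.iloc[0] == pytest.approx(0.5, abs=0.05)

    def test_invalid_side(self):
        lfc = pd.DataFrame({"centered_lfc": [0.0] * 11, "is_control": [True] * 11})
        with pytest.raises(ValueError):
            pb.empirical_pvalues(lfc, "up")

    def test_too_few_controls(self):
        lfc = pd.DataFrame({"centered_lfc": [0.0] * 5, "is_control": [True] * 5})
        with pytest.raises(ValueError):
            pb.empirical_pvalues(lfc, "enriched")


class TestRRA:
    def test_k1_beta_identity(self):
        """For a single-guide site, rho equals the guide's percentile
        (Beta(1,1) is uniform) whenever it passes alpha."""
        # 100 guides, target guide is rank 1 -> u = 0.01
        p = pd.Series(np.linspace(0.001, 1, 100), index=[f"g{i}" for i in range(100)])
        sites = pd.Series({f"g{i}": f"s{i}" for i in range(100)})
        out = pb.rra_site_scores(p, sites, alpha=0.05, n_perm=100, seed=0)
        assert out.loc["s0", "rho"] == pytest.approx(0.01)
        assert out.loc["s3", "rho"] == pytest.approx(0.04)

    def test_no_guide_below_alpha(self):
        p = pd.Series([0.5, 0.9, 0.7, 0.95], index=list("abcd"))
        sites = pd.Series({"a": "s1", "b": "s1", "c": "s2", "d": "s2"})
        out = pb.rra_site_scores(p, sites, alpha=0.05, n_perm=200, seed=0)
        assert (out["rho"] == 1.0).all()
        assert (out["p_value"] > 0.5).all()

    def test_planted_top_percentile_site(self):
        """A 3-guide site whose guides sit in the global top 1% scores
        permutation p <= 0.01 at n_perm=1000."""
        rng = np.random.default_rng(1)
        n = 1000
        p = pd.Series(rng.uniform(size=n), index=[f"g{i}" for i in range(n)])
        p.iloc[:3] = [0.001, 0.002, 0.003]  # top 1% of 1000 guides
        sites = pd.Series(
            {f"g{i}": (f"planted" if i < 3 else f"s{i // 5}") for i in range(n)}
        )
        out = pb.rra_site_scores(p, sites, alpha=0.05, n_perm=1000, seed=2)
        assert out.loc["planted", "p_value"] <= 0.01
        # null sites stay calibrated in the decision-relevant lower tail
        # (p has an atom at 1 from sites with no guide under alpha)
        null_p = out.drop("planted")["p_value"]
        assert (null_p < 0.05).mean() < 0.1
        assert (null_p < 0.2).mean() < 0.3

    def test_invalid_alpha(self):
        p = pd.Series([0.5], index=["a"])
        with pytest.raises(ValueError):
            pb.rra_site_scores(p, pd.Series({"a": "s"}), alpha=1.5)


class TestBHFDR:
    def test_flat_pvalues(self):
        assert np.allclose(pb.bh_fdr([0.03] * 5), 0.03)

    def test_stepup_example(self):
        assert np.allclose(pb.bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_p(self):
        assert pb.bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_empty(self):
        assert pb.bh_fdr(np.array([])).size == 0

    def test_matches_independent_stepup_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 30))
            assert np.allclose(pb.bh_fdr(p), stepup_bh(list(p)))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pb.bh_fdr([0.5, 0.0])


class TestOverlapCounts:
    def test_two_sets(self):
        out = pb.overlap_counts({"a", "b", "c"}, {"b", "c", "d"})
        assert out == {"A_only": 1, "B_only": 1, "AB": 2}

    def test_disjoint(self):
        assert pb.overlap_counts({"a"}, {"b"})["AB"] == 0

    def test_subset(self):
        out = pb.overlap_counts({"a", "b"}, {"a", "b", "c"})
        assert out["AB"] == 2 and out["A_only"] == 0

    def test_three_sets(self):
        out = pb.overlap_counts({1, 2, 3}, {2, 3, 4}, {3, 4, 5})
        assert out["ABC"] == 1
        assert out["AB_only"] == 1
        assert out["BC_only"] == 1
        assert out["A_only"] == 1 and out["C_only"] == 1
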