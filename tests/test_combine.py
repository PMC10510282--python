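import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import irwinhall

from translatome import design
from translatome.combine import (
    additive_combine,
    both_icd_pvalue,
    combined_stats,
    effect_pvalue,
    irwin_hall_cdf,
    rescue_pvalue,
    vwt_pvalue,
)


class TestAdditiveCombine:
    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ([0.05, 0.05], 0.1**2 / 2),
            ([0.01, 0.03], 0.04**2 / 2),
            ([0.02, 0.02], 0.04**2 / 2),
            ([0.01, 0.01], 0.02**2 / 2),
            ([0.1, 0.1, 0.1], 0.3**3 / 6),
            ([1.0], 1.0),
            ([0.0, 0.0, 0.0, 0.0], 0.0),
            ([1.0, 1.0], 1.0),  # capped: 2^2/2 = 2 -> 1
        ],
    )
    def test_paper_mode_arithmetic(self, pvals, expected):
        assert additive_combine(pvals, "paper") == pytest.approx(
            expected, abs=1e-15
        )

    def test_exact_mode_beyond_the_cap(self):
        # k=2, sum=1.5: Irwin-Hall CDF = 1 - (2-1.5)^2/2 = 0.875
        assert additive_combine([0.75, 0.75], "exact") == pytest.approx(0.875)
        assert additive_combine([0.75, 0.75], "paper") == 1.0

    @pytest.mark.parametrize("k", [2, 4])
    def test_modes_agree_below_unit_sum(self, k):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.dirichlet(np.ones(k)) * rng.uniform(0, 1)
            paper = additive_combine(p, "paper")
            exact = additive_combine(p, "exact")
            assert abs(paper - exact) < 1e-12

    @pytest.mark.parametrize("k", [2, 3, 4, 6])
    def test_irwin_hall_matches_scipy(self, k):
        s = np.linspace(0, k, 501)
        np.testing.assert_allclose(
            irwin_hall_cdf(s, k), irwinhall.cdf(s, k), atol=1e-12
        )

    def test_exact_matches_monte_carlo_tails(self):
        rng = np.random.default_rng(1)
        n = 200_000
        for k in (2, 4):
            s_grid = [0.5, 1.0, 1.5] if k == 2 else [1.0, 2.0, 3.0]
            sums = rng.random((n, k)).sum(axis=1)
            for s in s_grid:
                mc = (sums <= s).mean()
                exact = irwin_hall_cdf(s, k)
                se = np.sqrt(max(exact * (1 - exact), 1e-12) / n)
                assert abs(mc - exact) < 4 * se + 1e-9

    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=5),
        st.integers(0, 4),
        st.floats(0, 1),
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_monotone_in_each_input(self, pvals, idx, bump):
        idx = idx % len(pvals)
        higher = list(pvals)
        higher[idx] = min(1.0, higher[idx] + bump)
        for mode in ("paper", "exact"):
            assert additive_combine(higher, mode) >= additive_combine(
                pvals, mode
            ) - 1e-15

    def test_inputs_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            additive_combine([0.5, 1.2])
        with pytest.raises(ValueError):
            additive_combine([-0.1])
        with pytest.raises(ValueError):
            additive_combine([])

    def test_null_calibration_at_alpha_005(self):
        rng = np.random.default_rng(2)
        u = rng.random((50_000, 2))
        combined = np.minimum(1.0, u.sum(axis=1) ** 2 / 2)
        rate = (combined < 0.05).mean()
        assert abs(rate - 0.05) < 0.005


class TestDesignStatistics:
    def test_rescue_examples(self):
        assert rescue_pvalue(0.01, 0.03) == pytest.approx(0.0008)
        assert rescue_pvalue(1.0, 1.0) == 1.0

    def test_effect_is_exchangeable_and_composes(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            a, b = rng.random(2)
            assert effect_pvalue(a, b) == effect_pvalue(b, a)
            assert effect_pvalue(a, b) == additive_combine([a, b])

    def test_vwt_gate(self):
        # passes: both lfc above gate, same sign
        assert vwt_pvalue(0.04, 0.04, 1.0, 0.9) == pytest.approx(
            0.08**2 / 2
        )
        # opposite direction
        assert np.isnan(vwt_pvalue(0.04, 0.04, 1.0, -1.0))
        # second magnitude below the gate
        assert np.isnan(vwt_pvalue(0.04, 0.04, 1.0, 0.3))

    def test_both_icd_examples(self):
        assert both_icd_pvalue(0.01, 0.01) == pytest.approx(0.0002)
        assert both_icd_pvalue(1.0, 1.0) == 1.0
        assert np.isnan(both_icd_pvalue(float("nan"), 0.01))
        rng = np.random.default_rng(4)
        for _ in range(1000):
            a, b = rng.random(2)
            assert both_icd_pvalue(a, b) == additive_combine([a, b])


def _result_frame(index, lfc, p, tested=None):
    tested = np.ones(len(index), bool) if tested is None else tested
    return pd.DataFrame(
        {
            "base_mean": 100.0,
            "log2fc": lfc,
            "se": 0.1,
            "p": p,
            "padj": p,
            "tested": tested,
        },
        index=index,
    )


def make_results(index, rng):
    results = {}
    for geno in design.KO_GENOTYPES:
        results[design.baseline_name(geno)] = _result_frame(
            index, rng.normal(0, 1, len(index)), rng.random(len(index))
        )
        for icd in design.ICDS:
            for name in (
                design.icd_vs_baseline_name(geno, icd),
                design.icd_vs_wt_name(geno, icd),
            ):
                results[name] = _result_frame(
                    index, rng.normal(0, 1, len(index)), rng.random(len(index))
                )
    return results


class TestCombinedStatsTable:
    def test_matches_scalar_functions(self):
        rng = np.random.default_rng(5)
        index = pd.Index([f"g{i}" for i in range(50)], name="gene_id")
        results = make_results(index, rng)
        table = combined_stats(results).set_index(["gene_id", "genotype", "icd"])
        for gene in ["g0", "g7", "g33"]:
            for geno in design.KO_GENOTYPES:
                base = results[design.baseline_name(geno)].loc[gene]
                for icd in design.ICDS:
                    vs_b = results[design.icd_vs_baseline_name(geno, icd)].loc[gene]
                    vs_wt = results[design.icd_vs_wt_name(geno, icd)].loc[gene]
                    row = table.loc[(gene, geno, icd)]
                    assert row["rescue_p"] == pytest.approx(
                        rescue_pvalue(base["p"], vs_b["p"])
                    )
                    assert row["effect_p"] == pytest.approx(
                        effect_pvalue(vs_wt["p"], vs_b["p"])
                    )
                    want_vwt = vwt_pvalue(
                        base["p"], vs_wt["p"], base["log2fc"], vs_wt["log2fc"]
                    )
                    got = row["vwt_p"]
                    assert (np.isnan(got) and np.isnan(want_vwt)) or (
                        got == pytest.approx(want_vwt)
                    )

    def test_both_icd_nested_composition(self):
        rng = np.random.default_rng(6)
        index = pd.Index([f"g{i}" for i in range(20)], name="gene_id")
        results = make_results(index, rng)
        table = combined_stats(results, both_mode="nested-k2")
        sub = table.set_index(["gene_id", "genotype", "icd"])
        for gene in ["g1", "g13"]:
            for geno in design.KO_GENOTYPES:
                r19 = sub.loc[(gene, geno, "ICD19"), "rescue_p"]
                rd19 = sub.loc[(gene, geno, "ICDd19"), "rescue_p"]
                assert sub.loc[(gene, geno, "ICD19"), "both_rescue_p"] == (
                    pytest.approx(both_icd_pvalue(r19, rd19))
                )

    def test_flat_k4_uses_raw_inputs(self):
        rng = np.random.default_rng(7)
        index = pd.Index(["g0"], name="gene_id")
        results = make_results(index, rng)
        table = combined_stats(results, both_mode="flat-k4")
        geno = design.KO_GENOTYPES[0]
        p_base = results[design.baseline_name(geno)].loc["g0", "p"]
        p19 = results[design.icd_vs_baseline_name(geno, "ICD19")].loc["g0", "p"]
        pd19 = results[design.icd_vs_baseline_name(geno, "ICDd19")].loc["g0", "p"]
        want = additive_combine([p_base, p19, p_base, pd19])
        got = table[
            (table["gene_id"] == "g0") & (table["genotype"] == geno)
        ]["both_rescue_p"].iloc[0]
        assert got == pytest.approx(want)

    def test_untested_inputs_propagate_as_missing(self):
        rng = np.random.default_rng(8)
        index = pd.Index(["g0", "g1"], name="gene_id")
        results = make_results(index, rng)
        geno = design.KO_GENOTYPES[0]
        results[design.baseline_name(geno)].loc["g0", "tested"] = False
        table = combined_stats(results)
        sub = table[(table["gene_id"] == "g0") & (table["genotype"] == geno)]
        assert sub["rescue_p"].isna().all()
        assert sub["both_rescue_p"].isna().all()
        other = table[(table["gene_id"] == "g1") & (table["genotype"] == geno)]
        assert other["rescue_p"].notna().all()
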