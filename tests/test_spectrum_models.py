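"""Mutation categories, spectrum tables and regression tests."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from fluctspec.spectrum_models import (
    CATEGORIES,
    SNV_CLASSES,
    SpectrumTable,
    classify_substitution,
    fit_binomial_class,
    fit_multinomial,
    relative_frequencies,
    tabulate_spectrum,
    type2_tests_multinomial,
)

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
ALL_PAIRS = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]


def make_table(counts_by_condition):
    rows = []
    for (strain, glucose), counts in counts_by_condition.items():
        for cat, c in zip(CATEGORIES, counts):
            rows.append(dict(category=cat, strain=strain, glucose=glucose,
                             count=c))
    return SpectrumTable.from_long(pd.DataFrame(rows))


class TestClassification:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("A", "G", "AT>GC"), ("T", "C", "AT>GC"),
        ("G", "A", "GC>AT"), ("C", "T", "GC>AT"),
        ("A", "C", "AT>CG"), ("T", "G", "AT>CG"),
        ("A", "T", "AT>TA"), ("T", "A", "AT>TA"),
        ("G", "C", "GC>CG"), ("C", "G", "GC>CG"),
        ("G", "T", "GC>TA"), ("C", "A", "GC>TA"),
    ])
    def test_all_twelve_ordered_pairs(self, ref, alt, expected):
        assert classify_substitution(ref, alt) == expected

    def test_total_over_pairs_and_complement_invariant(self):
        for r, a in ALL_PAIRS:
            cls = classify_substitution(r, a)
            assert cls in SNV_CLASSES
            assert classify_substitution(COMPLEMENT[r], COMPLEMENT[a]) == cls

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("A", "A")
        with pytest.raises(ValueError):
            classify_substitution("N", "A")


class TestTabulation:
    def test_counts_partitioned_by_category(self):
        calls = pd.DataFrame({
            "strain": ["s"] * 3, "glucose": ["low"] * 3,
            "category": ["AT>GC", "AT>GC", "GC>TA"],
        })
        table = tabulate_spectrum(calls)
        row = table.counts.loc[("s", "low")]
        assert row["AT>GC"] == 2 and row["GC>TA"] == 1
        assert row.sum() == 3

    def test_none_detected_excluded(self):
        calls = pd.DataFrame({
            "strain": ["s"] * 3, "glucose": ["low"] * 3,
            "category": ["AT>GC", "none_detected", "deletion"],
        })
        assert tabulate_spectrum(calls).counts.values.sum() == 2

    def test_unknown_category_is_an_error(self):
        calls = pd.DataFrame({"strain": ["s"], "glucose": ["low"],
                              "category": ["bogus"]})
        with pytest.raises(ValueError):
            tabulate_spectrum(calls)

    def test_relative_frequencies_sum_to_one(self):
        table = make_table({("s", "low"): [2, 0, 0, 0, 0, 1, 0, 0],
                            ("s", "high"): [3, 3, 3, 3, 3, 3, 3, 3]})
        freqs = relative_frequencies(table)
        assert np.allclose(freqs.sum(axis=1), 1.0, atol=1e-12)
        assert freqs.loc[("s", "low"), "AT>GC"] == pytest.approx(2 / 3)
        assert freqs.loc[("s", "low"), "GC>TA"] == pytest.approx(1 / 3)

    def test_empty_condition_flagged_as_nan(self):
        table = make_table({("s", "low"): [1, 0, 0, 0, 0, 0, 0, 0],
                            ("s", "high"): [0] * 8})
        freqs = relative_frequencies(table)
        assert freqs.loc[("s", "high")].isna().all()


class TestMultinomialModel:
    def test_intercept_only_recovers_observed_frequencies(self):
        table = make_table({("s", "low"): [10, 5, 3, 2, 1, 4, 2, 3]})
        fit = fit_multinomial(table, ())
        counts = table.counts.values[0].astype(float)
        probs = counts / counts.sum()
        eta = np.concatenate([[0.0], fit.coef[0]])
        fitted = np.exp(eta) / np.exp(eta).sum()
        assert np.allclose(fitted, probs, atol=1e-7)

    def test_saturated_loglik_dominates_submodels(self):
        rng = np.random.default_rng(4)
        table = make_table({(s, g): rng.multinomial(100, np.full(8, 1 / 8))
                            for s in ("a", "b") for g in ("low", "high")})
        ll_full = fit_multinomial(table, ("glucose", "strain", "interaction")).loglik
        for terms in [(), ("glucose",), ("strain",), ("glucose", "strain")]:
            assert fit_multinomial(table, terms).loglik <= ll_full + 1e-8

    def test_single_predictor_lr_equals_g_statistic(self):
        rng = np.random.default_rng(7)
        p_low = np.array([0.35, 0.15, 0.1, 0.1, 0.05, 0.1, 0.05, 0.1])
        p_high = np.array([0.2, 0.2, 0.1, 0.15, 0.05, 0.15, 0.05, 0.1])
        table = make_table({("s", "low"): rng.multinomial(150, p_low),
                            ("s", "high"): rng.multinomial(180, p_high)})
        lr = 2 * (fit_multinomial(table, ("glucose",)).loglik
                  - fit_multinomial(table, ()).loglik)
        g, _, dof, _ = st.chi2_contingency(table.counts.values,
                                           lambda_="log-likelihood")
        assert dof == 7
        assert abs(lr - g) / g < 1e-6

    def test_agrees_with_statsmodels_mnlogit(self):
        """Independent cross-check of the grouped Newton fit."""
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        table = make_table({
            (s, g): rng.multinomial(120, np.array([0.3, 0.15, 0.1, 0.1,
                                                   0.05, 0.15, 0.05, 0.1]))
            for s in ("a", "b") for g in ("low", "high")})
        fit = fit_multinomial(table, ("glucose", "strain"))
        # expand grouped counts to individual observations for MNLogit
        counts = table.counts
        y_rows, x_rows = [], []
        for (strain, glucose), row in counts.iterrows():
            for j, c in enumerate(row.values):
                for _ in range(int(c)):
                    y_rows.append(j)
                    x_rows.append([1.0,
                                   1.0 if glucose != "low" else 0.0,
                                   1.0 if strain != "a" else 0.0])
        res = sm.MNLogit(np.array(y_rows), np.array(x_rows)).fit(disp=False)
        assert fit.loglik == pytest.approx(float(res.llf), abs=1e-5)

    def test_type2_df_is_seven_per_term(self):
        rng = np.random.default_rng(2)
        table = make_table({(s, g): rng.multinomial(80, np.full(8, 1 / 8))
                            for s in ("a", "b") for g in ("low", "high")})
        results = type2_tests_multinomial(table)
        assert [t.term for t in results] == ["glucose", "strain", "interaction"]
        assert all(t.df == 7 for t in results)
        assert all(0 <= t.p <= 1 for t in results)

    def test_identical_glucose_levels_give_zero_lr(self):
        rng = np.random.default_rng(3)
        base_a = rng.multinomial(90, np.full(8, 1 / 8))
        base_b = rng.multinomial(90, np.array([0.3, 0.1, 0.1, 0.1,
                                               0.05, 0.15, 0.1, 0.1]))
        table = make_table({("a", "low"): base_a, ("a", "high"): base_a,
                            ("b", "low"): base_b, ("b", "high"): base_b})
        results = {t.term: t for t in type2_tests_multinomial(table)}
        assert results["glucose"].lr_stat < 1e-6
        assert results["glucose"].p > 0.999


class TestBinomialPerClass:
    def test_balanced_table_gives_zero_statistics(self):
        table = make_table({(s, g): [10, 5, 5, 5, 5, 5, 5, 10]
                            for s in ("a", "b") for g in ("low", "high")})
        for t in fit_binomial_class(table, "AT>GC"):
            assert t.lr_stat < 1e-6
            assert t.df == 1

    def test_single_predictor_matches_2x2_g_test(self):
        table = make_table({("s", "low"): [30, 10, 5, 5, 5, 5, 5, 5],
                            ("s", "high"): [15, 15, 8, 8, 8, 8, 4, 4]})
        hits = table.counts["AT>GC"].values
        totals = table.counts.sum(axis=1).values
        contingency = np.array([hits, totals - hits]).T
        g, _, dof, _ = st.chi2_contingency(contingency,
                                           lambda_="log-likelihood",
                                           correction=False)
        assert dof == 1
        # with one condition pair, the glucose term is the only predictor
        t = [r for r in fit_binomial_class(table, "AT>GC")
             if r.term == "glucose"][0]
        assert abs(t.lr_stat - g) / g < 1e-6

    def test_never_observed_category_flagged(self):
        table = make_table({(s, g): [10, 5, 5, 5, 5, 5, 5, 0]
                            for s in ("a", "b") for g in ("low", "high")})
        for t in fit_binomial_class(table, "deletion"):
            assert np.isnan(t.lr_stat)
            assert "never observed" in t.note

    def test_unknown_category_rejected(self):
        table = make_table({("s", "low"): [1] * 8, ("s", "high"): [1] * 8})
        with pytest.raises(ValueError):
            fit_binomial_class(table, "AT→GC")
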