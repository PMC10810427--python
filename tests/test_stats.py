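"""Statistical stage against closed-form and reference-implementation oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from mitorepeat.simulate import make_cohort
from mitorepeat.stats_analysis import (
    aicc_compare,
    anova_sequential,
    contingency,
    correlate_counts,
    drop_nonsignificant,
    fit_model,
    run_factor_analysis,
    tukey_hsd,
)


class TestCorrelateCounts:
    def test_perfect_linearity(self):
        x = np.array([1.0, 2, 3, 5, 8])
        r, r2, p = correlate_counts(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        x = np.array([1.0, -1, 1, -1])
        y = np.array([1.0, 1, -1, -1])
        r, _, _ = correlate_counts(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="variance"):
            correlate_counts([1, 1, 1], [1, 2, 3])

    def test_closed_form_oracle(self, rng):
        """50 random pairs match the hand-computed r and t-transform p."""
        for _ in range(50):
            n = int(rng.integers(5, 60))
            x, y = rng.normal(size=n), rng.normal(size=n)
            r, r2, p = correlate_counts(x, y)
            xc, yc = x - x.mean(), y - y.mean()
            r_hand = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            t = r_hand * np.sqrt((n - 2) / (1 - r_hand**2))
            p_hand = 2 * scipy.stats.t.sf(abs(t), n - 2)
            assert r == pytest.approx(r_hand, abs=1e-12)
            assert p == pytest.approx(p_hand, abs=1e-12)


def _design_matrix(data, response, terms):
    """Independent treatment-coded design builder (no patsy/statsmodels)."""
    cols = [np.ones(len(data))]
    names = ["Intercept"]
    for t in terms:
        parts = t.split(":")
        blocks = []
        for v in parts:
            col = data[v]
            if col.dtype == object or str(col.dtype) == "category":
                levels = sorted(col.unique())
                blocks.append([(col == lv).astype(float).to_numpy() for lv in levels[1:]])
            else:
                blocks.append([col.to_numpy().astype(float)])
        prod = blocks[0]
        for b in blocks[1:]:
            prod = [x * y for x in prod for y in b]
        cols += prod
        names += [f"{t}_{i}" for i in range(len(prod))]
    return np.column_stack(cols), names


class TestFitModel:
    def test_two_level_factor_is_mean_difference(self):
        df = pd.DataFrame(dict(y=[1.0, 2, 3, 7, 8, 9], g=["a", "a", "a", "b", "b", "b"]))
        fit = fit_model(df, "y", ["g"])
        assert fit.coefficients["g[T.b]"] == pytest.approx(8 - 2)
        assert fit.coefficients["Intercept"] == pytest.approx(2)

    def test_intercept_only_grand_mean(self):
        df = pd.DataFrame(dict(y=[1.0, 5, 6, 8]))
        fit = fit_model(df, "y", [])
        assert fit.coefficients["Intercept"] == pytest.approx(5.0)
        assert fit.rss == pytest.approx(((np.array([1.0, 5, 6, 8]) - 5) ** 2).sum())

    def test_normal_equations_oracle(self, rng):
        """n=120, three factors + covariate: coefficients match lstsq on an
        independently built design matrix to 1e-8."""
        n = 120
        df = pd.DataFrame(
            dict(
                a=rng.choice(list("xyz"), n),
                b=rng.choice(list("pq"), n),
                c=rng.normal(size=n),
            )
        )
        df["y"] = rng.normal(size=n) + (df.a == "y") * 2 + df.c * 0.5
        fit = fit_model(df, "y", ["a", "b", "c"])
        X, _ = _design_matrix(df, "y", ["a", "b", "c"])
        beta, *_ = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)
        assert np.allclose(np.sort(fit.coefficients.to_numpy()), np.sort(beta), atol=1e-8)

    def test_missing_rows_dropped_and_counted(self):
        df = pd.DataFrame(
            dict(y=[1.0, 2, 3, 4], g=["a", None, "b", "b"])
        )
        fit = fit_model(df, "y", ["g"])
        assert fit.n == 3 and fit.n_dropped == 1

    def test_single_level_factor_reported_aliased(self):
        df = pd.DataFrame(dict(y=[1.0, 2, 3, 4], g=["a", "a", "a", "a"], h=list("xxyy")))
        fit = fit_model(df, "y", ["g", "h"])
        assert fit.aliased == ["g"]
        assert fit.terms == ["h"]

    def test_confounded_factors_rank_resolved(self):
        # b is a copy of a: its columns are perfectly aliased
        df = pd.DataFrame(dict(y=np.arange(8.0), a=list("xxyyxxyy"), b=list("ppqqppqq")))
        fit = fit_model(df, "y", ["a", "b"])
        assert "b" in fit.aliased and fit.terms == ["a"]


class TestAnovaSequential:
    def test_two_level_factor_f_equals_t_squared(self):
        df = pd.DataFrame(dict(y=[1.0, 2, 4, 7, 8, 12], g=list("aaabbb")))
        fit = fit_model(df, "y", ["g"])
        tbl = anova_sequential(fit)
        t, _ = scipy.stats.ttest_ind(df.y[df.g == "a"], df.y[df.g == "b"])
        assert tbl.loc[0, "F"] == pytest.approx(t**2, abs=1e-10)

    def test_balanced_design_order_invariant(self, rng):
        df = pd.DataFrame(
            dict(
                a=np.repeat(list("xy"), 20),
                b=list(np.tile(np.repeat(list("pq"), 10), 2)),
            )
        )
        df["y"] = rng.normal(size=40)
        t1 = anova_sequential(fit_model(df, "y", ["a", "b"])).set_index("term")
        t2 = anova_sequential(fit_model(df, "y", ["b", "a"])).set_index("term")
        for term in ("a", "b"):
            assert t1.loc[term, "sum_sq"] == pytest.approx(t2.loc[term, "sum_sq"])

    def test_projection_oracle(self, rng):
        """Sequential SS match explicit nested projections to 1e-8."""
        n = 90
        df = pd.DataFrame(
            dict(a=rng.choice(list("uvw"), n), b=rng.choice(list("mn"), n), c=rng.normal(size=n))
        )
        df["y"] = rng.normal(size=n) + (df.a == "v") * 1.5 + df.c
        terms = ["a", "b", "c"]
        tbl = anova_sequential(fit_model(df, "y", terms)).set_index("term")
        y = df["y"].to_numpy()
        prev_rss = ((y - y.mean()) ** 2).sum()
        for i, t in enumerate(terms):
            X, _ = _design_matrix(df, "y", terms[: i + 1])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = ((y - X @ beta) ** 2).sum()
            assert tbl.loc[t, "sum_sq"] == pytest.approx(prev_rss - rss, abs=1e-8)
            prev_rss = rss

    def test_sum_of_squares_partition(self, rng):
        n = 60
        df = pd.DataFrame(dict(a=rng.choice(list("xy"), n), c=rng.normal(size=n)))
        df["y"] = rng.normal(size=n)
        fit = fit_model(df, "y", ["a", "c"])
        tbl = anova_sequential(fit)
        total_ss = ((df.y - df.y.mean()) ** 2).sum()
        assert tbl.sum_sq.sum() == pytest.approx(total_ss, abs=1e-8)


class TestNestedAnova:
    def test_population_within_island_degrees_of_freedom(self):
        """With every population wholly island or mainland, the nested table
        attributes 1 df to island, (n_pops - 2) to population-within-island,
        and the sums of squares partition the total."""
        from mitorepeat.simulate import make_cohort
        from mitorepeat.stats_analysis import nested_anova

        cohort = make_cohort(41, island_effect=3.0)
        tab = nested_anova(cohort, "short").set_index("term")
        n_pops = cohort.population.nunique()
        assert tab.loc["island", "df"] == 1
        assert tab.loc["population(within island)", "df"] == n_pops - 2
        assert tab.df.sum() == len(cohort) - 1
        total_ss = ((cohort["short"] - cohort["short"].mean()) ** 2).sum()
        assert tab.sum_sq.sum() == pytest.approx(total_ss)


class TestAiccCompare:
    def test_identical_models_split_weight(self, rng):
        df = pd.DataFrame(dict(y=rng.normal(size=30), g=rng.choice(list("ab"), 30)))
        f1 = fit_model(df, "y", ["g"])
        f2 = fit_model(df, "y", ["g"])
        tbl = aicc_compare([f1, f2])
        assert np.allclose(tbl.weight, [0.5, 0.5])

    def test_weights_normalize(self, rng):
        df = pd.DataFrame(
            dict(y=rng.normal(size=40), g=rng.choice(list("ab"), 40), c=rng.normal(size=40))
        )
        fits = [fit_model(df, "y", t) for t in ([], ["g"], ["c"], ["g", "c"])]
        tbl = aicc_compare(fits)
        assert tbl.weight.sum() == pytest.approx(1.0)
        assert tbl.delta.min() == 0.0

    def test_formula_oracle(self, rng):
        """AICc matches the hand formula from RSS via the Gaussian MLE
        log-likelihood, to 1e-10."""
        n = 35
        df = pd.DataFrame(dict(y=rng.normal(size=n), c=rng.normal(size=n)))
        fit = fit_model(df, "y", ["c"])
        sigma2 = fit.rss / n
        ll = -n / 2 * (np.log(2 * np.pi * sigma2) + 1)
        k = 3  # intercept, slope, residual variance
        aicc_hand = -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert fit.aicc == pytest.approx(aicc_hand, abs=1e-10)

    def test_different_rows_rejected(self, rng):
        df = pd.DataFrame(
            dict(y=rng.normal(size=20), g=["a"] * 10 + ["b"] * 10,
                 h=["x"] * 5 + [None] * 5 + ["y"] * 10)
        )
        f1 = fit_model(df, "y", ["g"])
        f2 = fit_model(df, "y", ["h"])
        with pytest.raises(ValueError, match="different rows"):
            aicc_compare([f1, f2])
        tbl = aicc_compare([f1, f2], allow_different_rows=True)
        assert len(tbl) == 2


class TestTukeyHsd:
    def test_two_groups_reduce_to_t_test(self):
        df = pd.DataFrame(dict(y=[3.0, 4, 5, 9, 10, 12], g=list("aaabbb")))
        fit = fit_model(df, "y", ["g"])
        row = tukey_hsd(fit, "g").iloc[0]
        _, p_t = scipy.stats.ttest_ind(df.y[df.g == "a"], df.y[df.g == "b"])
        assert row.p == pytest.approx(p_t, abs=1e-9)

    def test_shifted_group_only_significant_pairs(self, rng):
        n = 60
        levels = np.repeat(list("abcd"), n)
        y = rng.normal(size=4 * n)
        y[levels == "d"] += 2.0
        df = pd.DataFrame(dict(y=y, g=levels))
        fit = fit_model(df, "y", ["g"])
        tbl = tukey_hsd(fit, "g")
        sig = {(r.level_a, r.level_b) for r in tbl.itertuples() if r.p < 0.05}
        assert sig == {("a", "d"), ("b", "d"), ("c", "d")}

    def test_reference_implementation_oracle(self, rng):
        """Unbalanced groups: p-values within 1e-6 of scipy's Tukey-Kramer."""
        groups = {
            "a": rng.normal(0, 1, 12),
            "b": rng.normal(0.5, 1, 23),
            "c": rng.normal(0, 1, 7),
        }
        df = pd.DataFrame(
            dict(
                y=np.concatenate(list(groups.values())),
                g=np.repeat(list(groups), [len(v) for v in groups.values()]),
            )
        )
        fit = fit_model(df, "y", ["g"])
        ours = tukey_hsd(fit, "g").set_index(["level_a", "level_b"])
        ref = scipy.stats.tukey_hsd(*groups.values())
        for (i, a), (j, b) in [((0, "a"), (1, "b")), ((0, "a"), (2, "c")), ((1, "b"), (2, "c"))]:
            assert ours.loc[(a, b), "p"] == pytest.approx(ref.pvalue[i, j], abs=1e-6)


class TestContingency:
    def test_enumeration(self):
        df = pd.DataFrame(dict(a=["x", "x", "y", "y"], b=["p", "q", "p", "q"]))
        tab = contingency(df, "a", "b")
        assert (tab.to_numpy() == 1).all()

    def test_zero_cell_explicit(self):
        df = pd.DataFrame(dict(a=["x", "x", "y"], b=["p", "q", "p"]))
        tab = contingency(df, "a", "b")
        assert tab.loc["y", "q"] == 0

    def test_brute_force_oracle(self, rng):
        df = pd.DataFrame(
            dict(a=rng.choice(list("xyz"), 200), b=rng.choice(list("pqr"), 200))
        )
        tab = contingency(df, "a", "b")
        for a in "xyz":
            for b in "pqr":
                assert tab.loc[a, b] == ((df.a == a) & (df.b == b)).sum()


class TestDropNonsignificant:
    def test_null_factor_eliminated(self, rng):
        n = 200
        df = pd.DataFrame(
            dict(
                real=rng.choice(list("ab"), n),
                noise=rng.choice(list("uvw"), n),
            )
        )
        df["y"] = rng.normal(size=n) + (df.real == "b") * 3
        fit = fit_model(df, "y", ["real", "noise"])
        reduced = drop_nonsignificant(fit)
        assert reduced.terms == ["real"]

    def test_true_effects_survive(self, rng):
        n = 400
        df = pd.DataFrame(
            dict(a=rng.choice(list("xy"), n), b=rng.choice(list("pq"), n))
        )
        df["y"] = rng.normal(size=n) + (df.a == "y") * 2 + (df.b == "q") * 1.5
        reduced = drop_nonsignificant(fit_model(df, "y", ["a", "b"]))
        assert set(reduced.terms) == {"a", "b"}

    def test_marginality_protects_main_effects(self, rng):
        n = 300
        df = pd.DataFrame(dict(a=rng.choice(list("xy"), n), b=rng.choice(list("pq"), n)))
        # pure interaction effect, no main effects
        df["y"] = rng.normal(size=n) + ((df.a == "y") & (df.b == "q")) * 3
        reduced = drop_nonsignificant(fit_model(df, "y", ["a", "b", "a:b"]))
        assert "a:b" in reduced.terms
        assert {"a", "b"} <= set(reduced.terms)

    def test_intercept_only_unchanged(self, rng):
        df = pd.DataFrame(dict(y=rng.normal(size=20)))
        fit = fit_model(df, "y", [])
        assert drop_nonsignificant(fit) is fit


class TestRunFactorAnalysis:
    def test_generative_truth_recovered(self):
        """A cohort built with a tissue effect and no sex effect keeps tissue
        and drops sex."""
        cohort = make_cohort(
            11, tissue_effect={"blood": 0, "feather": 0, "muscle": 4, "internal_organ": 4},
            noise_sd=2.0,
        )
        report = run_factor_analysis(cohort, response="long")
        assert "tissue" in report["selected_terms"]
        assert "sex" not in report["selected_terms"]

    def test_confounded_age_effect_vanishes_in_subset(self):
        """With the sampling imbalance (island adults in muscle/organ,
        mainland juveniles in blood/feather) a single-factor age contrast is
        significant in the full cohort but not among muscle/organ samples,
        where both ages occur."""
        cohort = make_cohort(
            13,
            tissue_effect={"blood": 0, "feather": 0, "muscle": 4, "internal_organ": 4},
            age_effect=0.0,
            noise_sd=2.0,
            confound_age_tissue=True,
            age_missing_rate=0.1,
        )
        full_fit = fit_model(cohort, "long", ["age_class"])
        p_full = anova_sequential(full_fit).loc[0, "p"]
        sub = cohort[cohort.tissue.isin(["muscle", "internal_organ"])]
        p_sub = anova_sequential(fit_model(sub, "long", ["age_class"])).loc[0, "p"]
        assert p_full < 0.05
        assert p_sub > 0.05

    def test_row_order_invariance(self):
        cohort = make_cohort(17)
        r1 = run_factor_analysis(cohort, response="short")
        r2 = run_factor_analysis(cohort.sample(frac=1, random_state=0), response="short")
        assert r1["selected_terms"] == r2["selected_terms"]
        assert r1["aicc_table"] == r2["aicc_table"]

    def test_empty_intersection_error(self):
        est = pd.DataFrame(
            dict(sample_id=["a"], repeat_label=["long"], copies=[5], status=["ok"])
        )
        meta = pd.DataFrame(dict(sample_id=["b"]))
        with pytest.raises(ValueError, match="no samples"):
            run_factor_analysis(est, meta, response="long")

    def test_report_serializable(self):
        import json

        cohort = make_cohort(19)
        report = run_factor_analysis(cohort, response="long")
        json.dumps(report, default=str)
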