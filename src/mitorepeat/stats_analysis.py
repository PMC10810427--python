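"""Factor analysis of repeat copy numbers: OLS models, backward elimination
by AICc, sequential ANOVA, Akaike weights, Tukey-Kramer post hocs and
contingency diagnostics.

Models are ordinary least squares on treatment-coded factors (alphabetical
baseline), fitted through statsmodels.  Model selection uses the
small-sample-corrected Akaike criterion AICc = -2l + 2k + 2k(k+1)/(n-k-1)
with k counting every estimated parameter including the residual variance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ModelFit",
    "correlate_counts",
    "fit_model",
    "drop_nonsignificant",
    "anova_sequential",
    "nested_anova",
    "aicc_compare",
    "tukey_hsd",
    "contingency",
    "run_factor_analysis",
]


def correlate_counts(x, y) -> tuple[float, float, float]:
    """Pearson correlation of two copy-number vectors: (r, r^2, two-sided p).

    The p-value comes from the t transform t = r sqrt((n-2)/(1-r^2)) with
    n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(r) ** 2, float(p)


def _vars_of_term(term: str) -> frozenset[str]:
    return frozenset(t.strip() for t in term.split(":"))


@dataclass
class ModelFit:
    """An OLS fit plus the bookkeeping needed for AICc model comparison."""

    response: str
    terms: list[str]
    data: pd.DataFrame  # complete-case rows actually used
    result: object  # statsmodels RegressionResults
    n_dropped: int
    aliased: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(self.result.nobs)

    @property
    def coefficients(self) -> pd.Series:
        return self.result.params

    @property
    def rss(self) -> float:
        return float(self.result.ssr)

    @property
    def loglik(self) -> float:
        return float(self.result.llf)

    @property
    def df_resid(self) -> float:
        return float(self.result.df_resid)

    @property
    def n_params(self) -> int:
        # coefficients + residual variance
        return len(self.result.params) + 1

    @property
    def aicc(self) -> float:
        k, n = self.n_params, self.n
        if n - k - 1 <= 0:
            return float("inf")
        return -2.0 * self.loglik + 2 * k + 2.0 * k * (k + 1) / (n - k - 1)

    def formula(self) -> str:
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"{self.response} ~ {rhs}"

    def summary(self) -> str:
        return str(self.result.summary())


def fit_model(
    data: pd.DataFrame,
    response: str,
    terms: list[str],
) -> ModelFit:
    """OLS of ``response`` on ``terms`` (factor names and a:b interactions).

    Rows with missing values in any used column are dropped (count logged on
    the fit).  Categorical terms are treatment-coded with the alphabetically
    first level as baseline.  Factors that are constant (or interactions that
    are fully aliased) on the complete-case rows are reported and dropped
    rather than fitted, mirroring the NA coefficients a rank-deficient
    factor model produces elsewhere.
    """
    cols = sorted({v for t in terms for v in _vars_of_term(t)})
    missing = [c for c in cols + [response] if c not in data.columns]
    if missing:
        raise KeyError(f"columns not in data: {missing}")
    sub = data[[response] + cols].dropna()
    n_dropped = len(data) - len(sub)
    if len(sub) < 2:
        raise ValueError("fewer than 2 complete rows")
    aliased: list[str] = []
    usable: list[str] = []
    for t in terms:
        bad = False
        for v in _vars_of_term(t):
            col = sub[v]
            if (col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype)) and col.nunique() < 2:
                bad = True
        if bad:
            aliased.append(t)
        else:
            usable.append(t)
    rhs = " + ".join(usable) if usable else "1"
    model = smf.ols(f"{response} ~ {rhs}", data=sub)
    # detect remaining rank deficiency (confounded factor combinations)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        keep, taken = [], np.zeros((model.exog.shape[0], 0))
        slices = model.data.design_info.term_name_slices
        for t in ["Intercept"] + usable:
            block = model.exog[:, slices[t]]
            cand = np.hstack([taken, block])
            if np.linalg.matrix_rank(cand) == cand.shape[1]:
                taken = cand
                if t != "Intercept":
                    keep.append(t)
            elif t != "Intercept":
                aliased.append(t)
        usable = keep
        rhs = " + ".join(usable) if usable else "1"
        model = smf.ols(f"{response} ~ {rhs}", data=sub)
    result = model.fit()
    return ModelFit(response, usable, sub, result, n_dropped, aliased)


def drop_nonsignificant(fit: ModelFit) -> ModelFit:
    """Backward elimination: repeatedly remove the single term whose removal
    lowers AICc the most, until no removal lowers it.

    Marginality is respected — a main effect is not droppable while it
    appears in a retained interaction.  Refits use the same rows as the
    input fit so that the AICc values stay comparable.
    """
    current = fit
    while True:
        droppable = []
        for t in current.terms:
            tv = _vars_of_term(t)
            if any(tv < _vars_of_term(o) for o in current.terms if o != t):
                continue
            droppable.append(t)
        if not droppable:
            return current
        trials = []
        for t in droppable:
            reduced = [x for x in current.terms if x != t]
            trial = fit_model(current.data, current.response, reduced)
            trials.append((trial.aicc, t, trial))
        trials.sort(key=lambda x: (x[0], x[1]))
        best_aicc, _t, best_fit = trials[0]
        if best_aicc < current.aicc:
            current = best_fit
        else:
            return current


def anova_sequential(fit: ModelFit) -> pd.DataFrame:
    """Type-I (sequential) ANOVA table in the model's term order."""
    if fit.df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    if not fit.terms:
        return pd.DataFrame(
            columns=["term", "df", "sum_sq", "mean_sq", "F", "p"]
        ).astype({"df": float})
    tbl = sm.stats.anova_lm(fit.result, typ=1)
    tbl = tbl.rename(
        columns={"sum_sq": "sum_sq", "mean_sq": "mean_sq", "F": "F", "PR(>F)": "p"}
    )
    tbl.insert(0, "term", tbl.index)
    tbl["mean_sq"] = tbl["sum_sq"] / tbl["df"]
    return tbl.reset_index(drop=True)


def aicc_compare(
    fits: list[ModelFit], *, allow_different_rows: bool = False
) -> pd.DataFrame:
    """AICc ranking with deltas and Akaike weights.

    Models fitted to different row sets are not comparable (their likelihoods
    are over different data); this is an error unless explicitly overridden.
    """
    if not fits:
        raise ValueError("no fits to compare")
    resp = {f.response for f in fits}
    if len(resp) > 1:
        raise ValueError(f"fits have different responses: {sorted(resp)}")
    if not allow_different_rows:
        idx0 = set(fits[0].data.index)
        for f in fits[1:]:
            if set(f.data.index) != idx0:
                raise ValueError(
                    "fits use different rows (likely different missingness); "
                    "refit on a common subset or pass allow_different_rows=True"
                )
    rows = pd.DataFrame(
        {
            "model": [f.formula() for f in fits],
            "k": [f.n_params for f in fits],
            "n": [f.n for f in fits],
            "AICc": [f.aicc for f in fits],
        }
    )
    rows["delta"] = rows["AICc"] - rows["AICc"].min()
    rel = np.exp(-rows["delta"] / 2)
    rows["weight"] = rel / rel.sum()
    return rows.sort_values("AICc", kind="stable").reset_index(drop=True)


def nested_anova(
    data: pd.DataFrame, response: str, outer: str = "island", inner: str = "population"
) -> pd.DataFrame:
    """Sequential decomposition for a factor nested in another.

    With every level of ``inner`` belonging to exactly one level of ``outer``
    (each population is wholly island or mainland), the inner factor aliases
    the outer one, so degrees of freedom come from projection ranks:
    SS(outer) first, then SS(inner | outer), F against the residual of the
    full nested fit.
    """
    sub = data[[response, outer, inner]].dropna()
    n = len(sub)
    y = sub[response].astype(float).to_numpy()

    def design(cols: list[str]) -> np.ndarray:
        mats = [np.ones((n, 1))]
        for c in cols:
            levels = sorted(sub[c].astype(str).unique())
            for lv in levels[1:]:
                mats.append((sub[c].astype(str) == lv).to_numpy(float)[:, None])
        return np.hstack(mats)

    def rss_rank(X: np.ndarray) -> tuple[float, int]:
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        return float(((y - X @ beta) ** 2).sum()), int(rank)

    rss0 = float(((y - y.mean()) ** 2).sum())
    rss1, r1 = rss_rank(design([outer]))
    rss2, r2 = rss_rank(design([outer, inner]))
    df_outer, df_inner, df_resid = r1 - 1, r2 - r1, n - r2
    ms_resid = rss2 / df_resid
    rows = []
    for term, df, ss in (
        (outer, df_outer, rss0 - rss1),
        (f"{inner}(within {outer})", df_inner, rss1 - rss2),
    ):
        f_stat = (ss / df) / ms_resid if df > 0 else np.nan
        p = float(scipy.stats.f.sf(f_stat, df, df_resid)) if df > 0 else np.nan
        rows.append(dict(term=term, df=df, sum_sq=ss, mean_sq=ss / max(df, 1), F=f_stat, p=p))
    rows.append(
        dict(term="Residual", df=df_resid, sum_sq=rss2, mean_sq=ms_resid, F=np.nan, p=np.nan)
    )
    return pd.DataFrame(rows)


def tukey_hsd(fit: ModelFit, factor: str, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey-Kramer honest significant differences between levels of ``factor``.

    Differences are between raw level means of the response; the standard
    error uses the fit's residual mean square with the Tukey-Kramer
    correction for unequal group sizes, and p-values come from the
    studentized range distribution with (n_levels, residual df).
    """
    if factor not in {v for t in fit.terms for v in _vars_of_term(t)}:
        raise KeyError(f"factor {factor!r} not in model terms")
    groups = fit.data.groupby(factor, observed=True)[fit.response]
    means, sizes = groups.mean(), groups.size()
    if (sizes < 1).any() or len(means) < 2:
        raise ValueError("each level needs at least one observation")
    k = len(means)
    df = fit.df_resid
    mse = fit.rss / df
    q_crit = scipy.stats.studentized_range.ppf(1 - alpha, k, df)
    rows = []
    for a, b in itertools.combinations(sorted(means.index), 2):
        diff = means[b] - means[a]
        se = np.sqrt(mse / 2 * (1 / sizes[a] + 1 / sizes[b]))
        q = abs(diff) / se
        p = float(scipy.stats.studentized_range.sf(q, k, df))
        half = q_crit * se
        rows.append(
            dict(
                level_a=a,
                level_b=b,
                diff=float(diff),
                se=float(se),
                p=p,
                ci_low=float(diff - half),
                ci_high=float(diff + half),
            )
        )
    return pd.DataFrame(rows)


def contingency(
    data: pd.DataFrame,
    factor_a: str,
    factor_b: str,
    levels_a: list | None = None,
    levels_b: list | None = None,
) -> pd.DataFrame:
    """Count matrix over all level combinations, keeping explicit zero cells."""
    sub = data[[factor_a, factor_b]].dropna()
    tab = pd.crosstab(sub[factor_a], sub[factor_b])
    la = levels_a or sorted(set(sub[factor_a]))
    lb = levels_b or sorted(set(sub[factor_b]))
    return tab.reindex(index=la, columns=lb, fill_value=0)


# ---------------------------------------------------------------------------
# orchestration

_DEFAULT_FACTORS = ["sex", "island", "population", "haplogroup", "age_class", "tissue"]
_DEFAULT_COVARIATES = ["median_coverage"]


def _df_records(df: pd.DataFrame) -> list[dict]:
    return df.replace({np.nan: None}).to_dict(orient="records")


def run_factor_analysis(
    estimates: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    response: str = "long",
    factors: list[str] | None = None,
    covariates: list[str] | None = None,
    nest_population_in_island: bool = False,
) -> dict:
    """The full statistical sequence for one repeat.

    Full additive model -> AICc backward elimination -> sequential ANOVA of
    the surviving factors with their pairwise interactions -> AICc comparison
    of the candidate models -> contingency diagnostics -> Tukey post hocs ->
    subset re-runs (juveniles only; blood only; muscle + internal organ only).
    Returns a JSON-serializable report.
    """
    factors = factors if factors is not None else list(_DEFAULT_FACTORS)
    covariates = covariates if covariates is not None else list(_DEFAULT_COVARIATES)
    table = estimates
    if "repeat_label" in table.columns:
        table = table[table.get("status", "ok") == "ok"] if "status" in table.columns else table
        table = table.pivot_table(
            index="sample_id", columns="repeat_label", values="copies", aggfunc="first"
        ).reset_index()
    if metadata is not None:
        table = table.merge(metadata, on="sample_id", how="inner")
    if len(table) == 0:
        raise ValueError("no samples shared between estimates and metadata")
    if response not in table.columns:
        raise KeyError(f"response column {response!r} missing after join")

    factors = [f for f in factors if f in table.columns]
    covariates = [c for c in covariates if c in table.columns]

    report: dict = {"response": response, "n_samples": int(len(table))}

    full = fit_model(table, response, factors + covariates)
    report["full_model"] = {
        "formula": full.formula(),
        "n": full.n,
        "n_dropped_missing": full.n_dropped,
        "aliased": full.aliased,
        "AICc": full.aicc,
    }
    reduced = drop_nonsignificant(full)
    kept = reduced.terms
    report["selected_terms"] = kept
    kept_factors = [t for t in kept if t in factors]

    # ANOVA with pairwise interactions among surviving categorical factors
    inter = [f"{a}:{b}" for a, b in itertools.combinations(kept_factors, 2)]
    anova_fit = fit_model(table, response, kept + inter)
    report["anova_with_interactions"] = {
        "formula": anova_fit.formula(),
        "aliased": anova_fit.aliased,
        "table": _df_records(anova_sequential(anova_fit)),
    }

    # candidate models on the rows complete for the richest candidate
    base = anova_fit.data
    candidates = [fit_model(base, response, kept + inter)]
    candidates.append(fit_model(base, response, kept))
    for f in kept_factors:
        candidates.append(fit_model(base, response, [f]))
    seen, uniq = set(), []
    for c in candidates:
        if c.formula() not in seen:
            seen.add(c.formula())
            uniq.append(c)
    report["aicc_table"] = _df_records(aicc_compare(uniq))

    report["contingency"] = {
        f"{a}_x_{b}": contingency(table, a, b).to_dict()
        for a, b in itertools.combinations(kept_factors, 2)
    }

    if nest_population_in_island and {"island", "population"} <= set(table.columns):
        report["nested_island_population"] = _df_records(
            nested_anova(table, response, "island", "population")
        )

    report["tukey"] = {}
    for f in kept_factors:
        sub_fit = fit_model(table, response, [f])
        if sub_fit.terms and table[f].nunique() >= 2:
            report["tukey"][f] = _df_records(tukey_hsd(sub_fit, f))

    # subset re-runs mirroring the tissue/age imbalance diagnostics
    subsets = {
        "juveniles_only": table[table.get("age_class") == "juvenile"],
        "blood_only": table[table.get("tissue") == "blood"],
        "muscle_organ_only": table[table.get("tissue").isin(["muscle", "internal_organ"])]
        if "tissue" in table.columns
        else table.iloc[0:0],
    }
    report["subsets"] = {}
    for name, sub in subsets.items():
        entry: dict = {"n": int(len(sub))}
        for f in ["age_class", "tissue", "island"]:
            if f == "tissue" and name in ("blood_only",):
                continue
            if f in sub.columns and sub[f].nunique() >= 2 and len(sub.dropna(subset=[f])) > sub[f].nunique():
                try:
                    sf = fit_model(sub, response, [f])
                    if sf.terms:
                        tab = anova_sequential(sf)
                        entry[f"anova_{f}"] = _df_records(tab)
                except (ValueError, KeyError):
                    pass
        report["subsets"][name] = entry
    return report
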