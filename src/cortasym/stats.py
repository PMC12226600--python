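"""Cross-sectional, longitudinal and correlation inference on the cohort table.

The module follows the statsmodels convention: a model object is built
from a cohort :class:`~pandas.DataFrame` and ``fit()`` returns a results
object carrying estimates, uncertainties and a ``summary()`` table.  Thin
functional wrappers (:func:`group_comparison`, :func:`longitudinal_model`,
:func:`spearman_associations`, :func:`biomarker_group_comparison`) expose
the same computations for script use.

Analyses implemented:

* **Group comparison** — ANCOVA: a linear model ``outcome ~ group +
  covariates`` (age-adjusted by default), an omnibus F-test on the group
  factor, and Tukey HSD on the covariate-adjusted group means using the
  model's residual variance and the studentized-range distribution.
* **Longitudinal change** — per-group linear mixed-effects model with a
  random intercept per subject; the time-varying age-at-MRI fixed effect
  carries the within-subject change between visits.  Sex and (for patient
  groups) age of onset enter as fixed effects.
* **Spearman associations** — rank correlations with pairwise deletion of
  missing values, for small-sample biomarker/cognition links.
* **Biomarker group contrasts** — per-biomarker one-way ANOVA plus
  pairwise Welch tests with Benjamini-Hochberg adjustment, the layout of a
  clinical Table 1.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05

__all__ = [
    "GroupComparisonModel",
    "GroupComparisonResults",
    "LongitudinalModel",
    "LongitudinalResults",
    "CorrelationResult",
    "group_comparison",
    "longitudinal_model",
    "spearman_associations",
    "biomarker_group_comparison",
]


def _check_groups(table: pd.DataFrame, groups: str, outcome: str) -> list[str]:
    counts = table.groupby(groups)[outcome].count()
    small = counts[counts < 2]
    if len(counts) < 2:
        raise ValueError("group comparison needs at least two groups")
    if len(small):
        raise ValueError(
            f"groups with fewer than 2 observations: {list(small.index)}"
        )
    if np.isclose(table[outcome].var(ddof=1), 0):
        raise ValueError(f"outcome {outcome!r} has zero variance")
    return list(counts.index)


@dataclass
class GroupComparisonResults:
    """ANCOVA omnibus + Tukey-adjusted pairwise contrasts."""

    model: str
    outcome: str
    groups: str
    omnibus_f: float
    omnibus_p: float
    df_resid: float
    # rows: group_a, group_b, difference (b - a, covariate-adjusted), se, p_tukey
    pairwise: pd.DataFrame = field(repr=False)
    adjusted_means: pd.Series = field(repr=False)

    def summary(self) -> str:
        lines = [
            f"Group comparison: {self.model}",
            f"Omnibus F({self.groups}) = {self.omnibus_f:.3f}, p = {self.omnibus_p:.3g}",
            "",
            self.pairwise.to_string(index=False),
        ]
        return "\n".join(lines)


class GroupComparisonModel:
    """ANCOVA with Tukey HSD on covariate-adjusted group means.

    Parameters
    ----------
    table : DataFrame
        Cohort table, baseline rows only.
    outcome, groups : str
        Outcome column and the grouping factor.
    covariates : sequence of str
        Additional model terms (default: age at MRI).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        outcome: str = "cai",
        groups: str = "group",
        covariates: Sequence[str] = ("age_at_mri",),
    ) -> None:
        cols = [outcome, groups, *covariates]
        self.data = table[cols].dropna().copy()
        self.outcome = outcome
        self.groups = groups
        self.covariates = tuple(covariates)
        self.levels = _check_groups(self.data, groups, outcome)

    def fit(self) -> GroupComparisonResults:
        terms = " + ".join([f"C({self.groups})", *self.covariates])
        formula = f"{self.outcome} ~ {terms}"
        fit = smf.ols(formula, data=self.data).fit()
        anova = sm.stats.anova_lm(fit, typ=2)
        omnibus_f = float(anova.loc[f"C({self.groups})", "F"])
        omnibus_p = float(anova.loc[f"C({self.groups})", "PR(>F)"])

        k = len(self.levels)
        names = list(fit.params.index)
        cov = fit.cov_params().to_numpy()
        params = fit.params.to_numpy()

        def effect_vector(level: str) -> np.ndarray:
            v = np.zeros(len(names))
            label = f"C({self.groups})[T.{level}]"
            if label in names:
                v[names.index(label)] = 1.0
            return v

        rows = []
        for a, b in itertools.combinations(self.levels, 2):
            L = effect_vector(b) - effect_vector(a)
            diff = float(L @ params)
            se = float(np.sqrt(L @ cov @ L))
            q = abs(diff) / se * np.sqrt(2.0)
            p = float(sps.studentized_range.sf(q, k, fit.df_resid))
            rows.append({"group_a": a, "group_b": b, "difference": diff, "se": se, "p_tukey": p})
        pairwise = pd.DataFrame(rows)

        # adjusted means: prediction at covariate means
        cov_means = {c: self.data[c].mean() for c in self.covariates if np.issubdtype(self.data[c].dtype, np.number)}
        adj = {}
        for level in self.levels:
            pred_row = {self.groups: level, **cov_means}
            for c in self.covariates:
                if c not in cov_means:  # categorical covariate: use modal level
                    pred_row[c] = self.data[c].mode().iloc[0]
            adj[level] = float(fit.predict(pd.DataFrame([pred_row])).iloc[0])
        return GroupComparisonResults(
            model=formula,
            outcome=self.outcome,
            groups=self.groups,
            omnibus_f=omnibus_f,
            omnibus_p=omnibus_p,
            df_resid=float(fit.df_resid),
            pairwise=pairwise,
            adjusted_means=pd.Series(adj),
        )


def group_comparison(
    table: pd.DataFrame,
    outcome: str = "cai",
    groups: str = "group",
    covariates: Sequence[str] = ("age_at_mri",),
) -> GroupComparisonResults:
    """ANCOVA (F-test on the group factor, adjusted for covariates) + Tukey HSD."""
    return GroupComparisonModel(table, outcome, groups, covariates).fit()


@dataclass
class LongitudinalResults:
    """Mixed-model fixed effects for one clinical group."""

    group: str
    model: str
    fixed_effects: pd.DataFrame = field(repr=False)  # term, estimate, se, p
    n_subjects: int = 0
    n_observations: int = 0
    converged: bool = True
    singular: bool = False

    @property
    def age_effect(self) -> tuple[float, float, float]:
        row = self.fixed_effects.loc[self.fixed_effects["term"] == "age_at_mri"].iloc[0]
        return float(row["estimate"]), float(row["se"]), float(row["p"])

    def summary(self) -> str:
        flags = []
        if not self.converged:
            flags.append("NOT CONVERGED")
        if self.singular:
            flags.append("singular random-effect variance")
        head = f"Longitudinal mixed model [{self.group}]: {self.model}"
        if flags:
            head += f"  ({'; '.join(flags)})"
        return head + "\n" + self.fixed_effects.to_string(index=False)


class LongitudinalModel:
    """Random-intercept mixed model of within-subject change for one group.

    The cohort table must contain repeated rows per subject (visits); the
    outcome is regressed on the time-varying age at MRI plus sex and, for
    patient groups, age of onset.  The age-at-MRI estimate quantifies
    change between visits.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        group: str,
        outcome: str = "cai",
        include_onset: bool | None = None,
        visit_interaction: bool = False,
    ) -> None:
        sub = table[table["group"] == group].copy() if "group" in table else table.copy()
        if include_onset is None:
            include_onset = group != "CTR"
        terms = ["age_at_mri", "sex"]
        if include_onset:
            terms.append("age_of_onset")
        cols = ["subject_id", "visit", outcome, *[t for t in terms if t != "sex"], "sex"]
        sub = sub[list(dict.fromkeys(cols))].dropna()
        if not (sub.groupby("subject_id")["visit"].nunique() > 1).any():
            raise ValueError(f"no subject in group {group!r} has more than one visit")
        self.data = sub
        self.group = group
        self.outcome = outcome
        self.terms = terms
        self.visit_interaction = visit_interaction

    def fit(self) -> LongitudinalResults:
        rhs = " + ".join(self.terms)
        if self.visit_interaction:
            rhs += " + age_at_mri:C(visit)"
        formula = f"{self.outcome} ~ {rhs}"
        # centre numeric covariates: harmless for the slopes, necessary for a
        # well-conditioned profile likelihood at age-in-years scale
        data = self.data.copy()
        for term in self.terms:
            if term in data.columns and np.issubdtype(data[term].dtype, np.number):
                data[term] = data[term] - data[term].mean()
        model = smf.mixedlm(formula, data=data, groups=data["subject_id"])
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                fit = model.fit(reml=True, method=["lbfgs", "powell"])
            except np.linalg.LinAlgError:
                fit = model.fit(reml=True, method="powell")
        singular = any("singular" in str(w.message).lower() or "boundary" in str(w.message).lower() for w in caught)
        if float(np.asarray(fit.cov_re).ravel()[0]) <= 1e-10:
            singular = True
        fe = fit.fe_params
        rows = []
        for term in fe.index:
            rows.append(
                {
                    "term": term,
                    "estimate": float(fe[term]),
                    "se": float(fit.bse_fe[term]),
                    "p": float(fit.pvalues[term]),
                }
            )
        return LongitudinalResults(
            group=self.group,
            model=formula + " + (1 | subject)",
            fixed_effects=pd.DataFrame(rows),
            n_subjects=int(self.data["subject_id"].nunique()),
            n_observations=int(len(self.data)),
            converged=bool(fit.converged),
            singular=singular,
        )


def longitudinal_model(
    table: pd.DataFrame, group: str, outcome: str = "cai", **kwargs
) -> LongitudinalResults:
    """Fit the per-group random-intercept mixed model of the outcome over visits."""
    return LongitudinalModel(table, group, outcome, **kwargs).fit()


@dataclass
class CorrelationResult:
    """Spearman rank correlation for one variable pair."""

    x: str
    y: str
    rho: float
    p: float | None
    n: int
    insufficient: bool = False


def spearman_associations(
    table: pd.DataFrame, x_columns: Sequence[str], y_column: str, min_n: int = 4
) -> list[CorrelationResult]:
    """Spearman rho between each x column and y, with pairwise deletion.

    Pairs with fewer than ``min_n`` complete observations are flagged as
    insufficient and carry no p-value.
    """
    results = []
    for x in x_columns:
        pair = table[[x, y_column]].dropna()
        n = len(pair)
        if n < min_n:
            results.append(CorrelationResult(x=x, y=y_column, rho=float("nan"), p=None, n=n, insufficient=True))
            continue
        rho, p = sps.spearmanr(pair[x], pair[y_column])
        results.append(CorrelationResult(x=x, y=y_column, rho=float(rho), p=float(p), n=n))
    return results


def biomarker_group_comparison(
    table: pd.DataFrame,
    biomarker_columns: Sequence[str],
    groups: str = "group",
) -> pd.DataFrame:
    """Per-biomarker one-way ANOVA + BH-adjusted pairwise contrasts.

    Returns a tidy frame with one row per biomarker and group pair:
    ``biomarker, omnibus_p, group_a, group_b, p_raw, p_bh``.  The BH
    adjustment is applied across the pairwise family within each
    biomarker.  A biomarker with no usable data is skipped with a warning.
    """
    out_rows = []
    for marker in biomarker_columns:
        if marker not in table.columns:
            warnings.warn(f"biomarker column {marker!r} absent; skipped")
            continue
        sub = table[[groups, marker]].dropna()
        counts = sub.groupby(groups)[marker].count()
        usable = counts[counts >= 2]
        if len(usable) < 2:
            warnings.warn(f"biomarker {marker!r} lacks two groups with data; skipped")
            continue
        levels = list(usable.index)
        samples = [sub.loc[sub[groups] == g, marker].to_numpy() for g in levels]
        if all(np.allclose(s, s[0]) for s in samples):
            warnings.warn(f"biomarker {marker!r} has zero variance; skipped")
            continue
        omnibus = sps.f_oneway(*samples)
        pairs = list(itertools.combinations(range(len(levels)), 2))
        raw = []
        for i, j in pairs:
            t = sps.ttest_ind(samples[i], samples[j], equal_var=False)
            raw.append(float(t.pvalue))
        adj = multipletests(raw, method="fdr_bh")[1]
        for (i, j), p_raw, p_bh in zip(pairs, raw, adj):
            out_rows.append(
                {
                    "biomarker": marker,
                    "omnibus_p": float(omnibus.pvalue),
                    "group_a": levels[i],
                    "group_b": levels[j],
                    "p_raw": p_raw,
                    "p_bh": float(p_bh),
                }
            )
    return pd.DataFrame(out_rows, columns=["biomarker", "omnibus_p", "group_a", "group_b", "p_raw", "p_bh"])
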