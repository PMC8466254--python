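"""Descriptive and inferential statistics for implant-deviation tables.

Mirrors the analysis plan of a typical guided-surgery accuracy study:
mean ± SD and range per group, two-sample t tests (pooled Student by
default, Welch by flag), one-way ANOVA with Tukey-Kramer multiple
comparisons for three-level factors, and an unbalanced multi-way factorial
ANOVA with interactions using type-III (partial) sums of squares under
sum-to-zero contrasts.  Consistency arithmetic (count-weighted pooling of
subgroup means) and the standard two-group t-test sample-size calculation
round out the layer.

Standard machinery is delegated: t tests and distributions to scipy.stats,
the factorial linear model to statsmodels OLS/anova_lm, quartiles to
numpy's linear-interpolation quantiles.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError

__all__ = [
    "GroupSummary",
    "TestResult",
    "AnovaTable",
    "describe",
    "two_sample_t",
    "one_way_anova",
    "tukey_kramer",
    "factorial_anova",
    "pooled_mean",
    "sample_size_two_group_t",
]


@dataclass(frozen=True)
class GroupSummary:
    """Descriptives of one group: n, mean ± SD, range, quartiles."""

    n: int
    mean: float
    sd: float
    min: float
    max: float
    q1: float
    median: float
    q3: float

    def __str__(self) -> str:
        return (
            f"n={self.n}  {self.mean:.2f} ± {self.sd:.2f}  "
            f"(range {self.min:.2f}–{self.max:.2f}, "
            f"quartiles {self.q1:.2f}/{self.median:.2f}/{self.q3:.2f})"
        )


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple
    p_value: float
    method: str


@dataclass(frozen=True)
class AnovaTable:
    """Per-term decomposition: name, sum of squares, df, F, p; residual last."""

    terms: pd.DataFrame  # columns: term, sum_sq, df, F, p

    def term(self, name: str) -> pd.Series:
        match = self.terms[self.terms["term"] == name]
        if match.empty:
            raise KeyError(f"no term {name!r}; have {list(self.terms['term'])}")
        return match.iloc[0]

    @property
    def residual(self) -> pd.Series:
        return self.terms.iloc[-1]


def describe(values) -> GroupSummary:
    """Mean, sample SD (n-1), range and linear-interpolation quartiles."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ConfigError("cannot describe an empty sample")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # linear interpolation
    return GroupSummary(
        n=int(x.size),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        min=float(x.min()),
        max=float(x.max()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
    )


def two_sample_t(a, b, variant: str = "pooled") -> TestResult:
    """Two-sided two-sample t test from raw samples or (mean, sd, n) summaries.

    ``variant='pooled'`` is the classic Student test (df = n1 + n2 - 2);
    ``'welch'`` uses the Satterthwaite df.  Summary-statistic inputs give
    results identical to raw samples with matching moments.  Two groups with
    zero variance and equal means return t = 0, p = 1 by convention.
    """
    if variant not in ("pooled", "welch"):
        raise ConfigError(f"t-test variant must be 'pooled' or 'welch', got {variant!r}")
    equal_var = variant == "pooled"

    def as_summary(g):
        if isinstance(g, tuple) and len(g) == 3:
            mean, sd, n = g
            if n < 2:
                raise ConfigError("each group needs n >= 2")
            if sd < 0:
                raise ConfigError("sd must be >= 0")
            return float(mean), float(sd), int(n)
        x = np.asarray(g, dtype=float)
        if x.size < 2:
            raise ConfigError("each group needs n >= 2")
        return float(x.mean()), float(x.std(ddof=1)), int(x.size)

    m1, s1, n1 = as_summary(a)
    m2, s2, n2 = as_summary(b)
    if s1 == 0.0 and s2 == 0.0:
        if m1 == m2:
            df = n1 + n2 - 2 if equal_var else float(n1 + n2 - 2)
            return TestResult(0.0, df, 1.0, f"two-sample t ({variant})")
        raise ConfigError("both groups have zero variance with unequal means")
    res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=equal_var)
    if equal_var:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TestResult(
        statistic=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        method=f"two-sample t ({variant})",
    )


def _check_groups(groups: Sequence) -> list:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ConfigError("need at least 2 groups")
    for i, g in enumerate(gs):
        if g.size < 2:
            raise ConfigError(f"group {i} has n < 2")
    return gs


def one_way_anova(groups: Sequence) -> AnovaTable:
    """Classic between/within sum-of-squares decomposition with F and p."""
    gs = _check_groups(groups)
    all_x = np.concatenate(gs)
    grand = all_x.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b = len(gs) - 1
    df_w = all_x.size - len(gs)
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    F = ms_b / ms_w if ms_w > 0 else (0.0 if ms_b == 0 else np.inf)
    p = float(sps.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    terms = pd.DataFrame(
        {
            "term": ["between", "residual"],
            "sum_sq": [ss_between, ss_within],
            "df": [df_b, df_w],
            "F": [F, np.nan],
            "p": [p, np.nan],
        }
    )
    return AnovaTable(terms=terms)


def tukey_kramer(groups: Sequence, labels: Sequence[str] | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons (studentized range, unequal n).

    For each pair the statistic is q = |mean_i - mean_j| /
    sqrt(MSW/2 * (1/n_i + 1/n_j)) referred to the studentized-range
    distribution with k groups and the within-group df.  Returns a frame
    with one row per pair: group_1, group_2, diff, p, significant.
    """
    gs = _check_groups(groups)
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(gs))]
    k = len(gs)
    df_w = sum(g.size for g in gs) - k
    msw = sum(((g - g.mean()) ** 2).sum() for g in gs) / df_w
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = gs[j].mean() - gs[i].mean()
        se = math.sqrt(msw / 2.0 * (1.0 / gs[i].size + 1.0 / gs[j].size))
        q = abs(diff) / se if se > 0 else np.inf
        p = float(sps.studentized_range.sf(q, k, df_w)) if np.isfinite(q) else 0.0
        rows.append(
            {
                "group_1": labels[i],
                "group_2": labels[j],
                "diff": diff,
                "p": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)


def factorial_anova(
    table: pd.DataFrame,
    outcome: str,
    factors: Sequence[str],
    include_interactions: bool = True,
) -> AnovaTable:
    """Unbalanced factorial ANOVA with type-III SS, sum-to-zero contrasts.

    Fits an OLS linear model of ``outcome`` on the categorical ``factors``
    with all two-way and the highest-order interaction when
    ``include_interactions`` is set, and reports partial (type III) sums of
    squares — the convention under which each term is adjusted for every
    other, appropriate for unbalanced designs.  Interaction terms that are
    inestimable because of empty cells are dropped with a warning.
    """
    import warnings

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for f in factors:
        if f not in table.columns:
            raise ConfigError(f"factor {f!r} not in table columns {list(table.columns)}")
        nlev = table[f].nunique()
        if nlev < 2:
            raise ConfigError(f"factor {f!r} has {nlev} observed level(s); need >= 2")
    if outcome not in table.columns:
        raise ConfigError(f"outcome {outcome!r} not in table")

    # rename columns to formula-safe identifiers (user factor names may
    # collide with patsy built-ins or contain spaces)
    safe = {f: f"_f{i}" for i, f in enumerate(factors)}
    back = {f"C({v}, Sum)": k for k, v in safe.items()}
    data = table[[outcome, *factors]].rename(columns={outcome: "_y", **safe})
    mains = [f"C({safe[f]}, Sum)" for f in factors]
    terms = list(mains)
    if include_interactions and len(factors) > 1:
        for r in range(2, len(factors) + 1):
            for combo in itertools.combinations(range(len(factors)), r):
                cols = [safe[factors[i]] for i in combo]
                # drop interactions with empty cells (inestimable)
                observed = data.groupby(cols, observed=True).size()
                full = np.prod([data[c].nunique() for c in cols])
                if len(observed) < full:
                    names = [factors[i] for i in combo]
                    warnings.warn(
                        f"interaction {':'.join(names)} dropped: empty cells", stacklevel=2
                    )
                    continue
                terms.append(":".join(mains[i] for i in combo))
    formula = "_y ~ " + " + ".join(terms)
    model = smf.ols(formula, data=data).fit()
    aov = sm.stats.anova_lm(model, typ=3)

    rows = []
    for name, row in aov.iterrows():
        if name == "Intercept":
            continue
        clean = ":".join(back.get(part, part) for part in str(name).split(":"))
        rows.append(
            {
                "term": "residual" if name == "Residual" else clean,
                "sum_sq": float(row["sum_sq"]),
                "df": float(row["df"]),
                "F": float(row["F"]) if np.isfinite(row.get("F", np.nan)) else np.nan,
                "p": float(row["PR(>F)"]) if np.isfinite(row.get("PR(>F)", np.nan)) else np.nan,
            }
        )
    return AnovaTable(terms=pd.DataFrame(rows))


def pooled_mean(subgroups: Sequence[tuple], round_2dp: bool = False) -> float:
    """Implant-count-weighted mean of subgroup means: sum(n*m)/sum(n).

    The consistency check for published tables: a marginal row's mean must
    equal the weighted mean of its subgroup rows.  ``round_2dp`` applies the
    2-decimal rounding used when comparing against printed values.
    """
    if not subgroups:
        raise ConfigError("pooled_mean needs at least one (mean, n) pair")
    means = np.array([m for m, _ in subgroups], dtype=float)
    ns = np.array([n for _, n in subgroups], dtype=float)
    if np.any(ns < 1):
        raise ConfigError("all subgroup counts must be >= 1")
    value = float((means * ns).sum() / ns.sum())
    return round(value, 2) if round_2dp else value


def _two_group_power(n: int, d: float, alpha: float) -> float:
    """Exact power of the two-sided pooled t test at equal n per group."""
    df = 2 * n - 2
    nc = d * math.sqrt(n / 2.0)
    tcrit = sps.t.ppf(1 - alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def sample_size_two_group_t(effect_size_d: float, power: float, alpha: float) -> int:
    """Smallest equal n per group giving the two-sided t test >= target power.

    Uses the exact noncentral-t power function; ``effect_size_d`` is Cohen's
    d (mean difference over common SD).
    """
    if effect_size_d <= 0:
        raise ConfigError("effect size must be > 0")
    if not (0.0 < power < 1.0) or not (0.0 < alpha < 1.0):
        raise ConfigError("power and alpha must lie in (0, 1)")
    n = 2
    while _two_group_power(n, effect_size_d, alpha) < power:
        n += 1
        if n > 10_000_000:  # pragma: no cover - guard against pathological input
            raise ConfigError("required sample size exceeds 1e7")
    return n
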