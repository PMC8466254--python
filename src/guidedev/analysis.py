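"""Cohort-level analysis: descriptives, group tests, factorial ANOVA, flags.

Reproduces the analysis plan of a guided-surgery accuracy study on a
deviation table: per-factor group summaries of the six metrics, two-sample
t tests for two-level factors, one-way ANOVA with Tukey-Kramer pairwise
comparisons for factors with three or more levels, a multi-way type-III
factorial ANOVA over the jointly significant factors, and counts of
safety-margin violations.  No multiplicity correction is applied across the
six outcome metrics by default (the study convention); a Bonferroni flag is
available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigError
from .geometry import METRIC_COLUMNS, DeviationRecord, safety_flags
from .stats import AnovaTable, describe, factorial_anova, one_way_anova, tukey_kramer, two_sample_t

__all__ = ["CohortAnalysis", "analyze_cohort", "safety_flag_counts"]

log = logging.getLogger(__name__)


@dataclass
class CohortAnalysis:
    """Container for everything :func:`analyze_cohort` computes."""

    summaries: pd.DataFrame              # factor, level, metric, n, mean, sd, ...
    tests: pd.DataFrame                  # factor, metric, method, statistic, p
    tukey: pd.DataFrame                  # factor, metric, pairwise rows
    factorial: dict = field(default_factory=dict)  # metric -> AnovaTable
    flag_counts: pd.DataFrame | None = None


def safety_flag_counts(frame: pd.DataFrame, lateral_margin_mm: float = 2.0, depth_margin_mm: float = 2.0) -> pd.DataFrame:
    """Count implants whose deviations exceed the safety margins."""
    counts: dict[str, int] = {}
    for _, row in frame.iterrows():
        rec = DeviationRecord(**{c: row[c] for c in METRIC_COLUMNS})
        for name, flagged in safety_flags(rec, lateral_margin_mm, depth_margin_mm).items():
            counts[name] = counts.get(name, 0) + int(flagged)
    out = pd.DataFrame(
        {"flag": list(counts.keys()), "n_exceeding": list(counts.values())}
    )
    out["n_total"] = len(frame)
    return out


def analyze_cohort(
    frame: pd.DataFrame,
    factors: list[str] | None = None,
    t_variant: str = "pooled",
    alpha: float = 0.05,
    bonferroni: bool = False,
    lateral_margin_mm: float = 2.0,
    depth_margin_mm: float = 2.0,
) -> CohortAnalysis:
    """Full statistical pass over a deviation table.

    ``factors`` defaults to every non-metric column.  Two-level factors get
    a two-sample t test per metric; factors with >= 3 levels get one-way
    ANOVA plus Tukey-Kramer pairwise comparisons.  Factors found significant
    for at least one metric then enter a joint factorial ANOVA with
    interactions (when at least two such factors exist and each has >= 2
    levels).  With a single observed group only descriptives are produced.
    """
    if factors is None:
        factors = [c for c in frame.columns if c not in METRIC_COLUMNS]
    for f in factors:
        if f not in frame.columns:
            available = [c for c in frame.columns if c not in METRIC_COLUMNS]
            raise ConfigError(f"unknown factor {f!r}; available factors: {available}")

    alpha_eff = alpha / len(METRIC_COLUMNS) if bonferroni else alpha

    sum_rows, test_rows, tukey_rows = [], [], []
    significant_factors: list[str] = []
    for factor in factors:
        levels = sorted(frame[factor].dropna().unique())
        for metric in METRIC_COLUMNS:
            groups = [frame.loc[frame[factor] == lev, metric].to_numpy() for lev in levels]
            for lev, g in zip(levels, groups):
                s = describe(g)
                sum_rows.append(
                    {"factor": factor, "level": lev, "metric": metric, **vars(s)}
                )
            if len(levels) < 2:
                log.warning("factor %r has a single level: descriptives only", factor)
                continue
            if any(len(g) < 2 for g in groups):
                log.warning("factor %r: a level has n < 2, tests skipped", factor)
                continue
            if len(levels) == 2:
                res = two_sample_t(groups[0], groups[1], variant=t_variant)
                test_rows.append(
                    {
                        "factor": factor,
                        "metric": metric,
                        "method": res.method,
                        "statistic": res.statistic,
                        "p": res.p_value,
                    }
                )
                if res.p_value < alpha_eff:
                    significant_factors.append(factor)
            else:
                aov = one_way_anova(groups)
                row = aov.term("between")
                test_rows.append(
                    {
                        "factor": factor,
                        "metric": metric,
                        "method": "one-way ANOVA",
                        "statistic": row["F"],
                        "p": row["p"],
                    }
                )
                if row["p"] < alpha_eff:
                    significant_factors.append(factor)
                tk = tukey_kramer(groups, labels=[str(l) for l in levels], alpha=alpha_eff)
                tk.insert(0, "metric", metric)
                tk.insert(0, "factor", factor)
                tukey_rows.append(tk)

    significant_factors = sorted(set(significant_factors))
    factorial: dict[str, AnovaTable] = {}
    if len(significant_factors) >= 2:
        for metric in METRIC_COLUMNS:
            factorial[metric] = factorial_anova(
                frame, metric, significant_factors, include_interactions=True
            )

    return CohortAnalysis(
        summaries=pd.DataFrame(sum_rows),
        tests=pd.DataFrame(test_rows),
        tukey=pd.concat(tukey_rows, ignore_index=True) if tukey_rows else pd.DataFrame(),
        factorial=factorial,
        flag_counts=safety_flag_counts(frame, lateral_margin_mm, depth_margin_mm),
    )
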