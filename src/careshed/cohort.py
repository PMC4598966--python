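"""Eligibility filtering and between-region comparison statistics.

Cohort membership is gated on the WHODAS 2.0 self-care domain score (0-100,
higher = more severe dysfunction): participants at or above the population
mean score qualify.  Region comparisons use the Pearson chi-square on r x 2
contingency tables (no continuity correction), Fisher's exact test when
expected cells are small, and two-sample t statistics computed from printed
summary statistics (pooled-variance by default, Welch as a variant).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .points import ValidationError

#: Self-care domain score at/above which a record qualifies (the population
#: mean in the motivating cohort).
DEFAULT_SELF_CARE_THRESHOLD = 39.93

#: Conventional minimum expected cell count below which Fisher's exact test
#: replaces the chi-square on 2x2 tables.
MIN_EXPECTED_FOR_CHI2 = 5.0


def filter_eligible(
    records: pd.DataFrame,
    score_column: str = "self_care_score",
    threshold: float = DEFAULT_SELF_CARE_THRESHOLD,
) -> pd.DataFrame:
    """Keep records whose self-care score is >= threshold.

    Scores must lie in [0, 100]; anything outside is a data error, not a
    filterable value.
    """
    if score_column not in records.columns:
        raise ValidationError(f"records lack a {score_column!r} column")
    scores = records[score_column].to_numpy(dtype=float)
    bad = (scores < 0) | (scores > 100) | ~np.isfinite(scores)
    if bad.any():
        raise ValidationError(
            f"{int(bad.sum())} score(s) outside [0, 100] in {score_column!r}"
        )
    return records.loc[scores >= threshold].copy()


@dataclass(frozen=True)
class TestResult:
    """A test statistic with degrees of freedom, p-value, and a method tag."""

    statistic: float
    df: float
    p_value: float
    method: str

    @property
    def stars(self) -> str:
        """Significance stars at 0.05 / 0.01 / 0.001."""
        if self.p_value < 0.001:
            return "***"
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            # 4 significant figures, matching the report convention
            "p_value": float(f"{self.p_value:.4g}"),
            "method": self.method,
            "stars": self.stars,
        }


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValidationError(f"contingency table must be at least 2x2, got {t.shape}")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValidationError("contingency cells must be finite and nonnegative")
    return t


def expected_counts(table) -> np.ndarray:
    """Expected cell counts under independence (row total x col total / n)."""
    t = _as_table(table)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValidationError("zero row or column marginal; expected counts undefined")
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()


def pearson_chi2(table) -> TestResult:
    """Pearson chi-square, Sum (O-E)^2/E, without continuity correction."""
    t = _as_table(table)
    expected_counts(t)  # validates marginals
    stat, p, df, _ = stats.chi2_contingency(t, correction=False)
    return TestResult(float(stat), float(df), float(p), "pearson-chi2")


def fisher_exact_2x2(table) -> TestResult:
    """Fisher's exact test on a 2x2 table, two-sided (probability ordering).

    The p-value sums hypergeometric probabilities of all tables with the same
    margins that are no more probable than the observed one.  The "statistic"
    reported is the sample odds ratio; df is not applicable and set to 1.
    """
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ValidationError(f"Fisher's exact test requires a 2x2 table, got {t.shape}")
    if not np.allclose(t, np.round(t)):
        raise ValidationError("Fisher's exact test requires integer cell counts")
    odds, p = stats.fisher_exact(np.round(t).astype(int), alternative="two-sided")
    return TestResult(float(odds), 1.0, float(p), "fisher-exact")


def association_test(table) -> TestResult:
    """Chi-square, switching to Fisher's exact on 2x2 tables with small cells.

    Fisher's exact is used when the table is 2x2 and any expected cell count
    falls below 5 (the conventional trigger); otherwise the uncorrected
    Pearson chi-square is reported.
    """
    t = _as_table(table)
    e = expected_counts(t)
    if t.shape == (2, 2) and np.any(e < MIN_EXPECTED_FOR_CHI2):
        return fisher_exact_2x2(t)
    return pearson_chi2(t)


@dataclass(frozen=True)
class SummaryStatPair:
    """Mean, SD and n for two groups, as printed in a summary table."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int

    def __post_init__(self) -> None:
        if self.sd_a < 0 or self.sd_b < 0:
            raise ValidationError("standard deviations must be nonnegative")
        if self.n_a < 2 or self.n_b < 2:
            raise ValidationError("each group needs n >= 2")


def two_sample_t(pair: SummaryStatPair, variant: str = "pooled") -> TestResult:
    """Two-sample t statistic from summary statistics.

    ``variant="pooled"`` uses the df-weighted pooled variance with
    df = n_a + n_b - 2; ``variant="welch"`` uses the Welch-Satterthwaite
    statistic and df.  A degenerate case (both SDs zero) yields t = 0 when
    the means agree and an error otherwise.
    """
    if variant not in ("pooled", "welch"):
        raise ValidationError(f"unknown t-test variant {variant!r}")
    if pair.sd_a == 0 and pair.sd_b == 0:
        if pair.mean_a == pair.mean_b:
            df = pair.n_a + pair.n_b - 2
            return TestResult(0.0, float(df), 1.0, f"t-{variant}")
        raise ValidationError("zero variance in both groups with unequal means")
    res = stats.ttest_ind_from_stats(
        pair.mean_a, pair.sd_a, pair.n_a,
        pair.mean_b, pair.sd_b, pair.n_b,
        equal_var=(variant == "pooled"),
    )
    if variant == "pooled":
        df = float(pair.n_a + pair.n_b - 2)
    else:
        va, vb = pair.sd_a**2 / pair.n_a, pair.sd_b**2 / pair.n_b
        df = (va + vb) ** 2 / (va**2 / (pair.n_a - 1) + vb**2 / (pair.n_b - 1))
    return TestResult(float(res.statistic), float(df), float(res.pvalue), f"t-{variant}")


def compare_report(
    contingency: Optional[dict] = None,
    summaries: Optional[dict] = None,
    t_variant: str = "pooled",
) -> dict:
    """Cohort-comparison report over named contingency tables and summary pairs.

    ``contingency`` maps a variable name to an r x 2 table (list/array);
    ``summaries`` maps a variable name to a SummaryStatPair.  Categorical
    variables go through :func:`association_test`; continuous summaries
    through :func:`two_sample_t` with the stated variant (labelled in the
    output).
    """
    out: dict = {"schema_version": 1, "categorical": {}, "continuous": {}}
    for name, table in (contingency or {}).items():
        out["categorical"][name] = association_test(table).to_dict()
    for name, pair in (summaries or {}).items():
        out["continuous"][name] = two_sample_t(pair, t_variant).to_dict()
    return out


def format_report_text(report: dict) -> str:
    """Plain-text rendering of a comparison report with significance stars."""
    lines = [f"{'variable':<40} {'statistic':>10} {'df':>7} {'p':>10}  method"]
    for kind in ("categorical", "continuous"):
        for name, r in report.get(kind, {}).items():
            lines.append(
                f"{name:<40} {r['statistic']:>10.4g} {r['df']:>7.4g} "
                f"{r['p_value']:>10.4g}{r['stars']:<3} {r['method']}"
            )
    return "\n".join(lines)
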