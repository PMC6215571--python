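"""Cohort arithmetic and group-level statistics.

Gestational age is conventionally written "weeks + days" (e.g. ``27+6``);
postconceptional age at surgery is the gestational age at birth plus the
postnatal age in days.  Group differences in the two expression statistics
are assessed with a two-sided two-sample t-test (pooled variance by default,
Welch available), and within-group association with maturation by the sample
Pearson correlation against age expressed in decimal weeks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, UndefinedCorrelationError

__all__ = [
    "GestationalAge",
    "CohortRecord",
    "GroupComparison",
    "GroupReport",
    "ga_add_days",
    "ga_to_decimal_weeks",
    "two_sample_ttest",
    "pearson_correlation",
    "compare_groups",
]


@dataclass(frozen=True, order=True)
class GestationalAge:
    """Age as completed weeks plus remaining days (0-6)."""

    weeks: int
    days: int = 0

    def __post_init__(self) -> None:
        if self.weeks < 0 or not (0 <= self.days <= 6):
            raise ValueError(f"invalid gestational age {self.weeks}+{self.days}")

    @property
    def total_days(self) -> int:
        return 7 * self.weeks + self.days

    @classmethod
    def from_total_days(cls, total: int) -> "GestationalAge":
        if total < 0:
            raise ValueError(f"total days must be >= 0, got {total}")
        return cls(total // 7, total % 7)

    @classmethod
    def from_string(cls, text: str) -> "GestationalAge":
        """Parse the conventional ``"27+6"`` notation."""
        w, _, d = text.partition("+")
        return cls(int(w.strip()), int(d.strip() or 0))

    def __str__(self) -> str:
        return f"{self.weeks}+{self.days}"


@dataclass(frozen=True)
class CohortRecord:
    """Per-patient metadata in the study-table schema."""

    patient_id: str
    group: str  # "NEC" | "control" (simulated cohorts may use *-like labels)
    tissue: str  # "ileum" | "jejunum" | "colon"
    ga_birth: GestationalAge
    birth_weight_g: float
    postnatal_age_days: int
    sex: str

    def __post_init__(self) -> None:
        if self.postnatal_age_days < 0:
            raise ValueError("postnatal age must be >= 0")
        if self.birth_weight_g <= 0:
            raise ValueError("birth weight must be > 0")

    @property
    def ga_surgery(self) -> GestationalAge:
        """Postconceptional age at surgery = birth GA + postnatal days."""
        return ga_add_days(self.ga_birth, self.postnatal_age_days)

    @property
    def is_case(self) -> bool:
        return "nec" in self.group.lower()


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-sample t-test between two groups."""

    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    df: float
    p: float
    variant: str
    flagged: bool = False  # set when a degenerate-variance convention applied


def ga_add_days(ga: GestationalAge, days: int) -> GestationalAge:
    """Add postnatal days to a gestational age, renormalizing to weeks+days."""
    if days < 0:
        raise ValueError(f"days to add must be >= 0, got {days}")
    return GestationalAge.from_total_days(ga.total_days + int(days))


def ga_to_decimal_weeks(ga: GestationalAge) -> float:
    """Gestational age as real-valued weeks (weeks + days / 7)."""
    return ga.weeks + ga.days / 7.0


def two_sample_ttest(a, b, variant: str = "pooled") -> GroupComparison:
    """Two-sided two-sample t-test between value lists *a* and *b*.

    ``variant="pooled"`` is the classic equal-variance test (the conventional
    spreadsheet two-sample choice); ``"welch"`` does not pool variances.
    With zero variance in both groups and equal means, ``p = 1`` by
    convention and the result is flagged.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError(
            f"each group needs >= 2 values, got {a.size} and {b.size}"
        )
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    base = dict(
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        variant=variant,
    )
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return GroupComparison(**base, t=0.0, df=df, p=1.0, flagged=True)
        t = np.inf if a.mean() > b.mean() else -np.inf
        return GroupComparison(**base, t=float(t), df=df, p=0.0, flagged=True)
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return GroupComparison(
        **base, t=float(res.statistic), df=float(res.df), p=float(res.pvalue)
    )


def pearson_correlation(x, y) -> float:
    """Sample Pearson correlation coefficient of two equally long lists."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise UndefinedCorrelationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise UndefinedCorrelationError(f"need >= 3 pairs, got {x.size}")
    if x.var() == 0 or y.var() == 0:
        raise UndefinedCorrelationError("correlation undefined for zero-variance data")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class GroupReport:
    """Tabular group-comparison report: t-tests plus per-group age correlations."""

    tests: pd.DataFrame
    correlations: pd.DataFrame

    def summary(self) -> str:
        lines = ["Group comparison (two-sided two-sample t-test)", "-" * 48]
        lines.append(self.tests.to_string(index=False))
        lines.append("")
        lines.append("Within-group Pearson correlations vs age (decimal weeks)")
        lines.append("-" * 48)
        lines.append(self.correlations.to_string(index=False))
        return "\n".join(lines)


_STATISTICS = ("expr_per_um", "pct_area")
_AGE_VARIABLES = ("ga_birth_weeks", "postconceptional_weeks")


def compare_groups(results, variant: str = "pooled") -> GroupReport:
    """Compare the two expression statistics between case and control groups.

    Parameters
    ----------
    results : list of (CohortRecord, ExpressionResult)
    variant : t-test variant ("pooled" or "welch").

    Runs the t-test on expression/um and percent DAB area, and computes each
    statistic's Pearson correlation with gestational age at birth and with
    postconceptional age at surgery, separately per group.  Correlations that
    are undefined (too few subjects, zero variance) are reported as NaN.
    """
    rows = []
    for record, res in results:
        rows.append(
            {
                "group": "NEC" if record.is_case else "control",
                "expr_per_um": res.expr_per_um,
                "pct_area": res.pct_area,
                "ga_birth_weeks": ga_to_decimal_weeks(record.ga_birth),
                "postconceptional_weeks": ga_to_decimal_weeks(record.ga_surgery),
            }
        )
    df = pd.DataFrame(rows)
    groups = set(df["group"])
    if groups != {"NEC", "control"}:
        raise InsufficientDataError(
            f"both a NEC-like and a control-like group are required, got {sorted(groups)}"
        )
    nec = df[df["group"] == "NEC"]
    ctl = df[df["group"] == "control"]

    test_rows = []
    for stat in _STATISTICS:
        cmp = two_sample_ttest(nec[stat], ctl[stat], variant=variant)
        test_rows.append(
            {
                "statistic": stat,
                "n_nec": cmp.n_a,
                "n_control": cmp.n_b,
                "mean_nec": cmp.mean_a,
                "mean_control": cmp.mean_b,
                "sd_nec": cmp.sd_a,
                "sd_control": cmp.sd_b,
                "t": cmp.t,
                "df": cmp.df,
                "p": cmp.p,
                "variant": cmp.variant,
            }
        )

    corr_rows = []
    for stat in _STATISTICS:
        for age_var in _AGE_VARIABLES:
            for gname, gdf in (("NEC", nec), ("control", ctl)):
                try:
                    r = pearson_correlation(gdf[age_var], gdf[stat])
                except UndefinedCorrelationError:
                    r = float("nan")
                corr_rows.append(
                    {
                        "statistic": stat,
                        "age_variable": age_var,
                        "group": gname,
                        "n": len(gdf),
                        "r": r,
                    }
                )
    return GroupReport(tests=pd.DataFrame(test_rows), correlations=pd.DataFrame(corr_rows))
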