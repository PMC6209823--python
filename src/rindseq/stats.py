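"""Contingency-table association statistics and viability formulas.

Two families of 2x2 Fisher's exact tests are produced from the per-sample
break summaries:

* repair-defect association — per sample, (MIB + OR<=1 breaks, OR>1
  breaks) against the same two counts in wild type: does a repair-impaired
  condition shift breaks toward the pathologic classes?
* MIB association — within one sample, (OR<=1, OR>1) among MIB reads
  against the same split among reads mapped from the first base: does
  insertion at the break end prefer one break class?

Each result carries the two-sided exact p-value, the cross-product odds
ratio (a*d)/(c*b), the conditional maximum-likelihood odds ratio (the
noncentral-hypergeometric MLE reported by standard exact-test software)
and an exact conditional 95% CI. Point estimates differ between the two
estimators in strongly unbalanced tables, which is why both are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .breaktypes import SampleBreakSummary

__all__ = [
    "ContingencyResult",
    "fisher_exact",
    "or_crossproduct",
    "table1_analysis",
    "table2_analysis",
    "pct_viability",
    "pct_difference",
    "read_viability_table",
    "compare_groups",
]


@dataclass
class ContingencyResult:
    """A 2x2 table (a b / c d) with exact-test statistics."""

    a: int
    b: int
    c: int
    d: int
    p_value: float
    or_crossproduct: float
    or_cmle: float
    ci95: tuple[float, float]
    degenerate: bool = False
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "sample": self.label,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "d": self.d,
            "p_value": self.p_value,
            "or_crossproduct": self.or_crossproduct,
            "or_cmle": self.or_cmle,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
            "degenerate": self.degenerate,
        }


def or_crossproduct(a: int, b: int, c: int, d: int) -> float:
    """(a*d)/(c*b), with the usual conventions at zero cells: 0 when the
    numerator alone is zero, +inf when the denominator alone is zero, NaN
    when both are."""
    num, den = a * d, c * b
    if den > 0:
        return num / den
    return math.nan if num == 0 else math.inf


def fisher_exact(a: int, b: int, c: int, d: int, label: str = "") -> ContingencyResult:
    """Two-sided Fisher's exact test on the table ((a, b), (c, d)).

    The p-value is the exact two-sided value (sum of hypergeometric
    probabilities not exceeding that of the observed table, margins
    fixed); the conditional-MLE odds ratio and its exact conditional 95%
    CI come from the noncentral hypergeometric likelihood. Tables with a
    zero margin carry ``degenerate=True`` (p = 1, conditional estimate
    undefined).
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0 or v != int(v):
            raise ValueError(f"cell {name}={v} must be a non-negative integer")
    if a + b + c + d == 0:
        raise ValueError("all-zero contingency table")
    cp = or_crossproduct(a, b, c, d)
    degenerate = min(a + b, c + d, a + c, b + d) == 0
    if degenerate:
        return ContingencyResult(
            a, b, c, d, 1.0, cp, math.nan, (0.0, math.inf), True, label
        )
    table = [[a, b], [c, d]]
    p = sps.fisher_exact(table, alternative="two-sided").pvalue
    res = _scipy_odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(0.95)
    return ContingencyResult(
        a, b, c, d, float(p), cp, float(res.statistic), (float(ci.low), float(ci.high)),
        False, label,
    )


def table1_analysis(
    summaries: list[SampleBreakSummary], anchor: SampleBreakSummary
) -> list[ContingencyResult]:
    """Repair-defect association tests: each sample's (MIB + OR<=1, OR>1)
    counts against the wild-type anchor's. The anchor itself is skipped
    (self-comparison is uninformative)."""
    c, d = anchor.mib_and_or_le1, anchor.n_or_gt1
    results = []
    for s in summaries:
        if s.sample_id == anchor.sample_id:
            continue
        results.append(fisher_exact(s.mib_and_or_le1, s.n_or_gt1, c, d, label=s.sample_id))
    return results


def table2_analysis(summary: SampleBreakSummary) -> ContingencyResult:
    """MIB-vs-break-class association within one sample: OR<=1 / OR>1
    among MIB reads against the same split among reads mapped from the
    first base."""
    return fisher_exact(
        summary.n_mib_or_le1,
        summary.n_mib_or_gt1,
        summary.n_or_le1,
        summary.n_or_gt1,
        label=summary.sample_id,
    )


def results_to_frame(results: list[ContingencyResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def write_results_tsv(results: list[ContingencyResult], path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# viability
# ---------------------------------------------------------------------------


def pct_viability(count_numerator: float, count_denominator: float) -> float:
    """100 * numerator / denominator: e.g. CFU at a late day over CFU at
    day 1, or induced over control CFU."""
    if count_denominator <= 0:
        raise ValueError("denominator count must be positive")
    return 100.0 * count_numerator / count_denominator


def pct_difference(pct_control: float, pct_induced: float) -> float:
    """100 * (control - induced) / control: relative viability loss of
    endonuclease-induced cells versus control."""
    if pct_control <= 0:
        raise ValueError("control viability must be positive")
    return 100.0 * (pct_control - pct_induced) / pct_control


def read_viability_table(path) -> pd.DataFrame:
    """Viability TSV with columns sample_id, timepoint, condition,
    cfu_count (counts must be non-negative)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "timepoint", "condition", "cfu_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"viability table missing columns: {sorted(missing)}")
    if (df["cfu_count"] < 0).any():
        raise ValueError("cfu_count must be non-negative")
    return df


def compare_groups(x, y, normal: bool = True) -> tuple[float, float]:
    """Thin wrapper around Student's t (normal data) or Mann-Whitney U:
    returns (statistic, p_value) for two replicate groups."""
    if normal:
        res = sps.ttest_ind(x, y)
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
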