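"""Agreement statistics between localization methods and the surgical EZ.

A method call "correctly localizes" when it matches the post-surgically
confirmed reference on both side and sublobar location.  The combined
mesial+lateral temporal class MLT is matched by MT, LT or MLT calls (the
reference involves both subregions), while MT against LT is a mismatch.

On top of the per-method summaries this module provides Cohen's kappa with
its verbal concordance bands, the exact binomial McNemar test on paired
discordant calls, Pearson's chi-square and one-way ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .studytable import METHODS, EZCall, StudyRow

__all__ = [
    "MatchRule",
    "MethodSummary",
    "match",
    "summarize",
    "summary_table",
    "discordant_counts",
    "cohen_kappa",
    "kappa_band",
    "mcnemar_exact",
    "chi_square",
    "one_way_anova",
]

KAPPA_BANDS = (
    # (upper edge of band, verbal label); bands are (lower, upper] intervals
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "excellent"),
)
# the published cut-points leave gaps, e.g. "fair" starts above 0.21 while
# "slight" ends at 0.20; values falling in a gap band low and are flagged
_GAP_LOWER = (0.20, 0.40, 0.60, 0.80)
_GAP_WIDTH = 0.01


@dataclass(frozen=True)
class MatchRule:
    """Concordance rule between a method call and the reference EZ."""

    side_must_match: bool = True
    mlt_matches_components: bool = True  # MLT <-> MT or LT counts as a match

    def sublobar_match(self, call: str, reference: str) -> bool:
        if call == reference:
            return True
        if self.mlt_matches_components:
            if reference == "MLT" and call in ("MT", "LT"):
                return True
            if call == "MLT" and reference in ("MT", "LT"):
                return True
        return False


def match(call: EZCall, reference: EZCall, rule: MatchRule = MatchRule()) -> bool:
    """True iff ``call`` correctly localizes the reference EZ."""
    if reference.is_negative:
        raise ValueError("reference EZ must not be Negative (undefined in the study design)")
    if call.is_negative:
        return False
    if rule.side_must_match and call.side != reference.side:
        return False
    return rule.sublobar_match(call.sublobar, reference.sublobar)


@dataclass
class MethodSummary:
    """Positive/negative and localizing/non-localizing counts for one method."""

    method: str
    n: int
    positive: int
    localizing: int

    @property
    def negative(self) -> int:
        return self.n - self.positive

    @property
    def non_localizing(self) -> int:
        # positive but not correctly localizing
        return self.positive - self.localizing

    def pct(self, count: int) -> float:
        return round(100.0 * count / self.n, 1)


def summarize(rows: list[StudyRow], method: str, rule: MatchRule = MatchRule()) -> MethodSummary:
    """Count positive and correctly localizing studies for one method.

    Positive = a non-Negative call (for MRI: a lesional finding; unspecific
    and normal MRI both count as negative).  Localizing = positive and
    matching the reference under ``rule``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if not rows:
        raise ValueError("empty study table")
    positive = localizing = 0
    for row in rows:
        call = row.calls[method]
        if call.is_negative:
            continue
        positive += 1
        if match(call, row.reference, rule):
            localizing += 1
    return MethodSummary(method=method, n=len(rows), positive=positive, localizing=localizing)


def summary_table(rows: list[StudyRow], rule: MatchRule = MatchRule()) -> pd.DataFrame:
    """Per-method summary counts and percentages, one row per method."""
    recs = []
    for method in METHODS:
        s = summarize(rows, method, rule)
        recs.append(
            {
                "method": method,
                "positive": s.positive,
                "positive_pct": s.pct(s.positive),
                "negative": s.negative,
                "negative_pct": s.pct(s.negative),
                "localizing": s.localizing,
                "localizing_pct": s.pct(s.localizing),
                "non_localizing": s.non_localizing,
                "non_localizing_pct": s.pct(s.non_localizing),
            }
        )
    return pd.DataFrame(recs)


def discordant_counts(
    rows: list[StudyRow], method_a: str, method_b: str, rule: MatchRule = MatchRule()
) -> tuple[int, int]:
    """Paired discordant counts (a localizes & b does not, and vice versa)."""
    b = c = 0
    for row in rows:
        la = match(row.calls[method_a], row.reference, rule) if not row.calls[method_a].is_negative else False
        lb = match(row.calls[method_b], row.reference, rule) if not row.calls[method_b].is_negative else False
        if la and not lb:
            b += 1
        elif lb and not la:
            c += 1
    return b, c


def cohen_kappa(calls_a, calls_b) -> tuple[float, tuple[float, float]]:
    """Cohen's kappa between two categorical assignments, with 95% CI.

    kappa = (p_o - p_e) / (1 - p_e), with observed agreement p_o and chance
    agreement p_e from the marginal products; the CI uses the asymptotic
    standard error sqrt(p_o (1 - p_o) / (n (1 - p_e)^2)).
    """
    a = list(calls_a)
    b = list(calls_b)
    if len(a) != len(b):
        raise ValueError("call lists differ in length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 paired calls")
    cats = sorted(set(a) | set(b), key=str)
    index = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)))
    for x, y in zip(a, b):
        table[index[x], index[y]] += 1
    table /= n
    p_o = float(np.trace(table))
    p_e = float(table.sum(axis=1) @ table.sum(axis=0))
    if p_e >= 1.0:
        warnings.warn("both raters constant and equal; kappa defined as 1", stacklevel=2)
        return 1.0, (1.0, 1.0)
    kappa = (p_o - p_e) / (1.0 - p_e)
    se = np.sqrt(p_o * (1.0 - p_o) / (n * (1.0 - p_e) ** 2))
    half = 1.959963984540054 * se
    return float(kappa), (float(kappa - half), float(kappa + half))


def kappa_band(kappa: float) -> tuple[str, bool]:
    """Verbal concordance band for a kappa value.

    Returns (band, in_gap); values in the gaps between the published
    cut-points (e.g. 0.205, or 0.81 which is above "substantial" but not
    strictly above the "excellent" edge) map to the lower band with the
    gap flag set.  Non-positive kappa is "poor".
    """
    if not -1.0 <= kappa <= 1.0 + 1e-12:
        raise ValueError(f"kappa must be in [-1, 1], got {kappa}")
    if kappa <= 0:
        return "poor", False
    in_gap = any(g < kappa <= g + _GAP_WIDTH for g in _GAP_LOWER)
    for i, (upper, label) in enumerate(KAPPA_BANDS):
        edge = upper + (_GAP_WIDTH if in_gap and upper in _GAP_LOWER else 0.0)
        if kappa <= edge:
            return label, in_gap
    return "excellent", in_gap


def mcnemar_exact(b: int, c: int) -> float:
    """Exact two-sided McNemar p from the discordant counts.

    p = min(1, 2 P(X <= min(b, c))) with X ~ Binomial(b + c, 1/2).
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        warnings.warn("no discordant pairs; McNemar p defined as 1", stacklevel=2)
        return 1.0
    p = 2.0 * stats.binom.cdf(min(b, c), n, 0.5)
    return float(min(1.0, p))


def chi_square(table) -> tuple[float, float]:
    """Pearson chi-square on a 2-way contingency table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or (table < 0).any():
        raise ValueError("need a 2-way table of non-negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def one_way_anova(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(np.var(g) == 0 for g in groups):
        raise ValueError("zero within-group variance everywhere; F undefined")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)
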