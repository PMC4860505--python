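"""Significance tests for fiber-assay summaries.

Three tests cover the comparisons the assay calls for, each usable either
from raw records or from published summary counts:

- a 2x2 chi-squared test (no continuity correction) for fiber-with-signal
  counts between two treatment groups,
- a pooled-variance two-sample Student t-test from summary statistics
  (mean, SD, n per group) for densities,
- a one-sample z-test of the double-sided proportion against 0.5 — the
  single- and double-sided categories are complementary outcomes of one
  sample, so the two-proportion comparison reduces to this form.

A two-sample Kolmogorov-Smirnov comparison of inter-signal spacing
distributions rounds out the set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    """Raised for degenerate inputs (zero margins, n < 2, empty samples)."""


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    df: float | None = None
    inputs: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise StatsError(f"p-value {self.p_value} outside [0, 1]")


def chi2_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Uncorrected chi-squared test on the 2x2 table [[a, b], [c, d]].

    chi2 = N (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)], df = 1. All four margins
    must be positive; no Yates continuity correction is applied.
    """
    cells = (a, b, c, d)
    if any(x < 0 or int(x) != x for x in cells):
        raise StatsError("cell counts must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    n = a + b + c + d
    margins = {"row1": a + b, "row2": c + d, "col1": a + c, "col2": b + d}
    for name, m in margins.items():
        if m == 0:
            raise StatsError(f"degenerate 2x2 table: margin {name} is zero")
    chi2 = n * (a * d - b * c) ** 2 / (margins["row1"] * margins["row2"] * margins["col1"] * margins["col2"])
    p = float(sps.chi2.sf(chi2, 1))
    return TestResult(
        method="chi2_2x2",
        statistic=float(chi2),
        p_value=p,
        df=1,
        inputs={"a": a, "b": b, "c": c, "d": d},
    )


def two_sample_t_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Pooled-variance Student t-test from per-group summary statistics."""
    if n1 < 2 or n2 < 2:
        raise StatsError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise StatsError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        t = 0.0 if mean1 == mean2 else np.inf * np.sign(mean1 - mean2)
    else:
        t = (mean1 - mean2) / se
    p = float(2.0 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    if mean1 == mean2:
        t, p = 0.0, 1.0
    return TestResult(
        method="two_sample_t_pooled",
        statistic=float(t),
        p_value=p,
        df=df,
        inputs={"mean1": mean1, "sd1": sd1, "n1": n1, "mean2": mean2, "sd2": sd2, "n2": n2},
    )


def two_proportion_z(k_single: int, k_double: int) -> TestResult:
    """z-test of the double-sided proportion against 0.5.

    With N = k_single + k_double and p_hat = k_double / N,
    z = (p_hat - 0.5) / sqrt(0.25 / N); two-sided normal p. The two
    categories partition one sample, so this one-sample formulation is the
    natural reading of a "two-proportion" comparison between them.
    """
    if k_single < 0 or k_double < 0:
        raise StatsError("counts must be non-negative")
    n = k_single + k_double
    if n == 0:
        raise StatsError("at least one classified fiber is required")
    p_hat = k_double / n
    z = (p_hat - 0.5) / np.sqrt(0.25 / n)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult(
        method="two_proportion_z_vs_half",
        statistic=float(z),
        p_value=p,
        df=None,
        inputs={"k_single": k_single, "k_double": k_double, "n": n, "p_double": p_hat},
    )


def two_proportion_z_independent(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Classical two-independent-sample proportion z-test (pooled SE).

    Provided for comparisons across experiments; not the default reading of
    the single- vs double-sided contrast.
    """
    if min(n1, n2) <= 0 or not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise StatsError("invalid counts")
    p1, p2 = k1 / n1, k2 / n2
    pp = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
    if se == 0:
        z = 0.0
    else:
        z = (p1 - p2) / se
    return TestResult(
        method="two_proportion_z_independent",
        statistic=float(z),
        p_value=float(2.0 * sps.norm.sf(abs(z))),
        df=None,
        inputs={"k1": k1, "n1": n1, "k2": k2, "n2": n2},
    )


def _spacing_summary(x: np.ndarray) -> dict:
    return {
        "n": int(x.size),
        "mean": float(x.mean()),
        "q25": float(np.percentile(x, 25)),
        "median": float(np.median(x)),
        "q75": float(np.percentile(x, 75)),
    }


def compare_spacing(distances_a: Sequence[float], distances_b: Sequence[float]) -> TestResult:
    """Two-sample Kolmogorov-Smirnov comparison of spacing distributions.

    Returns D and its two-sided p, plus empirical summaries (mean,
    quartiles) of both samples for a distribution-style report.
    """
    xa = np.asarray(list(distances_a), dtype=float)
    xb = np.asarray(list(distances_b), dtype=float)
    if xa.size == 0 or xb.size == 0:
        raise StatsError("both spacing samples must be non-empty")
    res = sps.ks_2samp(xa, xb, alternative="two-sided", method="auto")
    return TestResult(
        method="ks_2samp",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=None,
        inputs={"n_a": int(xa.size), "n_b": int(xb.size)},
        extra={"summary_a": _spacing_summary(xa), "summary_b": _spacing_summary(xb)},
    )
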