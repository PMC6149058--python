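"""Over/under-representation statistics against genome-wide baselines.

Three tests, one convention.  Repeat categories use the hypergeometric
distribution: drawing n peaks from a universe of N repeat instances of which
K belong to the category, the observed k in-category peaks give
p_over = P(X >= k) and p_under = P(X <= k).  Sequence classes use a 1-df
chi-square goodness of fit of the (in-class, out-of-class) split against the
genome-occupancy expectation (T*g_c, T*(1-g_c)).  Transcript class-count
tables use per-class 2x2 Fisher exact tests.  Throughout, fold enrichment is
observed/expected — f = (k/n)/(K/N) or (O_c/T)/g_c — so f > 1 always means
over-represented.  Families of p-values are adjusted by Benjamini-Hochberg.

p-values are floored at 1e-300 so extreme tails print as a number rather
than 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, fisher_exact, hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "P_FLOOR",
    "RepresentationResult",
    "hypergeom_representation",
    "chisq_class_representation",
    "fisher_two_by_two",
    "benjamini_hochberg",
    "transcript_class_enrichment",
    "repeat_representation_table",
    "class_representation_table",
]

P_FLOOR = 1e-300


@dataclass
class RepresentationResult:
    """One category/class tested against its genome-wide expectation."""

    name: str
    k: int  # observed count in the sample
    n: int  # sample size
    expected_prop: float  # K/N or g_c
    expected_count: float  # n * expected_prop
    fold: float  # (k/n) / expected_prop; >1 = over-represented
    p_over: float
    p_under: float
    q: float | None = None
    test: str = ""


def _floor(p: float) -> float:
    return max(float(p), P_FLOOR)


def hypergeom_representation(k: int, n: int, K: int, N: int, name: str = "") -> RepresentationResult:
    """Hypergeometric representation of one category.

    Parameters follow the sampling-without-replacement convention:
    *N* repeats in the genome, *K* of them in the category, *n* sampled
    (peaks overlapping any repeat), *k* observed in the category.
    """
    if not (0 <= k <= n and k <= K and n <= N and K <= N):
        raise ValueError(f"hypergeometric bounds violated: k={k}, n={n}, K={K}, N={N}")
    if n == 0 or K == 0:
        raise ValueError("n and K must be positive to define fold enrichment")
    p_over = _floor(hypergeom.sf(k - 1, N, K, n))
    p_under = _floor(hypergeom.cdf(k, N, K, n))
    expected_prop = K / N
    return RepresentationResult(
        name=name,
        k=k,
        n=n,
        expected_prop=expected_prop,
        expected_count=n * expected_prop,
        fold=(k / n) / expected_prop,
        p_over=p_over,
        p_under=p_under,
        test="hypergeometric",
    )


def chisq_class_representation(
    O_c: int, T: int, g_c: float, name: str = "", yates: bool = False
) -> RepresentationResult:
    """1-df chi-square goodness of fit of one class against genome occupancy.

    Observed (O_c, T - O_c) vs expected (T*g_c, T*(1-g_c)); two-sided p.
    No continuity correction by default (*yates* enables it).  The two-sided
    p is reported in both ``p_over`` and ``p_under`` slots; the fold's side
    of 1 carries the direction.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if not 0 <= O_c <= T:
        raise ValueError("require 0 <= O_c <= T")
    if not 0 < g_c < 1:
        raise ValueError("require 0 < g_c < 1")
    exp_in = T * g_c
    exp_out = T * (1 - g_c)
    correction = 0.5 if yates else 0.0
    stat = (max(abs(O_c - exp_in) - correction, 0.0)) ** 2 / exp_in + (
        max(abs((T - O_c) - exp_out) - correction, 0.0)
    ) ** 2 / exp_out
    p = _floor(chi2.sf(stat, df=1))
    return RepresentationResult(
        name=name,
        k=O_c,
        n=T,
        expected_prop=g_c,
        expected_count=exp_in,
        fold=(O_c / T) / g_c,
        p_over=p,
        p_under=p,
        test="chi-square",
    )


def fisher_two_by_two(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Fisher exact test on the 2x2 table [[a, b], [c, d]].

    Returns ``(odds_ratio, two_sided_p)``.  Two-sided p sums hypergeometric
    probabilities of tables at most as probable as the observed one.  A zero
    margin makes the table degenerate: p = 1 and the odds ratio is returned
    as NaN (undefined).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return (math.nan, 1.0)
    odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return (float(odds), float(p))


def benjamini_hochberg(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Adjusted values are clipped at 1 and are monotone non-decreasing when
    sorted by raw p.  An empty list returns an empty list.
    """
    if len(pvals) == 0:
        return []
    arr = np.asarray(pvals, dtype=float)
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1].tolist()


def transcript_class_enrichment(table: pd.DataFrame) -> pd.DataFrame:
    """Per-class fold enrichment between two conditions of a class-count table.

    *table* has one row per transcript class and exactly two count columns
    (condition 1, condition 2).  Each class is tested with a 2x2 Fisher
    exact test (class vs rest, condition 1 vs condition 2); fold is the
    ratio of within-condition proportions (condition 1 over condition 2,
    1 = no enrichment relative to random distribution); q is BH-adjusted
    across classes.
    """
    if table.shape[1] != 2:
        raise ValueError("class-count table must have exactly two condition columns")
    if len(table) < 2:
        raise ValueError("need at least two classes")
    if (table < 0).to_numpy().any():
        raise ValueError("counts must be non-negative")
    c1, c2 = table.columns
    tot1, tot2 = int(table[c1].sum()), int(table[c2].sum())
    if tot1 <= 0 or tot2 <= 0:
        raise ValueError("both condition totals must be positive")
    rows = []
    for cls_label, row in table.iterrows():
        a, c = int(row[c1]), int(row[c2])
        odds, p = fisher_two_by_two(a, tot1 - a, c, tot2 - c)
        prop1, prop2 = a / tot1, c / tot2
        fold = math.nan if prop2 == 0 else prop1 / prop2
        rows.append({"class": cls_label, "count_1": a, "count_2": c, "fold": fold, "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = benjamini_hochberg(out["p"].tolist())
    return out


def repeat_representation_table(
    by_repeat: dict[str, int], n: int, category_counts: dict[str, int], N: int
) -> pd.DataFrame:
    """Hypergeometric representation of every repeat category, BH-adjusted.

    *by_repeat* are observed in-category peak counts; *n* the number of
    peaks in the repeat universe; *category_counts*/*N* the genome-wide
    catalog.  One BH family across all tested categories (on p_over; the
    direction flag marks which tail is the interesting one).
    """
    results = [
        hypergeom_representation(by_repeat.get(cat, 0), n, K, N, name=cat)
        for cat, K in sorted(category_counts.items())
        if K > 0 and n > 0
    ]
    return _representation_frame(results)


def class_representation_table(
    by_class: dict[str, int], T: int, fractions: dict[str, float], yates: bool = False
) -> pd.DataFrame:
    """Chi-square representation of every sequence class, BH-adjusted."""
    results = [
        chisq_class_representation(by_class.get(cls_label, 0), T, g, name=cls_label, yates=yates)
        for cls_label, g in sorted(fractions.items())
        if 0 < g < 1 and T > 0
    ]
    return _representation_frame(results)


def _representation_frame(results: list[RepresentationResult]) -> pd.DataFrame:
    cols = [
        "name",
        "k",
        "n",
        "expected_prop",
        "expected_count",
        "fold",
        "p_over",
        "p_under",
        "q",
        "direction",
        "test",
    ]
    if not results:
        return pd.DataFrame(columns=cols)
    qs = benjamini_hochberg([r.p_over for r in results])
    rows = []
    for r, q in zip(results, qs):
        r.q = q
        rows.append(
            {
                "name": r.name,
                "k": r.k,
                "n": r.n,
                "expected_prop": r.expected_prop,
                "expected_count": r.expected_count,
                "fold": r.fold,
                "p_over": r.p_over,
                "p_under": r.p_under,
                "q": q,
                "direction": "over" if r.fold > 1 else ("under" if r.fold < 1 else "expected"),
                "test": r.test,
            }
        )
    return pd.DataFrame(rows, columns=cols)
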