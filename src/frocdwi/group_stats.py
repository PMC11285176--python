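"""Two-group comparison, correlation and agreement statistics.

The comparison workflow mirrors routine quantitative-imaging practice:

1. each group's values pass a normality gate — a Kolmogorov–Smirnov test
   against a normal with estimated mean/SD (Lilliefors correction, since the
   reference parameters are estimated from the sample), α = 0.05;
2. two groups are compared with the independent-samples t-test when both are
   normal, otherwise with the two-sided Mann–Whitney U test;
3. paired measurements (e.g. the same lesions under two DWI sequences) are
   assessed by Spearman rank correlation, intraclass correlation (two-way
   random effects, absolute agreement, single measures — ICC(2,1)), and
   Bland–Altman bias with 1.96·SD limits of agreement.

Spearman r and ICC estimates carry the conventional category labels; bin
edges are applied to the estimate rounded to 2 decimals, closed on both ends.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "AgreementResult",
    "normality_gate",
    "compare_groups",
    "spearman_with_category",
    "icc_with_category",
    "bland_altman",
    "SPEARMAN_BINS",
    "ICC_BINS",
]

ALPHA = 0.05

#: (upper edge, label) on the rounded |r| — conventional correlation strengths.
SPEARMAN_BINS = [(0.24, "little or no correlation"), (0.49, "fair correlation"),
                 (0.74, "moderate correlation"), (1.00, "good correlation")]

#: (upper edge, label) on the rounded ICC — conventional agreement strengths.
ICC_BINS = [(0.20, "poor agreement"), (0.40, "fair agreement"),
            (0.60, "moderate agreement"), (0.80, "good agreement"),
            (1.00, "excellent agreement")]


@dataclass
class AgreementResult:
    """Correlation / agreement summary.

    ``estimate`` and ``ci`` hold r or the ICC with its 95% CI; for
    Bland–Altman they are unused and ``bias``/``loa_lower``/``loa_upper``
    carry the mean difference and limits of agreement.
    """

    kind: str
    estimate: Optional[float] = None
    ci: Optional[Tuple[float, float]] = None
    category: Optional[str] = None
    bias: Optional[float] = None
    loa_lower: Optional[float] = None
    loa_upper: Optional[float] = None


def _categorize(value: float, bins) -> str:
    v = round(abs(value), 2)
    for hi, label in bins:
        if v <= hi:
            return label
    return bins[-1][1]


def normality_gate(x) -> str:
    """Classify a sample as ``"normal"`` or ``"non_normal"``.

    Lilliefors-corrected Kolmogorov–Smirnov test at α = 0.05; a degenerate
    (zero-variance) sample is non-normal by convention.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError("normality gate needs at least 5 observations")
    if np.std(x) == 0:
        return "non_normal"
    _, p = lilliefors(x, dist="norm")
    return "normal" if p >= ALPHA else "non_normal"


def compare_groups(x, y) -> Tuple[str, float, float]:
    """Two-group comparison routed through the normality gate.

    Returns ``(test_name, statistic, two_sided_p)`` where the test is the
    independent-samples t-test when both groups pass the gate, otherwise the
    Mann–Whitney U test.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if normality_gate(x) == "normal" and normality_gate(y) == "normal":
        stat, p = stats.ttest_ind(x, y)
        return "t", float(stat), float(p)
    stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    return "mannwhitneyu", float(stat), float(p)


def spearman_with_category(x, y) -> AgreementResult:
    """Spearman rank correlation with a Fisher-transform 95% CI and category."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must be paired")
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("rank correlation undefined for a constant sample")
    r = float(stats.spearmanr(x, y).statistic)
    if abs(r) < 1.0:
        z = np.arctanh(r)
        half = stats.norm.ppf(1 - ALPHA / 2) / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    else:
        ci = (r, r)
    return AgreementResult(kind="spearman", estimate=r, ci=ci,
                           category=_categorize(r, SPEARMAN_BINS))


def icc_with_category(ratings) -> AgreementResult:
    """ICC(2,1) — two-way random effects, absolute agreement, single measures.

    ``ratings`` is an n_subjects × k_raters table.  Estimation and the 95%
    CI follow the standard two-way ANOVA decomposition.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[1] < 2:
        raise ValueError("ratings must be an n x k table with k >= 2 raters")
    n = ratings.shape[0]
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if np.allclose(np.var(ratings.mean(axis=1)), 0):
        raise ValueError("zero between-subject variance: ICC undefined")

    import pingouin as pg

    k = ratings.shape[1]
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "rater": np.tile(np.arange(k), n),
        "score": ratings.ravel(),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(data=long, targets="subject", raters="rater",
                                   ratings="score")
    table = table.set_index("Type")
    # row label of the two-way random, absolute agreement, single-measure form
    label = "ICC(A,1)" if "ICC(A,1)" in table.index else "ICC2"
    row = table.loc[label]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    icc = float(row["ICC"])
    lo, hi = (float(v) for v in row[ci_col])
    return AgreementResult(kind="icc", estimate=icc, ci=(lo, hi),
                           category=_categorize(icc, ICC_BINS))


def bland_altman(x, y) -> AgreementResult:
    """Bland–Altman bias and 95% limits of agreement for paired samples.

    ``bias = mean(x − y)``; limits are ``bias ± 1.96 · SD(x − y)`` with the
    sample SD, matching the conventional Bland–Altman plot.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must be paired")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(kind="bland_altman", bias=bias,
                           loa_lower=bias - 1.96 * sd, loa_upper=bias + 1.96 * sd)
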