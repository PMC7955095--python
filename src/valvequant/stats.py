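"""Two-group comparison statistics for the valve metrics.

Each metric is compared between the two mouse groups (wild type vs
ApoE-deficient) with the rule: test each group for normality with a
Kolmogorov–Smirnov-type test; if both pass, use Student's unpaired
one-tailed t-test, otherwise the one-tailed Mann–Whitney U test. P-values
below alpha = 0.05 are significant; tables carry the conventional star
codes (* <= 0.05, ** <= 0.01, *** <= 0.001).

Because the normal parameters are estimated from the sample, the default
normality test is the Lilliefors-corrected KS test; the classical KS test
(fixed parameters) is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = ["GroupComparison", "normality", "compare_groups", "summarize",
           "star_code"]


@dataclass
class GroupComparison:
    metric: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    normality_p_a: float
    normality_p_b: float
    test_used: str            # "t_one_tailed" | "mann_whitney"
    direction: str            # alternative for group a vs b
    p_value: float
    alpha: float
    significant: bool


def normality(sample: Sequence[float], method: str = "lilliefors") -> float:
    """P-value of a KS-type normality test with estimated mean and SD.

    ``method="lilliefors"`` (default) corrects the KS null distribution
    for the estimated parameters; ``method="ks"`` runs the classical KS
    test against Normal(sample mean, sample SD), which is anti-conservative
    but matches the plain reading of "Kolmogorov–Smirnov test".
    """
    x = np.asarray(sample, float)
    if x.size < 3:
        raise ValueError("normality test needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("sample has zero variance")
    if method == "lilliefors":
        if x.size < 4:
            method = "ks"  # Lilliefors tables start at n = 4
        else:
            _, p = lilliefors(x, dist="norm")
            return float(p)
    if method == "ks":
        _, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
        return float(p)
    raise ValueError(f"unknown method {method!r}")


def compare_groups(a: Sequence[float], b: Sequence[float],
                   direction: str, alpha: float = 0.05,
                   metric: str = "", normality_method: str = "lilliefors",
                   ) -> GroupComparison:
    """Compare two groups with the normality-gated one-tailed test.

    ``direction`` is the pre-specified alternative for group *a* relative
    to group *b* (``"greater"`` or ``"less"``) and must be stated
    explicitly — a one-tailed test without a declared direction is
    meaningless. The gate is applied per group: if either group fails
    normality at ``alpha``, the comparison routes to Mann–Whitney U.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    p_norm_a = normality(a, normality_method)
    p_norm_b = normality(b, normality_method)

    if p_norm_a > alpha and p_norm_b > alpha:
        test_used = "t_one_tailed"
        _, p = sps.ttest_ind(a, b, alternative=direction, equal_var=True)
    else:
        test_used = "mann_whitney"
        _, p = sps.mannwhitneyu(a, b, alternative=direction)

    return GroupComparison(
        metric=metric,
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=int(a.size),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=int(b.size),
        normality_p_a=p_norm_a, normality_p_b=p_norm_b,
        test_used=test_used, direction=direction,
        p_value=float(p), alpha=alpha, significant=bool(p < alpha),
    )


def star_code(p: float) -> str:
    """Conventional significance stars: * <=0.05, ** <=0.01, *** <=0.001."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def summarize(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Summary table (mean ± SD per group, test, p-value, stars)."""
    if not comparisons:
        raise ValueError("no comparisons to summarize")
    rows = []
    for c in comparisons:
        rows.append({
            "metric": c.metric,
            "group_a": f"{c.mean_a:.4g} ± {c.sd_a:.4g} (n={c.n_a})",
            "group_b": f"{c.mean_b:.4g} ± {c.sd_b:.4g} (n={c.n_b})",
            "test": c.test_used,
            "p_value": c.p_value,
            "stars": star_code(c.p_value),
        })
    return pd.DataFrame(rows)
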