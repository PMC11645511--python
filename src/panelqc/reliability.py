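"""Internal-consistency reliability (Cronbach alpha) per scale and a
two-independent-samples comparison of alpha coefficients.

The comparison uses the Feldt ratio W = (1 - alpha1) / (1 - alpha2), referred
to an F distribution under the null of equal reliabilities, with a two-sided
p value. Under a compound-symmetric (parallel-items) Gaussian model,
(1 - alpha_hat)/(1 - alpha) in a single sample follows F(n-1, (n-1)(k-1));
each arm's degrees of freedom are therefore variance-matched to that
distribution as d = (n-1)(k-1)/k, which keeps the nominal test size for
small item counts where the cruder (n-1, n-1) convention runs liberal.
A large-sample chi-square expression of the same statistic (on ln W) is
reported alongside, since some sources label this comparison a chi-square
test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codebook import ScaleDefinition

__all__ = ["AlphaResult", "AlphaComparison", "reverse_code", "cronbach_alpha",
           "compare_alphas"]


@dataclass(frozen=True)
class AlphaResult:
    scale: str
    alpha: float
    n: int  # complete cases used (listwise within scale)
    k: int  # items


@dataclass(frozen=True)
class AlphaComparison:
    statistic: float  # Feldt W = (1-alpha1)/(1-alpha2)
    df1: float  # variance-matched (n-1)(k-1)/k per arm
    df2: float
    p_value: float  # two-sided, F reference
    chi2_statistic: float  # large-sample (ln W)^2 / var(ln W), 1 df
    chi2_p_value: float


def reverse_code(
    responses: pd.DataFrame, reverse_items, response_range=(1, 5)
) -> pd.DataFrame:
    """Invert reverse-keyed items: r -> (min + max) - r on the declared range."""
    lo, hi = response_range
    out = responses.copy()
    cols = [c for c in reverse_items if c in out.columns]
    out[cols] = (lo + hi) - out[cols]
    return out


def cronbach_alpha(
    responses: pd.DataFrame,
    scale: ScaleDefinition,
    response_range=(1, 5),
    min_cases: int = 3,
) -> AlphaResult:
    """Cronbach alpha for one scale.

    Reverse-keyed items are recoded first; cases with any missing scale item
    are dropped (listwise within scale). alpha = k/(k-1) * (1 - sum of item
    variances / variance of the total score); undefined (NaN) when the total
    score has zero variance.
    """
    if scale.k < 2:
        raise ValueError("alpha needs >=2 items")
    data = reverse_code(responses[list(scale.items)], scale.reverse_items, response_range)
    data = data.dropna()
    n = len(data)
    if n < min_cases:
        raise ValueError(f"scale {scale.name!r}: {n} complete cases < {min_cases}")
    arr = data.to_numpy(float)
    item_var = arr.var(axis=0, ddof=1).sum()
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return AlphaResult(scale.name, float("nan"), n, scale.k)
    k = scale.k
    return AlphaResult(scale.name, float(k / (k - 1) * (1 - item_var / total_var)), n, k)


def compare_alphas(
    alpha1: float, n1: int, k1: int, alpha2: float, n2: int, k2: int
) -> AlphaComparison:
    """Test equality of two independent-sample alpha coefficients.

    Feldt's W = (1-alpha1)/(1-alpha2) is referred to F(d1, d2) with
    variance-matched per-arm degrees of freedom d = (n-1)(k-1)/k; p is
    two-sided. The chi-square form refers (ln W)^2 / (2/d1 + 2/d2) to
    chi-square with 1 df (asymptotically equivalent for large samples).
    """
    for a, n, k in ((alpha1, n1, k1), (alpha2, n2, k2)):
        if a >= 1.0:
            raise ValueError("alpha must be < 1 for the reliability ratio test")
        if n <= k:
            raise ValueError("need n > k in each sample")
    df1 = (n1 - 1) * (k1 - 1) / k1
    df2 = (n2 - 1) * (k2 - 1) / k2
    w = (1.0 - alpha1) / (1.0 - alpha2)
    cdf = stats.f.cdf(w, df1, df2)
    p = float(2.0 * min(cdf, 1.0 - cdf))
    var_ln = 2.0 / df1 + 2.0 / df2
    chi2 = float(np.log(w) ** 2 / var_ln)
    chi2_p = float(stats.chi2.sf(chi2, 1))
    return AlphaComparison(
        statistic=float(w), df1=df1, df2=df2, p_value=min(p, 1.0),
        chi2_statistic=chi2, chi2_p_value=chi2_p,
    )
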