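"""Careless-response metrics: weighted kappa consistency on item pairs,
straight-lining rules, the mean-root-of-pairs statistic, and Winsorized
response-burden summaries.

Three straight-lining rules are implemented:

1. identical answered responses within *every* consecutive
   same-response-category set;
2. identical responses across a physical-function battery where a constant
   answer is implausible (a constant "without any difficulty", rating 5, is
   allowed);
3. identical responses within a mixed-direction sleep set (constant rating 3,
   "somewhat/sometimes", is allowed).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
import pandas as pd

from .codebook import Battery

__all__ = [
    "weighted_kappa",
    "interpret_kappa",
    "straightline_all_sets",
    "straightline_battery",
    "mean_root_of_pairs",
    "winsorized_burden",
    "BurdenSummary",
]


def weighted_kappa(x, y, categories=None, scheme: str = "quadratic") -> float:
    """Chance-corrected agreement for ordinal ratings.

    kappa = 1 - sum(w*O) / sum(w*E), with disagreement weights
    ``w_ij = (i - j)**2`` (quadratic) or ``|i - j|`` (linear) taken over the
    full declared category range -- the weights reflect the metric of the
    scale, not the sample -- O the observed joint proportions and E the
    chance proportions (outer product of the marginals). Pairwise-complete
    cases only.

    Returns NaN when chance disagreement is zero (both marginals degenerate),
    where the statistic is undefined.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 2:
        raise ValueError("need >=2 pairwise-complete cases")
    if categories is None:
        categories = np.arange(1, 6)
    cats = np.asarray(categories, float)
    if np.setdiff1d(np.union1d(x, y), cats).size:
        raise ValueError("observed values outside the declared category set")

    k = cats.size
    ix = np.searchsorted(cats, x)
    iy = np.searchsorted(cats, y)
    obs = np.zeros((k, k))
    np.add.at(obs, (ix, iy), 1.0)
    obs /= obs.sum()
    expe = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    diff = cats[:, None] - cats[None, :]
    if scheme == "quadratic":
        w = diff**2
    elif scheme == "linear":
        w = np.abs(diff)
    else:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    denom = float((w * expe).sum())
    if denom == 0.0:
        return float("nan")
    return float(1.0 - (w * obs).sum() / denom)


_KAPPA_BANDS = [
    (Decimal("0.20"), "slight"),
    (Decimal("0.40"), "fair"),
    (Decimal("0.60"), "moderate"),
    (Decimal("0.80"), "substantial"),
    (Decimal("1.00"), "almost perfect"),
]


def interpret_kappa(kappa: float) -> str:
    """Agreement label for a kappa value (Landis-Koch bands).

    The value is rounded half-up to 2 decimals first, matching reporting
    precision, so e.g. 0.205 lands in the fair band.
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [-1, 1]")
    k2 = Decimal(repr(float(kappa))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    if k2 < 0:
        return "poor"
    for upper, label in _KAPPA_BANDS:
        if k2 <= upper:
            return label
    return "almost perfect"


def straightline_battery(responses: pd.DataFrame, battery: Battery) -> pd.Series:
    """Flag respondents giving one identical response across a complete
    battery, unless that response is the battery's allowed category.

    Respondents missing any battery item are not flagged for it.
    """
    sub = responses[list(battery.items)]
    complete = sub.notna().all(axis=1)
    constant = sub.nunique(axis=1) == 1
    flag = complete & constant
    if battery.allowed_category is not None:
        flag &= sub.iloc[:, 0] != battery.allowed_category
    return flag.fillna(False).astype(bool)


def straightline_all_sets(responses: pd.DataFrame, batteries) -> pd.Series:
    """Flag respondents whose answered responses are constant within every
    consecutive same-response-category set.

    The constants may differ between sets. A respondent with no answered
    items in some set cannot be evaluated there and is not flagged.
    """
    batteries = list(batteries.values()) if isinstance(batteries, dict) else list(batteries)
    if not batteries:
        raise ValueError("need at least one battery")
    flag = pd.Series(True, index=responses.index)
    for bat in batteries:
        sub = responses[list(bat.items)]
        answered = sub.notna().sum(axis=1)
        constant = sub.nunique(axis=1) == 1
        flag &= (answered >= 1) & constant
    return flag.astype(bool)


def mean_root_of_pairs(
    responses: pd.DataFrame, battery, response_range=(1, 5)
) -> pd.Series:
    """Per-respondent straight-lining score for one battery.

    rp = 1 - mean over item pairs of sqrt(|r_i - r_j|), rescaled by
    sqrt(category range), so 1 means all answers identical (most
    straight-lining) and 0 means maximally spread answers. Respondents with
    fewer than two answered battery items are undefined (NaN).
    """
    items = list(battery.items) if isinstance(battery, Battery) else list(battery)
    lo, hi = response_range
    if hi <= lo:
        raise ValueError("response_range must be increasing")
    sub = responses[items].to_numpy(float)
    roots = np.stack(
        [np.sqrt(np.abs(sub[:, a] - sub[:, b])) for a, b in combinations(range(len(items)), 2)],
        axis=1,
    )
    n_valid = (~np.isnan(roots)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_root = np.nansum(roots, axis=1) / np.where(n_valid > 0, n_valid, np.nan)
    rp = 1.0 - mean_root / np.sqrt(hi - lo)
    return pd.Series(rp, index=responses.index, name="rp")


@dataclass(frozen=True)
class BurdenSummary:
    """Response-burden summary in minutes, on Winsorized durations."""

    mean: float
    sd: float
    median: float
    min: float
    max: float
    cap_seconds: float
    n: int


def winsorized_burden(durations_seconds) -> BurdenSummary:
    """Summaries of completion time after capping the top 2.5% of durations at
    the 97.5th percentile (linear-interpolation percentile), in minutes."""
    d = np.asarray(pd.Series(durations_seconds).dropna(), float)
    if d.size < 1:
        raise ValueError("need at least one duration")
    cap = float(np.percentile(d, 97.5))
    capped = np.minimum(d, cap) / 60.0
    return BurdenSummary(
        mean=float(capped.mean()),
        sd=float(capped.std(ddof=1)) if d.size > 1 else float("nan"),
        median=float(np.median(capped)),
        min=float(capped.min()),
        max=float(capped.max()),
        cap_seconds=cap,
        n=int(d.size),
    )
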