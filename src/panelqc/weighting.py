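"""Poststratification weighting by raking (iterative proportional fitting)
with weight trimming and scaling, plus imbalance diagnostics and weighted
estimators.

One raking cycle multiplies each respondent's weight by target/current for
every category of every raking variable in turn; after the cycle, weights
above the cap are trimmed to it and all weights rescaled to mean 1 (repeated
until the cap holds post-scaling). Convergence is declared when the total
absolute imbalance -- the sum over all raking variables and categories of
|weighted sample proportion - target proportion| -- drops to the tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MarginalTargets",
    "WeightVector",
    "load_targets",
    "rake",
    "total_absolute_imbalance",
    "weighted_mean",
    "weighted_proportions",
    "effective_sample_size",
    "weighted_estimates",
]

MISSING_CATEGORY = "(missing)"

#: per demographic variable: category -> target proportion
MarginalTargets = dict


def load_targets(path: str | Path) -> MarginalTargets:
    """Read raking targets from YAML; values are normalized per variable, so
    the file may hold percentages."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out: MarginalTargets = {}
    for var, cats in raw.items():
        total = float(sum(cats.values()))
        if total <= 0:
            raise ValueError(f"targets for {var!r} must be positive")
        out[var] = {c: float(v) / total for c, v in cats.items()}
    return out


@dataclass
class WeightVector:
    """Raking result: per-respondent weights (mean 1) plus diagnostics."""

    weights: pd.Series
    iterations: int
    converged: bool
    max_weight_cap: float | None
    total_absolute_imbalance: float
    cap_hits: int  # respondents at the cap in the final cycle

    def to_csv(self, path: str | Path) -> None:
        self.weights.to_frame("weight").to_csv(path)

    def diagnostics(self) -> dict:
        return {
            "iterations": self.iterations,
            "converged": self.converged,
            "max_weight_cap": self.max_weight_cap,
            "total_absolute_imbalance": self.total_absolute_imbalance,
            "cap_hits": self.cap_hits,
            "max_weight": float(self.weights.max()),
            "effective_sample_size": effective_sample_size(self.weights),
            "n": int(len(self.weights)),
        }


def _prepare(demographics: pd.DataFrame, targets: MarginalTargets):
    """Validate targets, absorb missing values into a weight-neutral category."""
    demo = demographics.copy()
    prepared: MarginalTargets = {}
    n = len(demo)
    for var, cats in targets.items():
        if var not in demo.columns:
            raise KeyError(f"raking variable {var!r} not in demographics")
        if any(v <= 0 for v in cats.values()):
            raise ValueError(f"targets for {var!r} must be strictly positive")
        if abs(sum(cats.values()) - 1.0) > 1e-6:
            raise ValueError(f"targets for {var!r} do not sum to 1")
        col = demo[var].astype(object)
        observed = set(col.dropna().unique())
        unknown = observed - set(cats)
        if unknown:
            raise ValueError(f"{var!r} has sample categories without targets: {sorted(unknown)}")
        var_targets = dict(cats)
        n_missing = int(col.isna().sum())
        if n_missing:
            # rake the missing category to its own sample share so it is
            # weight-neutral; stated targets share the remainder
            share = n_missing / n
            var_targets = {c: v * (1.0 - share) for c, v in cats.items()}
            var_targets[MISSING_CATEGORY] = share
            col = col.fillna(MISSING_CATEGORY)
            observed = observed | {MISSING_CATEGORY}
        empty = [c for c, v in var_targets.items() if v > 0 and c not in observed]
        if empty:
            raise ValueError(
                f"{var!r}: categories {empty} have nonzero targets but no sample members"
            )
        demo[var] = col
        prepared[var] = var_targets
    return demo, prepared


def total_absolute_imbalance(
    demographics: pd.DataFrame, weights, targets: MarginalTargets
) -> float:
    """Sum over raking variables and categories of |weighted share - target|."""
    w = np.asarray(weights, float)
    total = w.sum()
    imb = 0.0
    for var, cats in targets.items():
        if var not in demographics.columns:
            raise KeyError(f"variable {var!r} not in demographics")
        col = demographics[var]
        for cat, target in cats.items():
            share = w[(col == cat).to_numpy()].sum() / total
            imb += abs(share - target)
    return float(imb)


def rake(
    demographics: pd.DataFrame,
    targets: MarginalTargets,
    max_weight: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    base_weights=None,
) -> WeightVector:
    """Rake the sample to the marginal targets with trimming and scaling.

    ``max_weight`` caps individual weights (on the mean-1 scale) after every
    cycle; ``tol`` is the total-absolute-imbalance convergence tolerance.
    """
    if max_weight is not None and max_weight <= 1.0:
        raise ValueError("max_weight must exceed 1 (the mean weight)")
    demo, prepared = _prepare(demographics, targets)
    n = len(demo)
    if n == 0:
        raise ValueError("empty sample")
    w = (
        np.ones(n)
        if base_weights is None
        else np.asarray(base_weights, float).copy()
    )
    if (w <= 0).any():
        raise ValueError("base weights must be positive")
    w /= w.mean()

    masks = {
        var: {cat: (demo[var] == cat).to_numpy() for cat in cats}
        for var, cats in prepared.items()
    }
    imb = total_absolute_imbalance(demo, w, prepared)
    iterations = 0
    converged = imb <= tol
    while not converged and iterations < max_iter:
        for var, cats in prepared.items():
            total = w.sum()
            for cat, target in cats.items():
                mask = masks[var][cat]
                current = w[mask].sum() / total
                if current > 0 and target > 0:
                    w[mask] *= target / current
                    total = w.sum()
        # trim then rescale to mean 1, repeating so the cap survives scaling
        w /= w.mean()
        if max_weight is not None:
            for _ in range(100):
                over = w > max_weight
                if not over.any():
                    break
                w[over] = max_weight
                w /= w.mean()
        iterations += 1
        imb = total_absolute_imbalance(demo, w, prepared)
        converged = imb <= tol
    cap_hits = int((w >= (max_weight - 1e-12)).sum()) if max_weight is not None else 0
    return WeightVector(
        weights=pd.Series(w, index=demo.index, name="weight"),
        iterations=iterations,
        converged=converged,
        max_weight_cap=max_weight,
        total_absolute_imbalance=imb,
        cap_hits=cap_hits,
    )


def weighted_mean(values, weights) -> float:
    """Weight-normalized mean over non-missing values."""
    v = np.asarray(values, float)
    w = np.asarray(weights, float)
    keep = ~np.isnan(v)
    if not keep.any():
        raise ValueError("all values missing")
    return float(np.average(v[keep], weights=w[keep]))


def weighted_proportions(values, weights) -> dict:
    """Weighted category shares of a categorical column (missing dropped)."""
    s = pd.Series(values).astype(object)
    w = pd.Series(np.asarray(weights, float), index=s.index)
    keep = s.notna()
    s, w = s[keep], w[keep]
    total = w.sum()
    return {cat: float(w[s == cat].sum() / total) for cat in sorted(s.unique())}


def effective_sample_size(weights) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2; equals n iff weights
    are equal."""
    w = np.asarray(weights, float)
    return float(w.sum() ** 2 / (w**2).sum())


def weighted_estimates(values, weights) -> dict:
    """Weighted mean (numeric) or category proportions (categorical), with the
    effective sample size."""
    s = pd.Series(values)
    out: dict = {"effective_sample_size": effective_sample_size(weights)}
    if pd.api.types.is_numeric_dtype(s):
        out["mean"] = weighted_mean(s, weights)
    else:
        out["proportions"] = weighted_proportions(s, weights)
    return out
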