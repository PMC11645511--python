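"""Cross-sample comparison: scale scoring and T-score standardization,
small-effect flagging, benchmark deviation tables, and correlation-matrix
comparison with Fisher-z confidence intervals.

T-scores here are z-standardizations against a supplied reference sample
rescaled to mean 50, SD 10. This reproduces the T metric's construction but
is **not** the official item-calibration lookup for any published instrument;
the packaged reference is synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .codebook import Codebook
from .reliability import reverse_code

__all__ = [
    "score_scales",
    "tscore_standardize",
    "effect_flag",
    "fisher_ci",
    "CorrelationResult",
    "correlation_matrix",
    "CorrelationComparison",
    "compare_correlation_matrices",
    "benchmark_table",
    "load_benchmark",
]


def score_scales(responses: pd.DataFrame, codebook: Codebook) -> pd.DataFrame:
    """Per-respondent scale scores: mean of (reverse-recoded) scale items.

    Scores are prorated over answered items when at least half of a scale's
    items are answered; otherwise the score is missing.
    """
    rng = (codebook.response_min, codebook.response_max)
    out = {}
    for name, sc in codebook.scales.items():
        data = reverse_code(responses[list(sc.items)], sc.reverse_items, rng)
        answered = data.notna().sum(axis=1)
        score = data.mean(axis=1)
        out[name] = score.where(answered * 2 >= sc.k)
    return pd.DataFrame(out, index=responses.index)


def tscore_standardize(scores, reference) -> pd.Series:
    """T = 50 + 10 * (x - mean_ref) / sd_ref (reference SD with ddof=1)."""
    ref = np.asarray(pd.Series(reference).dropna(), float)
    if np.unique(ref).size < 2:
        raise ValueError("reference needs >=2 distinct values")
    mu, sd = ref.mean(), ref.std(ddof=1)
    s = pd.Series(scores, dtype=float)
    return 50.0 + 10.0 * (s - mu) / sd


def effect_flag(t1: float, t2: float, threshold: float = 2.0) -> bool:
    """Flag a difference exceeding ``threshold`` T-score points (strict >,
    so a difference of exactly the threshold is not flagged)."""
    return bool(abs(float(t1) - float(t2)) > threshold)


def fisher_ci(r: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    if not -1.0 < r < 1.0 or n < 4:
        return (float("nan"), float("nan"))
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + conf / 2.0) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


@dataclass
class CorrelationResult:
    r: pd.DataFrame
    n: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    method: str = "pearson"


def correlation_matrix(
    data: pd.DataFrame, method: str = "pearson", min_n: int = 3
) -> CorrelationResult:
    """Pairwise-complete correlation matrix with 95% Fisher-z CIs.

    Cells with a constant column or fewer than ``min_n`` complete pairs are
    undefined (NaN) rather than silently zero.
    """
    cols = list(data.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    n = np.zeros((k, k), int)
    lo = np.full((k, k), np.nan)
    hi = np.full((k, k), np.nan)
    arr = data.to_numpy(float)
    for i in range(k):
        r[i, i] = 1.0
        n[i, i] = int(np.isfinite(arr[:, i]).sum())
    for i, j in combinations(range(k), 2):
        keep = np.isfinite(arr[:, i]) & np.isfinite(arr[:, j])
        m = int(keep.sum())
        n[i, j] = n[j, i] = m
        if m < min_n:
            continue
        x, y = arr[keep, i], arr[keep, j]
        if np.unique(x).size < 2 or np.unique(y).size < 2:
            continue
        if method == "pearson":
            rij = float(stats.pearsonr(x, y).statistic)
        elif method == "spearman":
            rij = float(stats.spearmanr(x, y).statistic)
        else:
            raise ValueError(f"unknown method {method!r}")
        r[i, j] = r[j, i] = rij
        lo[i, j], hi[i, j] = fisher_ci(rij, m)
        lo[j, i], hi[j, i] = lo[i, j], hi[i, j]
    wrap = lambda a: pd.DataFrame(a, index=cols, columns=cols)
    return CorrelationResult(wrap(r), wrap(n), wrap(lo), wrap(hi), method)


@dataclass
class CorrelationComparison:
    """Elementwise comparison of two correlation matrices over the lower
    triangle (diagonal excluded)."""

    n_pairs: int
    mean_abs_diff: float
    max_abs_diff: float
    prop_exceeding: dict[float, float]
    n_sign_flips: int
    sign_flips: list[tuple[str, str]]
    share_second_larger: float  # share of pairs with |r2| > |r1|
    pair_table: pd.DataFrame = field(repr=False, default=None)


def compare_correlation_matrices(
    m1: pd.DataFrame,
    m2: pd.DataFrame,
    thresholds: Sequence[float] = (0.05, 0.10, 0.15, 0.20),
) -> CorrelationComparison:
    """Summarize how two samples' correlation structures differ.

    Matrices must cover the same variable set (order-insensitive; ``m2`` is
    aligned to ``m1``). Pairs undefined in either matrix are dropped.
    """
    m1 = getattr(m1, "r", m1)
    m2 = getattr(m2, "r", m2)
    if set(m1.columns) != set(m2.columns) or set(m1.index) != set(m2.index):
        raise ValueError("correlation matrices cover different variable sets")
    m2 = m2.loc[m1.index, m1.columns]
    rows = []
    for a, b in combinations(list(m1.columns), 2):
        r1, r2 = float(m1.loc[b, a]), float(m2.loc[b, a])
        if np.isnan(r1) or np.isnan(r2):
            continue
        rows.append(
            {
                "var_a": a,
                "var_b": b,
                "r1": r1,
                "r2": r2,
                "abs_diff": abs(r1 - r2),
                "sign_flip": r1 * r2 < 0,
                "second_larger": abs(r2) > abs(r1),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no comparable correlation pairs")
    flips = [(r.var_a, r.var_b) for r in table.itertuples() if r.sign_flip]
    return CorrelationComparison(
        n_pairs=len(table),
        mean_abs_diff=float(table["abs_diff"].mean()),
        max_abs_diff=float(table["abs_diff"].max()),
        prop_exceeding={
            float(t): float((table["abs_diff"] > t).mean()) for t in thresholds
        },
        n_sign_flips=len(flips),
        sign_flips=flips,
        share_second_larger=float(table["second_larger"].mean()),
        pair_table=table,
    )


def load_benchmark(path: str | Path) -> dict:
    """Read a benchmark config: category proportions (normalized per variable,
    so the file may hold percentages) and per-variable means."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    props = {}
    for var, cats in (raw.get("proportions") or {}).items():
        total = float(sum(cats.values()))
        props[var] = {c: float(v) / total for c, v in cats.items()}
    return {
        "source": raw.get("source", ""),
        "proportions": props,
        "means": {k: float(v) for k, v in (raw.get("means") or {}).items()},
    }


def benchmark_table(
    estimates: Mapping[str, Mapping[str, float]],
    benchmark: Mapping[str, float],
) -> pd.DataFrame:
    """Per-variable point estimates by analysis stage with absolute deviations
    from the benchmark.

    ``estimates`` maps stage name (e.g. all / no_fake / weighted, in display
    order) to variable -> estimate; each stage must cover every benchmark
    variable.
    """
    stages = list(estimates)
    rows = []
    for var, bench in benchmark.items():
        row = {"variable": var, "benchmark": float(bench)}
        for stage in stages:
            if var not in estimates[stage]:
                raise KeyError(f"stage {stage!r} missing benchmark variable {var!r}")
            est = float(estimates[stage][var])
            row[stage] = est
            row[f"dev_{stage}"] = abs(est - float(bench))
        rows.append(row)
    cols = ["variable", *stages, "benchmark", *[f"dev_{s}" for s in stages]]
    return pd.DataFrame(rows)[cols].set_index("variable")
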