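"""Analytic-dataset construction: speed and completeness screens, fake-condition
endorsement flags, and the respondent accounting table.

Screening rules (both boundaries strict, so exactly one second per item and
answering exactly half the items are retained):

* too fast: total duration / items assigned < 1 second;
* incomplete: answered / assigned items < one half;
* fake endorser: endorsed at least one of the embedded fake conditions
  (evaluated on the analytic set only; these respondents stay in the analytic
  set and are excluded in sensitivity subsets downstream).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .codebook import Codebook, default_codebook

__all__ = [
    "AccountingTable",
    "ScreeningResult",
    "filter_speeders",
    "filter_incomplete",
    "flag_fake_endorsers",
    "completion_rate",
    "accounting_from_counts",
    "build_analytic",
    "render_accounting",
]

FAKE_CONDITIONS = ("syndomitis", "chekalism")


@dataclass(frozen=True)
class AccountingTable:
    """Respondent bookkeeping: fielded through analytic, with removal counts.

    A respondent who is both too fast and incomplete is counted once, in the
    too-fast row, so the partition ``final_total = n_analytic + n_too_fast +
    n_incomplete`` always holds.
    """

    surveys_fielded: int
    final_total: int
    n_too_fast: int
    n_incomplete: int
    n_analytic: int
    n_fake: int
    completion_rate: float

    def __post_init__(self) -> None:
        if self.final_total - self.n_too_fast - self.n_incomplete != self.n_analytic:
            raise ValueError("accounting counts are inconsistent")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def filter_speeders(
    durations: pd.Series, items_assigned, threshold: float = 1.0
) -> pd.Series:
    """Flag respondents whose mean time per assigned item is < ``threshold`` s."""
    durations = pd.Series(durations).astype(float)
    items = pd.Series(items_assigned, index=durations.index).astype(float) \
        if np.ndim(items_assigned) else pd.Series(float(items_assigned), index=durations.index)
    if (durations <= 0).any():
        raise ValueError("durations must be positive")
    if (items <= 0).any():
        raise ValueError("items_assigned must be positive")
    return (durations / items) < threshold


def filter_incomplete(
    responses: pd.DataFrame, items_assigned=None, min_prop: float = 0.5
) -> pd.Series:
    """Flag respondents who answered strictly less than ``min_prop`` of their
    assigned items (answering exactly the threshold share is retained)."""
    answered = responses.notna().sum(axis=1).astype(float)
    if items_assigned is None:
        items_assigned = responses.shape[1]
    items = pd.Series(items_assigned, index=responses.index).astype(float) \
        if np.ndim(items_assigned) else pd.Series(float(items_assigned), index=responses.index)
    if (items <= 0).any():
        raise ValueError("items_assigned must be positive")
    return (answered / items) < min_prop


def flag_fake_endorsers(
    endorsements: pd.DataFrame, fake_ids=FAKE_CONDITIONS
) -> pd.Series:
    """Flag respondents endorsing one or both fake conditions."""
    missing = [c for c in fake_ids if c not in endorsements.columns]
    if missing:
        raise KeyError(f"fake condition columns missing: {missing}")
    return endorsements[list(fake_ids)].fillna(0).astype(float).sum(axis=1) > 0


def completion_rate(n_analytic: int, n_fielded: int) -> float:
    """Analytic respondents over surveys fielded, as a proportion."""
    if n_fielded <= 0:
        raise ZeroDivisionError("n_fielded must be positive")
    if not 0 < n_analytic <= n_fielded:
        raise ValueError("need 0 < n_analytic <= n_fielded")
    return n_analytic / n_fielded


def accounting_from_counts(
    surveys_fielded: int,
    final_total: int,
    n_too_fast: int,
    n_incomplete: int,
    n_fake: int = 0,
) -> AccountingTable:
    """Accounting table from already-tallied counts (e.g. a published table)."""
    n_analytic = final_total - n_too_fast - n_incomplete
    return AccountingTable(
        surveys_fielded=surveys_fielded,
        final_total=final_total,
        n_too_fast=n_too_fast,
        n_incomplete=n_incomplete,
        n_analytic=n_analytic,
        n_fake=n_fake,
        completion_rate=completion_rate(n_analytic, surveys_fielded),
    )


@dataclass
class ScreeningResult:
    analytic: pd.DataFrame  # cleaned responses, screened rows removed
    flags: pd.DataFrame  # too_fast, incomplete, fake_endorser, in_analytic
    accounting: AccountingTable
    n_out_of_range: int  # out-of-range responses coerced to missing


def build_analytic(
    responses: pd.DataFrame,
    durations: pd.Series,
    endorsements: pd.DataFrame,
    codebook: Codebook | None = None,
    surveys_fielded: int | None = None,
    speed_threshold: float = 1.0,
    min_prop: float = 0.5,
) -> ScreeningResult:
    """Clean responses and apply the screening rules.

    Out-of-range response values are coerced to missing (and counted) rather
    than dropping the respondent. The speed rule divides total duration by the
    full number of assigned items (ordinal items plus checklist/demographic
    items per the codebook); the completeness rule uses the ordinal matrix.
    """
    cb = codebook or default_codebook()
    if responses.index.has_duplicates:
        raise ValueError("duplicate respondent IDs")
    responses = responses.astype(float)
    in_range = responses.isna() | (
        (responses >= cb.response_min)
        & (responses <= cb.response_max)
        & (responses == responses.round())
    )
    n_oor = int((~in_range).to_numpy().sum())
    cleaned = responses.where(in_range)

    too_fast = filter_speeders(durations.loc[responses.index], cb.items_assigned,
                               speed_threshold)
    incomplete = filter_incomplete(cleaned, min_prop=min_prop)
    in_analytic = ~(too_fast | incomplete)
    analytic = cleaned.loc[in_analytic]

    fake = flag_fake_endorsers(endorsements.loc[analytic.index], cb.fake_conditions)
    fake = fake.reindex(responses.index, fill_value=False)

    flags = pd.DataFrame(
        {
            "too_fast": too_fast,
            "incomplete": incomplete,
            "fake_endorser": fake,
            "in_analytic": in_analytic,
        }
    )
    final_total = len(responses)
    n_fast = int(too_fast.sum())
    n_inc = int((incomplete & ~too_fast).sum())
    fielded = final_total if surveys_fielded is None else int(surveys_fielded)
    acc = AccountingTable(
        surveys_fielded=fielded,
        final_total=final_total,
        n_too_fast=n_fast,
        n_incomplete=n_inc,
        n_analytic=final_total - n_fast - n_inc,
        n_fake=int(fake.sum()),
        completion_rate=(final_total - n_fast - n_inc) / fielded if fielded else float("nan"),
    )
    return ScreeningResult(analytic=analytic, flags=flags, accounting=acc,
                           n_out_of_range=n_oor)


def render_accounting(acc: AccountingTable) -> str:
    """Plain-text accounting table (fielded counts through fake endorsement)."""
    pct = lambda a, b: f"{100 * a / b:.1f}" if b else "-"
    rows = [
        ("Surveys fielded, n", f"{acc.surveys_fielded:,}"),
        ("Final total upon field close, n", f"{acc.final_total:,}"),
        (
            "Too short response times (<1 s/item), n (%)",
            f"{acc.n_too_fast} ({pct(acc.n_too_fast, acc.final_total)})",
        ),
        (
            "Incomplete surveys (missing more than half), n/N (%)",
            f"{acc.n_incomplete}/{acc.final_total:,} ({pct(acc.n_incomplete, acc.final_total)})",
        ),
        ("Analytic dataset, n", f"{acc.n_analytic:,}"),
        (
            "Completion rate, n/N (%)",
            f"{acc.n_analytic:,}/{acc.surveys_fielded:,} ({pct(acc.n_analytic, acc.surveys_fielded)})",
        ),
        (
            "Endorsed fake conditions, n/N (%)",
            f"{acc.n_fake}/{acc.n_analytic:,} ({pct(acc.n_fake, acc.n_analytic)})",
        ),
    ]
    width = max(len(r[0]) for r in rows)
    return "\n".join(f"{name:<{width}}  {val}" for name, val in rows)
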