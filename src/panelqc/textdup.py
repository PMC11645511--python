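"""Copied-text detection for open-ended survey answers.

A respondent is flagged when their answer contains a contiguous run of at
least ``min_run`` words that is identical to a run in at least one other
respondent's answer and that covers at least ``min_cover`` of their own
answer's word count. Candidate pairs are found through a shingle (word
n-gram) index, then the exact longest common token run is measured per pair,
so the contract is the rule itself rather than an approximation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from difflib import SequenceMatcher

import pandas as pd

__all__ = ["normalize_tokens", "MatchedRun", "DuplicateReport", "find_copied"]

_WORD = re.compile(r"[^\W_]+", flags=re.UNICODE)


def normalize_tokens(text: str) -> list[str]:
    """Lowercase word tokens with punctuation stripped (deterministic)."""
    if not isinstance(text, str):
        return []
    return [t.casefold() for t in _WORD.findall(text)]


@dataclass(frozen=True)
class MatchedRun:
    respondent: str
    other: str
    run_length: int
    coverage: float  # run_length / respondent's own token count
    excerpt: str


@dataclass
class DuplicateReport:
    flags: pd.Series  # respondent -> bool
    matches: list[MatchedRun] = field(default_factory=list)

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


def find_copied(
    texts, min_run: int = 10, min_cover: float = 0.75
) -> DuplicateReport:
    """Flag answers copied from a common source.

    ``texts`` maps respondent id to raw answer text (Series or dict). Both
    members of a matching pair carry the shared run; each is flagged only if
    the run also covers ``min_cover`` of their *own* answer, so a long answer
    quoting a short one is not itself flagged. Empty answers are never
    flagged.
    """
    series = pd.Series(texts, dtype=object)
    if len(series) < 2:
        raise ValueError("need at least two responses to compare")
    tokens = {rid: normalize_tokens(t) for rid, t in series.items()}

    # shingle index: word n-gram -> responding ids
    index: dict[tuple, set] = {}
    for rid, toks in tokens.items():
        for i in range(len(toks) - min_run + 1):
            index.setdefault(tuple(toks[i : i + min_run]), set()).add(rid)
    candidates: set[tuple] = set()
    for ids in index.values():
        if len(ids) > 1:
            ids = sorted(ids)
            for i, a in enumerate(ids):
                for b in ids[i + 1 :]:
                    candidates.add((a, b))

    best: dict[str, tuple[int, str, list[str]]] = {}
    for a, b in candidates:
        sm = SequenceMatcher(None, tokens[a], tokens[b], autojunk=False)
        m = sm.find_longest_match(0, len(tokens[a]), 0, len(tokens[b]))
        if m.size < min_run:
            continue
        run = tokens[a][m.a : m.a + m.size]
        for rid, other in ((a, b), (b, a)):
            if m.size > best.get(rid, (0,))[0]:
                best[rid] = (m.size, other, run)

    flags = pd.Series(False, index=series.index)
    matches: list[MatchedRun] = []
    for rid, (size, other, run) in sorted(best.items()):
        total = len(tokens[rid])
        coverage = size / total if total else 0.0
        if total and coverage >= min_cover:
            flags.loc[rid] = True
            matches.append(
                MatchedRun(
                    respondent=str(rid),
                    other=str(other),
                    run_length=size,
                    coverage=coverage,
                    excerpt=" ".join(run[:15]),
                )
            )
    return DuplicateReport(flags=flags, matches=matches)
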