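"""Respondent-cohort generator with known ground truth.

Emulates the behavioral mix seen when the same health survey is fielded to an
opt-in convenience panel and to a probability-based panel:

* **attentive** respondents answer through an ordinal latent-trait model
  (correlated domain traits plus item noise, cut into categories 1-5);
* **straightliners** give a constant response within every consecutive
  same-response-category block;
* **speeders** finish in under one second per assigned item;
* **misrepresenters** endorse the embedded fake health conditions and
  over-endorse real ones;
* **copiers** paste a shared template sentence into the open-text prompt;

plus demographic selection bias (multiplicative per-variable distortion of
stated population margins) and a toggle for incomplete surveys. Every
respondent carries a ground-truth persona label so detector sensitivity and
mixture recovery are directly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from ._rng import substream
from .codebook import Codebook, default_codebook, packaged_path

__all__ = [
    "PERSONAS",
    "PersonaConfig",
    "Cohort",
    "generate_cohort",
    "generate_demographics",
    "expected_fake_flag_rate",
    "expected_trait_mean",
]

PERSONAS = ("attentive", "straightliner", "speeder", "misrepresenter", "copier")

#: Sign linking the shared health factor to each domain's item categories:
#: +1 where higher ratings mean better functioning, -1 for symptom domains.
TRAIT_ORIENTATION = {
    "physical_function": 1.0,
    "ability_to_participate": 1.0,
    "cognitive_function": 1.0,
    "anxiety": -1.0,
    "depressive_symptoms": -1.0,
    "fatigue": -1.0,
    "sleep_disturbance": -1.0,
    "pain_interference": -1.0,
}

_ITEM_LOADING = np.sqrt(0.7)  # trait loading; residual variance 0.3
_THRESHOLDS = np.array([-1.5, -0.5, 0.5, 1.5])  # equal-spaced cuts -> categories 1..5


def _normalize_proportions(d: Mapping[str, float], what: str) -> dict[str, float]:
    total = float(sum(d.values()))
    if total <= 0:
        raise ValueError(f"{what}: proportions must be positive")
    return {k: float(v) / total for k, v in d.items()}


@dataclass
class PersonaConfig:
    """Generative parameters for a synthetic respondent cohort."""

    n_respondents: int
    persona_mix: dict[str, float]
    fake_endorse_prob: float = 0.95
    overendorse_prob: float = 0.6
    trait_corr: object = None  # matrix, {"exchangeable": rho}, or None (=0.4)
    demo_marginals: dict[str, dict[str, float]] | None = None
    demo_bias: dict[str, dict[str, float]] | None = None
    demo_trait_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    health_loading: float = 0.5
    missing_rate: float = 0.02
    incomplete_frac: float = 0.0
    # optional secondary behavior: share of misrepresenters who also
    # straight-line (persona labels stay mutually exclusive)
    misrepresenter_straightline_frac: float = 0.0
    duration_median_spi: float = 12.0  # median seconds per assigned item
    duration_sigma: float = 0.5  # lognormal sigma of seconds per item
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 0:
            raise ValueError("n_respondents must be >= 0")
        unknown = set(self.persona_mix) - set(PERSONAS)
        if unknown:
            raise ValueError(f"unknown personas {sorted(unknown)}")
        vals = np.array([self.persona_mix.get(p, 0.0) for p in PERSONAS], float)
        if (vals < 0).any():
            raise ValueError("persona_mix entries must be >= 0")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"persona_mix sums to {vals.sum():.12f}, not 1")
        for p in (self.fake_endorse_prob, self.overendorse_prob, self.missing_rate,
                  self.incomplete_frac, self.misrepresenter_straightline_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.demo_marginals is not None:
            self.demo_marginals = {
                var: _normalize_proportions(cats, f"demo_marginals[{var}]")
                for var, cats in self.demo_marginals.items()
            }
            for var, cats in self.demo_marginals.items():
                if abs(sum(cats.values()) - 1.0) > 1e-9:
                    raise ValueError(f"marginals for {var!r} do not sum to 1")

    @property
    def mix_vector(self) -> np.ndarray:
        return np.array([self.persona_mix.get(p, 0.0) for p in PERSONAS], float)

    def resolve_trait_corr(self, n_traits: int) -> np.ndarray:
        """Materialize the trait correlation matrix and check it is PSD."""
        tc = self.trait_corr
        if tc is None:
            tc = {"exchangeable": 0.4}
        if isinstance(tc, Mapping) and "exchangeable" in tc:
            rho = float(tc["exchangeable"])
            mat = np.full((n_traits, n_traits), rho)
            np.fill_diagonal(mat, 1.0)
        else:
            mat = np.asarray(tc, float)
        if mat.shape != (n_traits, n_traits):
            raise ValueError(f"trait_corr must be {n_traits}x{n_traits}, got {mat.shape}")
        if not np.allclose(mat, mat.T, atol=1e-10):
            raise ValueError("trait_corr must be symmetric")
        if np.linalg.eigvalsh(mat).min() < -1e-8:
            raise ValueError("trait_corr must be positive semi-definite")
        return mat

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PersonaConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw.update(overrides)
        return cls(**raw)


def default_marginals() -> dict[str, dict[str, float]]:
    """Packaged national population margins, normalized to proportions."""
    with open(packaged_path("targets_national.yaml")) as fh:
        raw = yaml.safe_load(fh)
    return {var: _normalize_proportions(cats, var) for var, cats in raw.items()}


@dataclass
class Cohort:
    """Generated survey tables plus ground truth.

    ``responses`` holds raw ordinal answers (1-5, NaN = skipped); reverse-coded
    items are stored as the respondent saw them and are only inverted at
    scoring time.
    """

    responses: pd.DataFrame
    demographics: pd.DataFrame
    durations: pd.Series
    endorsements: pd.DataFrame
    texts: pd.Series
    truth: pd.DataFrame

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.responses.to_csv(path / "responses.csv")
        self.demographics.to_csv(path / "demographics.csv")
        self.durations.to_frame("duration_s").to_csv(path / "durations.csv")
        self.endorsements.to_csv(path / "endorsements.csv")
        self.texts.to_frame("text").to_csv(path / "texts.csv")
        self.truth.to_csv(path / "truth.csv")

    @classmethod
    def from_dir(cls, path: str | Path) -> "Cohort":
        path = Path(path)
        read = lambda n: pd.read_csv(path / n, index_col=0)
        return cls(
            responses=read("responses.csv"),
            demographics=read("demographics.csv"),
            durations=read("durations.csv")["duration_s"],
            endorsements=read("endorsements.csv"),
            texts=read("texts.csv")["text"].fillna(""),
            truth=read("truth.csv"),
        )

    def subset(self, ids) -> "Cohort":
        return Cohort(
            responses=self.responses.loc[ids],
            demographics=self.demographics.loc[ids],
            durations=self.durations.loc[ids],
            endorsements=self.endorsements.loc[ids],
            texts=self.texts.loc[ids],
            truth=self.truth.loc[ids],
        )


def generate_demographics(
    marginals: Mapping[str, Mapping[str, float]],
    bias: Mapping[str, Mapping[str, float]] | None,
    n: int,
    seed_or_rng,
) -> pd.DataFrame:
    """Draw ``n`` respondents' demographics from bias-distorted margins.

    Each variable is sampled independently with category probabilities
    proportional to ``marginal * bias`` (renormalized), so the realized share
    of a category with marginal ``p`` and bias ``b`` converges to
    ``b*p / sum_j b_j p_j``.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    bias = bias or {}
    cols: dict[str, np.ndarray] = {}
    for var, cats in marginals.items():
        names = list(cats)
        probs = np.array([cats[c] for c in names], float)
        bvar = bias.get(var, {})
        unknown = set(bvar) - set(names)
        if unknown:
            raise ValueError(f"bias for {var!r} names unknown categories {sorted(unknown)}")
        mult = np.array([bvar.get(c, 1.0) for c in names], float)
        if (mult < 0).any():
            raise ValueError("bias multipliers must be >= 0")
        probs = probs * mult
        probs = probs / probs.sum()
        cols[var] = rng.choice(names, size=n, p=probs)
    return pd.DataFrame(cols, index=_ids(n))


def _ids(n: int) -> pd.Index:
    return pd.Index([f"R{i:06d}" for i in range(n)], name="respondent_id")


def _vocabulary(n_words: int = 1200) -> list[str]:
    """Deterministic pronounceable vocabulary for word-salad text answers."""
    onsets = ["b", "d", "f", "g", "k", "l", "m", "n", "p", "r", "s", "t", "v", "z"]
    nuclei = ["a", "e", "i", "o", "u"]
    codas = ["", "n", "r", "s", "l", "m", "k", "t"]
    words = []
    for o1 in onsets:
        for v1 in nuclei:
            for o2 in onsets:
                for c in codas:
                    words.append(o1 + v1 + o2 + "a" + c)
                    if len(words) >= n_words:
                        return words
    return words


def _block_excluded_categories(cb: Codebook) -> dict[str, set[int]]:
    """Per consecutive set: allowed categories of any special battery inside it.

    Planted straight-liners avoid these constants so they trip the targeted
    rules, not just the all-sets rule.
    """
    out: dict[str, set[int]] = {name: set() for name in cb.consecutive_sets}
    for name, block in cb.consecutive_sets.items():
        for bat in cb.special_batteries.values():
            if bat.allowed_category is not None and set(bat.items) <= set(block.items):
                out[name].add(bat.allowed_category)
    return out


def generate_cohort(
    config: PersonaConfig,
    codebook: Codebook | None = None,
    seed: int | None = None,
) -> Cohort:
    """Generate a full synthetic cohort (responses, demographics, durations,
    condition endorsements, open-text answers, ground truth)."""
    cb = codebook or default_codebook()
    seed = config.seed if seed is None else int(seed)
    n = config.n_respondents
    ids = _ids(n)
    scale_names = list(cb.scales)
    n_traits = len(scale_names)
    corr = config.resolve_trait_corr(n_traits)
    marginals = config.demo_marginals or default_marginals()

    if n == 0:
        empty = pd.DataFrame(index=ids)
        return Cohort(
            responses=pd.DataFrame(index=ids, columns=list(cb.items), dtype=float),
            demographics=pd.DataFrame(index=ids, columns=list(marginals)),
            durations=pd.Series(index=ids, dtype=float, name="duration_s"),
            endorsements=pd.DataFrame(index=ids, columns=list(cb.all_conditions), dtype=int),
            texts=pd.Series(index=ids, dtype=object, name="text"),
            truth=empty,
        )

    persona = substream(seed, "cohort", "personas").choice(
        PERSONAS, size=n, p=config.mix_vector
    )
    # a lone copier has no partner to share text with; fold it back into the
    # attentive pool so ground truth stays unambiguous
    if (persona == "copier").sum() == 1:
        persona[persona == "copier"] = "attentive"

    demographics = generate_demographics(
        marginals, config.demo_bias, n, substream(seed, "cohort", "demographics")
    )

    # shared health factor from demographic category effects
    health = np.zeros(n)
    for var, effects in config.demo_trait_effects.items():
        if var not in demographics.columns:
            raise ValueError(f"demo_trait_effects names unknown variable {var!r}")
        health += demographics[var].map(lambda c: effects.get(c, 0.0)).to_numpy(float)

    rng_tr = substream(seed, "cohort", "traits")
    z = rng_tr.standard_normal((n, n_traits)) @ np.linalg.cholesky(
        corr + 1e-10 * np.eye(n_traits)
    ).T
    orient = np.array([TRAIT_ORIENTATION.get(s, 1.0) for s in scale_names])
    traits = config.health_loading * health[:, None] * orient[None, :] + z
    trait_ix = {s: i for i, s in enumerate(scale_names)}

    # ordinal responses via latent trait + item noise, cut at equal-spaced thresholds
    rng_resp = substream(seed, "cohort", "responses")
    resid = np.sqrt(1.0 - _ITEM_LOADING**2)
    resp = np.empty((n, cb.n_items))
    for j, item in enumerate(cb.items):
        latent = _ITEM_LOADING * traits[:, trait_ix[cb.trait_of(item)]]
        latent = latent + resid * rng_resp.standard_normal(n)
        cat = np.searchsorted(_THRESHOLDS, latent) + cb.response_min
        if item in cb.reverse_items:
            cat = (cb.response_min + cb.response_max) - cat
        resp[:, j] = cat
    responses = pd.DataFrame(resp, index=ids, columns=list(cb.items))

    # straight-liners: one constant per consecutive block, avoiding allowances
    rng_sl = substream(seed, "cohort", "straightline")
    sl_rows = np.flatnonzero(persona == "straightliner")
    secondary_sl = np.zeros(n, bool)
    if config.misrepresenter_straightline_frac > 0:
        mis_rows = np.flatnonzero(persona == "misrepresenter")
        secondary_sl[mis_rows] = (
            rng_sl.random(mis_rows.size) < config.misrepresenter_straightline_frac
        )
        sl_rows = np.concatenate([sl_rows, np.flatnonzero(secondary_sl)])
    excluded = _block_excluded_categories(cb)
    cats_all = list(range(cb.response_min, cb.response_max + 1))
    for i in sl_rows:
        for name, block in cb.consecutive_sets.items():
            choices = [c for c in cats_all if c not in excluded[name]]
            responses.loc[ids[i], list(block.items)] = rng_sl.choice(choices)

    # independent item skipping for non-straightliner personas
    rng_miss = substream(seed, "cohort", "missingness")
    if config.missing_rate > 0:
        skip = rng_miss.random((n, cb.n_items)) < config.missing_rate
        skip[persona == "straightliner", :] = False
        skip[secondary_sl, :] = False
        responses = responses.mask(pd.DataFrame(skip, index=ids, columns=responses.columns))

    # planted incompletes: attentive respondents answering < half their items
    planted_incomplete = np.zeros(n, bool)
    rng_inc = substream(seed, "cohort", "incomplete")
    n_inc = int(round(config.incomplete_frac * n))
    att_rows = np.flatnonzero(persona == "attentive")
    if n_inc > 0 and len(att_rows) > 0:
        chosen = rng_inc.choice(att_rows, size=min(n_inc, len(att_rows)), replace=False)
        planted_incomplete[chosen] = True
        half = cb.n_items // 2
        for i in chosen:
            keep = rng_inc.choice(
                cb.n_items, size=int(rng_inc.integers(2, max(3, half - 1))), replace=False
            )
            drop = np.setdiff1d(np.arange(cb.n_items), keep)
            responses.iloc[i, drop] = np.nan

    # durations: lognormal seconds-per-item; speeders forced under 1 s/item
    rng_dur = substream(seed, "cohort", "durations")
    spi = config.duration_median_spi * np.exp(
        config.duration_sigma * rng_dur.standard_normal(n)
    )
    fast = persona == "speeder"
    spi[fast] = rng_dur.uniform(0.3, 0.95, size=fast.sum())
    durations = pd.Series(spi * cb.items_assigned, index=ids, name="duration_s")

    # condition endorsements: candid respondents report true status; fake
    # conditions only come from misrepresenters
    rng_end = substream(seed, "cohort", "endorsements")
    from scipy.special import expit, logit

    cond_names = list(cb.conditions)
    prev = np.array([cb.conditions[c] for c in cond_names])
    p_true = expit(logit(prev)[None, :] - 0.8 * health[:, None])
    true_status = (rng_end.random((n, len(cond_names))) < p_true).astype(int)
    endorse = true_status.copy()
    mis = persona == "misrepresenter"
    endorse[mis] = (
        rng_end.random((mis.sum(), len(cond_names))) < config.overendorse_prob
    ).astype(int)
    fake_cols = (
        rng_end.random((n, len(cb.fake_conditions))) < config.fake_endorse_prob
    ).astype(int)
    fake_cols[~mis] = 0
    endorsements = pd.DataFrame(
        np.hstack([endorse, fake_cols]),
        index=ids,
        columns=cond_names + list(cb.fake_conditions),
    )

    # open text: word salad for everyone except copiers, who share templates
    rng_txt = substream(seed, "cohort", "texts")
    vocab = np.array(_vocabulary())
    texts = np.empty(n, dtype=object)
    for i in range(n):
        k = int(rng_txt.integers(12, 26))
        texts[i] = " ".join(rng_txt.choice(vocab, size=k, replace=False))
    cop_rows = np.flatnonzero(persona == "copier")
    if len(cop_rows) >= 2:
        templates = [
            " ".join(rng_txt.choice(vocab, size=14, replace=False)) for _ in range(5)
        ]
        order = rng_txt.permutation(cop_rows)
        for j, i in enumerate(order):
            # pair off copiers; an odd trailing copier joins the previous pair
            g = min(j // 2, (len(order) - 1 - len(order) % 2) // 2)
            texts[i] = templates[g % len(templates)]
    texts = pd.Series(texts, index=ids, name="text")

    truth = pd.DataFrame(
        {
            "persona": persona,
            "planted_incomplete": planted_incomplete,
            "secondary_straightline": secondary_sl,
            "health": health,
        },
        index=ids,
    )
    for s in scale_names:
        truth[f"trait_{s}"] = traits[:, trait_ix[s]]
    for j, c in enumerate(cond_names):
        truth[f"true_{c}"] = true_status[:, j]

    return Cohort(responses, demographics, durations, endorsements, texts, truth)


def expected_fake_flag_rate(config: PersonaConfig, n_fake_conditions: int = 2) -> float:
    """Expected share of respondents endorsing >=1 fake condition under the
    generator's own parameters."""
    p_any = 1.0 - (1.0 - config.fake_endorse_prob) ** n_fake_conditions
    return config.persona_mix.get("misrepresenter", 0.0) * p_any


def expected_trait_mean(
    config: PersonaConfig, scale: str, marginals: Mapping | None = None
) -> float:
    """Population (unbiased-sampling) mean of a domain trait, in closed form
    from the generator's demographic effects and margins."""
    marginals = marginals or config.demo_marginals or default_marginals()
    e_health = 0.0
    for var, effects in config.demo_trait_effects.items():
        cats = marginals[var]
        e_health += sum(cats[c] * effects.get(c, 0.0) for c in cats)
    return config.health_loading * TRAIT_ORIENTATION.get(scale, 1.0) * e_health
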