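"""End-to-end pipeline: simulate -> screen -> metrics -> weight -> compare.

Runs the full data-quality assessment on one or more synthetic panels
(typically a convenience-panel and a probability-panel emulation), producing
an accounting table, a quality-metric bundle computed on the full analytic
set and on the subset excluding fake-condition endorsers, raking weights with
diagnostics, benchmark deviation tables, and a cross-panel correlation
comparison. Every artifact carries a provenance block (seed, config hash) and
each stage draws from its own named random substream, so toggling one stage
never perturbs another's output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import careless, compare, reliability, screening, textdup, weighting
from ._rng import child_seed
from .codebook import Codebook, default_codebook, load_codebook, packaged_path
from .synthetic_cohort import Cohort, PersonaConfig, generate_cohort

__all__ = ["PipelineConfig", "Pipeline", "run_pipeline"]

#: ordinal numeric codings used for demographic correlations
AGE_MIDPOINTS = {"18-29": 23.5, "30-44": 37.0, "45-60": 52.5, "60+": 68.0}


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: Path = Path("panelqc_out")
    codebook: str | None = None  # path; None = packaged instrument
    panels: dict[str, object] = field(default_factory=dict)  # name -> path or mapping
    targets: str | None = None  # raking targets YAML; None = packaged national
    benchmark: str | None = None  # benchmark YAML; None = packaged national
    stages: dict[str, bool] = field(default_factory=dict)
    surveys_fielded: dict[str, int] = field(default_factory=dict)
    reference_n: int = 2000
    max_weight: float = 30.0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if not self.panels:
            self.panels = {
                "convenience": str(packaged_path("personas_convenience.yaml")),
                "probability": str(packaged_path("personas_probability.yaml")),
            }

    def stage_on(self, name: str) -> bool:
        return bool(self.stages.get(name, True))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        return cls(**raw)

    def digest(self) -> str:
        blob = dataclasses.asdict(self)
        blob["outdir"] = str(blob["outdir"])
        return hashlib.sha256(
            json.dumps(blob, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    return obj


class Pipeline:
    """Stage runner; intermediate results are cached in memory and persisted
    under the output directory so stages can also run in separate processes."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.codebook: Codebook = (
            load_codebook(config.codebook) if config.codebook else default_codebook()
        )
        self.targets = weighting.load_targets(
            config.targets or packaged_path("targets_national.yaml")
        )
        self.benchmark = compare.load_benchmark(
            config.benchmark or packaged_path("benchmark_national.yaml")
        )
        self._cohorts: dict[str, Cohort] = {}
        self._reference: pd.DataFrame | None = None  # reference scale scores

    # ------------------------------------------------------------------ util
    def _provenance(self) -> dict:
        return {"seed": self.config.seed, "config_digest": self.config.digest()}

    def _write_json(self, name: str, payload: dict) -> None:
        out = self.config.outdir
        out.mkdir(parents=True, exist_ok=True)
        payload = dict(payload)
        payload["provenance"] = self._provenance()
        (out / name).write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")

    def _persona_config(self, panel: str) -> PersonaConfig:
        spec = self.config.panels[panel]
        if isinstance(spec, (str, Path)):
            return PersonaConfig.from_yaml(spec)
        return PersonaConfig(**spec)

    def cohort(self, panel: str) -> Cohort:
        if panel not in self._cohorts:
            cdir = self.config.outdir / "cohorts" / panel
            if (cdir / "responses.csv").exists():
                self._cohorts[panel] = Cohort.from_dir(cdir)
            else:
                self._cohorts[panel] = self._simulate_panel(panel)
        return self._cohorts[panel]

    def screened(self, panel: str) -> screening.ScreeningResult:
        c = self.cohort(panel)
        return screening.build_analytic(
            c.responses,
            c.durations,
            c.endorsements,
            self.codebook,
            surveys_fielded=self.config.surveys_fielded.get(panel),
        )

    def subsets(self, panel: str) -> dict[str, pd.Index]:
        """Row sets for the two reporting columns: full analytic sample and
        the sample excluding fake-condition endorsers."""
        res = self.screened(panel)
        fake = res.flags.loc[res.analytic.index, "fake_endorser"]
        return {"all": res.analytic.index, "no_fake": res.analytic.index[~fake]}

    # ---------------------------------------------------------------- stages
    def _simulate_panel(self, panel: str) -> Cohort:
        cfg = self._persona_config(panel)
        return generate_cohort(
            cfg, self.codebook, seed=child_seed(self.config.seed, "simulate", panel)
        )

    def simulate(self) -> dict[str, Cohort]:
        for panel in self.config.panels:
            cohort = self._simulate_panel(panel)
            self._cohorts[panel] = cohort
            cohort.to_dir(self.config.outdir / "cohorts" / panel)
        return self._cohorts

    def screen(self) -> dict[str, screening.AccountingTable]:
        out = {}
        for panel in self.config.panels:
            res = self.screened(panel)
            self._write_json(
                f"accounting_{panel}.json",
                {"accounting": res.accounting, "n_out_of_range": res.n_out_of_range},
            )
            (self.config.outdir / f"accounting_{panel}.txt").write_text(
                screening.render_accounting(res.accounting) + "\n"
            )
            res.flags.to_csv(self.config.outdir / f"flags_{panel}.csv")
            out[panel] = res.accounting
        return out

    def metrics(self) -> dict[str, dict]:
        cb = self.codebook
        rng_range = (cb.response_min, cb.response_max)
        out = {}
        for panel in self.config.panels:
            cohort = self.cohort(panel)
            res = self.screened(panel)
            bundle: dict[str, dict] = {}
            alphas: dict[str, dict[str, reliability.AlphaResult]] = {}
            for label, idx in self.subsets(panel).items():
                resp = res.analytic.loc[idx]
                m: dict = {"n": int(len(resp))}
                m["kappa_pairs"] = {
                    p.label: (lambda k: {"kappa": k, "interpretation":
                                         careless.interpret_kappa(k) if np.isfinite(k) else None})(
                        careless.weighted_kappa(
                            resp[p.item_a], resp[p.item_b],
                            categories=np.arange(cb.response_min, cb.response_max + 1),
                        )
                    )
                    for p in cb.item_pairs
                }
                rule1 = careless.straightline_all_sets(resp, cb.consecutive_sets)
                rule2 = careless.straightline_battery(
                    resp, cb.special_batteries["physical_function_6"]
                )
                sleep1 = cb.special_batteries["sleep_set_1"]
                sleep2 = cb.special_batteries["sleep_set_2"]
                rule3 = careless.straightline_battery(resp, sleep1) | \
                    careless.straightline_battery(resp, sleep2)
                m["straightlining"] = {
                    "all_sets": {"n": int(rule1.sum()), "pct": 100 * rule1.mean()},
                    "physical_function": {"n": int(rule2.sum()), "pct": 100 * rule2.mean()},
                    "sleep_sets": {"n": int(rule3.sum()), "pct": 100 * rule3.mean()},
                }
                for bname, bat in (("sleep_set_1", sleep1), ("sleep_set_2", sleep2)):
                    rp = careless.mean_root_of_pairs(resp, bat, rng_range)
                    m[f"root_of_pairs_{bname}"] = {
                        "mean": float(rp.mean()), "sd": float(rp.std(ddof=1)),
                    }
                alphas[label] = {
                    name: reliability.cronbach_alpha(resp, sc, rng_range)
                    for name, sc in cb.scales.items()
                }
                m["cronbach_alpha"] = {
                    name: {"alpha": a.alpha, "n": a.n, "k": a.k}
                    for name, a in alphas[label].items()
                }
                complete_all = resp.notna().all(axis=1)
                m["completed_all_items"] = {
                    "n": int(complete_all.sum()), "pct": 100 * complete_all.mean(),
                }
                m["response_burden_minutes"] = careless.winsorized_burden(
                    cohort.durations.loc[idx]
                )
                dup = textdup.find_copied(cohort.texts.loc[idx])
                m["copied_text"] = {
                    "n": dup.n_flagged, "pct": 100 * dup.n_flagged / len(idx),
                }
                bundle[label] = m
            # alpha shift when fake endorsers are removed, tested as if the
            # two columns were independent samples (reporting convention)
            bundle["alpha_comparison_all_vs_no_fake"] = {
                name: reliability.compare_alphas(
                    alphas["all"][name].alpha, alphas["all"][name].n, cb.scales[name].k,
                    alphas["no_fake"][name].alpha, alphas["no_fake"][name].n,
                    cb.scales[name].k,
                )
                for name in cb.scales
                if alphas["all"][name].alpha < 1 and alphas["no_fake"][name].alpha < 1
            }
            self._write_json(f"metrics_{panel}.json", {"metrics": bundle})
            out[panel] = bundle
        return out

    def weight(self) -> dict[str, weighting.WeightVector]:
        out = {}
        for panel in self.config.panels:
            cohort = self.cohort(panel)
            idx = self.subsets(panel)["no_fake"]
            wv = weighting.rake(
                cohort.demographics.loc[idx],
                self.targets,
                max_weight=self.config.max_weight,
            )
            wv.to_csv(self.config.outdir / f"weights_{panel}.csv")
            self._write_json(f"weight_diagnostics_{panel}.json", wv.diagnostics())
            out[panel] = wv
        return out

    def _reference_scores(self) -> pd.DataFrame:
        """Scale scores of an unbiased attentive reference cohort (the
        synthetic stand-in for a national calibration sample)."""
        if self._reference is None:
            base = self._persona_config(next(iter(self.config.panels)))
            ref_cfg = dataclasses.replace(
                base,
                n_respondents=self.config.reference_n,
                persona_mix={"attentive": 1.0},
                demo_bias=None,
                incomplete_frac=0.0,
                missing_rate=0.0,
            )
            ref = generate_cohort(
                ref_cfg, self.codebook, seed=child_seed(self.config.seed, "reference")
            )
            self._reference = compare.score_scales(ref.responses, self.codebook)
        return self._reference

    def compare_panels(self) -> dict:
        cb = self.codebook
        ref = self._reference_scores()
        use_weights = self.config.stage_on("weight")
        weights = {
            p: (self.weight_vector_cached(p) if use_weights else None)
            for p in self.config.panels
        }
        panel_outputs: dict[str, dict] = {}
        corr_results: dict[str, compare.CorrelationResult] = {}
        for panel in self.config.panels:
            cohort = self.cohort(panel)
            subs = self.subsets(panel)
            scores = compare.score_scales(
                self.screened(panel).analytic, cb
            )
            tscores = pd.DataFrame(
                {s: compare.tscore_standardize(scores[s], ref[s]) for s in scores.columns}
            )
            stages_demo: dict[str, dict[str, float]] = {}
            stages_t: dict[str, dict[str, float]] = {}
            stage_plan = [("all", subs["all"], None), ("no_fake", subs["no_fake"], None)]
            if weights[panel] is not None:
                stage_plan.append(("weighted", subs["no_fake"], weights[panel].weights))
            for stage, idx, w in stage_plan:
                demo = cohort.demographics.loc[idx]
                dd: dict[str, float] = {}
                for var, cats in self.benchmark["proportions"].items():
                    props = (
                        weighting.weighted_proportions(demo[var], w.loc[idx])
                        if w is not None
                        else weighting.weighted_proportions(demo[var], np.ones(len(idx)))
                    )
                    for cat, share in cats.items():
                        dd[f"{var}={cat}"] = 100 * props.get(cat, 0.0)
                stages_demo[stage] = dd
                tt: dict[str, float] = {}
                for s in tscores.columns:
                    vals = tscores.loc[idx, s]
                    tt[s] = (
                        weighting.weighted_mean(vals, w.loc[idx])
                        if w is not None
                        else float(vals.mean())
                    )
                stages_t[stage] = tt
            bench_demo = {
                f"{var}={cat}": 100 * share
                for var, cats in self.benchmark["proportions"].items()
                for cat, share in cats.items()
            }
            demo_table = compare.benchmark_table(stages_demo, bench_demo)
            t_table = compare.benchmark_table(stages_t, self.benchmark["means"])
            if "weighted" in stages_t:
                t_table["small_effect_weighted"] = [
                    compare.effect_flag(r["weighted"], r["benchmark"])
                    for _, r in t_table.iterrows()
                ]
            demo_table.to_csv(self.config.outdir / f"benchmark_demographics_{panel}.csv")
            t_table.to_csv(self.config.outdir / f"benchmark_tscores_{panel}.csv")
            panel_outputs[panel] = {
                "demographics": demo_table,
                "tscores": t_table,
            }
            # unweighted correlations on the no-fake subset
            idx = subs["no_fake"]
            frame = tscores.loc[idx].copy()
            demo = cohort.demographics.loc[idx]
            frame["age"] = demo["age_group"].map(AGE_MIDPOINTS)
            frame["education"] = demo["education"].map(
                {c: i + 1 for i, c in enumerate(cb.demographic_variables["education"])}
            )
            frame["income"] = demo["income"].map(
                {c: i + 1 for i, c in enumerate(cb.demographic_variables["income"])}
            )
            cres = compare.correlation_matrix(frame)
            cres.r.to_csv(self.config.outdir / f"correlations_{panel}.csv")
            corr_results[panel] = cres

        result: dict = {"panels": list(self.config.panels)}
        names = list(corr_results)
        if len(names) >= 2:
            summary = compare.compare_correlation_matrices(
                corr_results[names[0]], corr_results[names[1]]
            )
            result["correlation_comparison"] = {
                "n_pairs": summary.n_pairs,
                "mean_abs_diff": summary.mean_abs_diff,
                "max_abs_diff": summary.max_abs_diff,
                "prop_exceeding": summary.prop_exceeding,
                "n_sign_flips": summary.n_sign_flips,
                "sign_flips": summary.sign_flips,
                "share_second_larger": summary.share_second_larger,
            }
        self._write_json("comparison.json", result)
        self._panel_outputs = panel_outputs
        return result

    def weight_vector_cached(self, panel: str) -> weighting.WeightVector:
        if not hasattr(self, "_weights"):
            self._weights = {}
        if panel not in self._weights:
            path = self.config.outdir / f"weights_{panel}.csv"
            cohort = self.cohort(panel)
            idx = self.subsets(panel)["no_fake"]
            if path.exists():
                w = pd.read_csv(path, index_col=0)["weight"]
                self._weights[panel] = weighting.WeightVector(
                    weights=w, iterations=-1, converged=True,
                    max_weight_cap=self.config.max_weight,
                    total_absolute_imbalance=weighting.total_absolute_imbalance(
                        cohort.demographics.loc[w.index], w, self.targets
                    ),
                    cap_hits=0,
                )
            else:
                self._weights[panel] = weighting.rake(
                    cohort.demographics.loc[idx], self.targets,
                    max_weight=self.config.max_weight,
                )
        return self._weights[panel]

    def run(self) -> dict:
        """Execute the enabled stages in order and write the report bundle."""
        cfg = self.config
        report: dict = {}
        if cfg.stage_on("simulate"):
            self.simulate()
        if cfg.stage_on("screen"):
            report["accounting"] = {p: a for p, a in self.screen().items()}
        if cfg.stage_on("metrics"):
            report["metrics"] = self.metrics()
        if cfg.stage_on("weight"):
            report["weights"] = {p: w.diagnostics() for p, w in self.weight().items()}
        if cfg.stage_on("compare"):
            report["comparison"] = self.compare_panels()
        self._write_json("report.json", report)
        return report


def run_pipeline(config: PipelineConfig) -> dict:
    return Pipeline(config).run()
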