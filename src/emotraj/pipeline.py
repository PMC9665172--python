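"""End-to-end orchestration: simulate -> clean -> score -> aggregate -> fit -> wordfreq.

A run is driven by a :class:`RunConfig` (loadable from YAML).  Each stage
writes its table to the output directory and records its in/out counts
in a manifest, so the audit arithmetic (posts dropped per rule, users
dropped per filter) is reproducible on any input.  A manifest hash over
the canonical config and the stage counts makes deterministic reruns
verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import aggregate as agg
from . import cleaning, mlm, scoring, synthetic, wordfreq
from .aggregate import DEFAULT_WINDOW, RegionConfig, StudyWindow
from .lexicon import Lexicon, load_lexicon, save_lexicon
from .mlm import DEFAULT_ANCHORS


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str = "emotraj_run"
    seed: int = 20200123
    # input paths; when absent the synthetic generator supplies them
    lexicon_path: Optional[str] = None
    posts_path: Optional[str] = None
    # synthetic overrides (ignored when posts_path is given)
    n_wuhan: int = 150
    n_non_hubei: int = 450
    window: StudyWindow = DEFAULT_WINDOW
    anchors: tuple = DEFAULT_ANCHORS
    cohort: str = "dataset2"
    weights: str = "user"
    min_users_per_day: int = 50
    models: tuple = ("empty", "model1", "model2")
    outcomes: tuple = ("valence", "arousal")
    top_words: int = 100
    regions: RegionConfig = field(default_factory=lambda: agg.DEFAULT_REGIONS)
    stages: tuple = ("simulate", "clean", "score", "aggregate", "fit", "wordfreq")

    def validate(self) -> None:
        if self.cohort not in {"dataset1", "dataset2"}:
            raise ValueError(f"unknown cohort rules {self.cohort!r}")
        if not set(self.models) <= {"empty", "model1", "model2"}:
            raise ValueError(f"unknown models in {self.models}")
        unknown = set(self.stages) - {"simulate", "clean", "score", "aggregate",
                                      "fit", "wordfreq"}
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}

        def _date(x):
            return x if isinstance(x, date) else date.fromisoformat(str(x))

        if "window" in raw:
            w = raw["window"]
            raw["window"] = StudyWindow(_date(w["start"]), _date(w["end"]),
                                        _date(w["event"]))
        if "anchors" in raw:
            raw["anchors"] = tuple(_date(a) for a in raw["anchors"])
        for key in ("models", "outcomes", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def canonical(self) -> dict:
        out = dataclasses.asdict(self)
        out["window"] = [self.window.start.isoformat(), self.window.end.isoformat(),
                         self.window.event.isoformat()]
        out["anchors"] = [a.isoformat() for a in self.anchors]
        return out


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.canonical(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order.

    Writes all stage tables plus ``report.json`` (emotion-map
    proportions, quadratic fit, by-day trajectories, descriptives,
    model tables) and ``manifest.json`` (config hash, seed, per-stage
    record counts) under ``config.out_dir``.  Stage failures raise
    :class:`PipelineError` naming the stage; tables written before the
    failure are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": _config_hash(config), "seed": config.seed,
                      "stages": {}}
    report: dict = {}

    def _finish() -> dict:
        manifest["manifest_hash"] = hashlib.sha256(
            json.dumps(manifest, sort_keys=True, default=str).encode()
        ).hexdigest()
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        return {"manifest": manifest, "report": report, "out_dir": str(out)}

    # ---- simulate / load ------------------------------------------------
    lexicon: Lexicon
    if "simulate" in config.stages and config.posts_path is None:
        try:
            synth = synthetic.SynthConfig(
                seed=config.seed,
                n_wuhan=config.n_wuhan,
                n_non_hubei=config.n_non_hubei,
                window=config.window,
                anchors=config.anchors,
            )
            corpus = synthetic.gen_corpus(synth)
            lexicon = corpus.lexicon
            posts = corpus.posts
            save_lexicon(lexicon, out / "lexicon.tsv")
            cleaning.write_posts(posts, out / "posts.jsonl")
            corpus.truth.person_days.to_csv(out / "truth_person_days.csv", index=False)
            manifest["stages"]["simulate"] = {
                "n_users": config.n_wuhan + config.n_non_hubei,
                "n_posts": len(posts),
            }
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise PipelineError("simulate", str(exc)) from exc
    else:
        try:
            if config.lexicon_path is None or config.posts_path is None:
                raise ValueError("lexicon_path and posts_path required without simulate")
            lexicon = load_lexicon(config.lexicon_path)
            posts = cleaning.read_posts(config.posts_path)
            manifest["stages"]["load"] = {"n_posts": len(posts)}
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("load", str(exc)) from exc

    # ---- clean ----------------------------------------------------------
    try:
        clean, errors = cleaning.clean_posts(posts)
        clean.to_csv(out / "clean.csv", index=False)
        manifest["stages"]["clean"] = {
            "in": len(posts), "out": len(clean), "rejected": len(errors),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("clean", str(exc)) from exc

    # ---- score ----------------------------------------------------------
    try:
        scores = scoring.score_posts(clean, lexicon)
        scores.drop(columns=["token_counts"]).to_csv(out / "scores.csv", index=False)
        summary = scoring.emotion_map_summary(scores)
        summary.to_csv(out / "emotion_map.csv")
        report["emotion_map"] = summary["proportion"].round(6).to_dict()
        n_scored = int(scores["valence"].notna().sum())
        if n_scored >= 4 and scores["valence"].nunique() >= 3:
            quad = scoring.fit_quadratic(scores)
            report["quadratic"] = {
                "intercept": quad.intercept, "linear": quad.linear,
                "quadratic": quad.quadratic, "r_squared": quad.r_squared,
                "f_stat": quad.f_stat, "df": list(quad.df), "n": quad.n,
            }
        manifest["stages"]["score"] = {
            "in": len(clean), "scored": n_scored,
            "missing": int(len(scores) - n_scored),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("score", str(exc)) from exc

    if "aggregate" not in config.stages:
        return _finish()

    # ---- aggregate ------------------------------------------------------
    try:
        groups = agg.assign_user_groups(scores, config.regions, config.window.event)
        scores = scores.merge(groups.rename("group"), left_on="user_id",
                              right_index=True, how="left")
        scores["group"] = scores["group"].fillna("excluded")
        n_excluded = int((scores["group"] == "excluded").sum())
        scores = scores[scores["group"] != "excluded"]
        filtered, audit = agg.filter_cohort(scores, config.window, config.cohort)
        person_days = agg.person_day(filtered)
        days = agg.by_day(person_days, grouped=True, weights=config.weights)
        desc = agg.descriptives(person_days)
        person_days.to_csv(out / "person_day.csv", index=False)
        days.to_csv(out / "by_day.csv", index=False)
        desc.to_csv(out / "descriptives.csv", index=False)
        report["descriptives"] = desc.round(6).to_dict(orient="records")
        manifest["stages"]["aggregate"] = {
            "excluded_location": n_excluded, **audit,
            "person_days": len(person_days),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("aggregate", str(exc)) from exc

    # ---- fit ------------------------------------------------------------
    if "fit" in config.stages:
        try:
            design = mlm.build_slope_design(
                StudyWindow(config.anchors[0], config.window.end, config.window.event),
                config.anchors,
            )
            design.to_csv(out / "slope_design.csv")
            fixed_rows, random_rows, lrt_rows = [], [], []
            report["models"] = {}
            pdays = mlm.attach_design(person_days, design)
            pdays = mlm.filter_min_users_per_day(pdays, config.min_users_per_day)
            for outcome in config.outcomes:
                for model in config.models:
                    key = f"{model}_{outcome}"
                    if model == "empty":
                        fit = mlm.fit_empty_model(pdays, outcome)
                        lrt = mlm.empty_model_lrt(pdays, outcome, fit)
                        report["models"][key] = {
                            "icc": fit.icc,
                            "between_var": float(fit.cov_re.iloc[0, 0]),
                            "residual_var": fit.residual_sd**2,
                            "minus2ll": fit.minus2ll,
                            "lrt_chisq": lrt.chisq, "lrt_df": lrt.df, "lrt_p": lrt.p,
                        }
                        continue
                    fit = mlm.fit_model(pdays, outcome, model)
                    lrts = mlm.random_effect_lrt_table(pdays, outcome, model, full=fit)
                    for r in fit.fixed.itertuples(index=False):
                        fixed_rows.append({"model": model, "outcome": outcome,
                                           "term": r.term, "estimate": r.estimate,
                                           "se": r.se, "p": r.p})
                    for term in fit.random_terms:
                        random_rows.append({"model": model, "outcome": outcome,
                                            "term": term,
                                            "sd": float(fit.random_sd[term])})
                    for r in lrts.itertuples(index=False):
                        lrt_rows.append({"model": model, "outcome": outcome,
                                         "term": r.term, "chisq": r.chisq,
                                         "df": r.df, "p": r.p})
                    report["models"][key] = {
                        "fixed": fit.fixed.round(6).to_dict(orient="records"),
                        "residual_sd": fit.residual_sd,
                        "minus2ll": fit.minus2ll,
                        "converged": fit.converged,
                        "n_obs": fit.n_obs, "n_users": fit.n_users,
                    }
            pd.DataFrame(fixed_rows).to_csv(out / "fixed_effects.csv", index=False)
            pd.DataFrame(random_rows).to_csv(out / "random_effects.csv", index=False)
            pd.DataFrame(lrt_rows).to_csv(out / "lrt.csv", index=False)
            manifest["stages"]["fit"] = {
                "n_obs": len(pdays), "models": len(report["models"]),
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("fit", str(exc)) from exc

    # ---- wordfreq -------------------------------------------------------
    if "wordfreq" in config.stages:
        try:
            pre = wordfreq.word_frequencies(
                scores, config.window.start,
                config.window.event - timedelta(days=1),
                k=config.top_words,
            )
            post = wordfreq.word_frequencies(
                scores, config.window.event, config.window.end, k=config.top_words,
            )
            pre.table.to_csv(out / "word_freq_pre.csv", index=False)
            post.table.to_csv(out / "word_freq_post.csv", index=False)
            manifest["stages"]["wordfreq"] = {
                "pre_tokens": pre.total_tokens, "post_tokens": post.total_tokens,
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("wordfreq", str(exc)) from exc

    return _finish()
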