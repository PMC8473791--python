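"""End-to-end orchestration of the two-step impairment analysis.

The pipeline runs: cohort acquisition (synthetic generation or CSV input)
-> behavioral scoring -> sham-only threshold derivation -> subject
labeling -> per-ion dataset assembly (dose + the four prescreen ATRC
scores as features) -> class-weighted LOOCV for each classifier -> the
full metric report, and writes every artifact with the configuration and
seed embedded so a rerun with the same config is byte-identical.

Each ion is analyzed in its own model run against sham (sham arms plus
that ion's arms at the configured doses); subjects missing any required
prescreen stage, or the post stage being predicted, are excluded and the
exclusions are counted by reason.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifiers import make_classifier
from .evaluation import loocv_scores, metrics_report, roc_curve, pr_curve
from .impairment import ImpairmentRule, derive_threshold, label_impairment, percent_impaired
from .population import group_comparisons, summary_table
from .scoring import (
    PRESCREEN_STAGES,
    Subject,
    read_trial_log_csv,
    scores_table,
    write_trial_log_csv,
)
from .synthetic import GenerativeParams, StudyDesign, Arm, default_design, generate_cohort


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one analysis run."""

    source: str = "synthetic"  # synthetic | trials_csv | scores_csv
    input_path: str | None = None
    design: StudyDesign = field(default_factory=default_design)
    params: GenerativeParams = field(default_factory=GenerativeParams)
    stages: tuple[str, ...] = ("SD", "CD")
    score_type: str = "ATRC"
    level: float = 0.95
    tie_rule: str = "strict_below"
    ions: tuple[str, ...] = ("He", "Si", "Fe")
    doses: tuple[float, ...] = (0.0, 1.0, 5.0, 10.0)
    feature_stages: tuple[str, ...] = PRESCREEN_STAGES
    classifiers: tuple[str, ...] = ("GNB", "SVM", "ANN")
    hyperparams: Mapping[str, Mapping] = field(default_factory=dict)
    cutoff: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.level <= 1.0:
            raise ValueError("level must lie in (0, 1]")
        if self.source not in ("synthetic", "trials_csv", "scores_csv"):
            raise ValueError(f"unknown source {self.source!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"] = design_to_dict(self.design)
        d["params"] = params_to_dict(self.params)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "design" in d and not isinstance(d["design"], StudyDesign):
            d["design"] = design_from_dict(d["design"])
        if "params" in d and not isinstance(d["params"], GenerativeParams):
            d["params"] = params_from_dict(d["params"])
        for key in ("stages", "ions", "doses", "feature_stages", "classifiers"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def design_to_dict(design: StudyDesign) -> dict:
    return {
        "arms": [[a.ion, a.dose_cgy, a.n] for a in design.arms],
        "stages_prescreen": list(design.stages_prescreen),
        "stages_post": list(design.stages_post),
    }


def design_from_dict(d: Mapping) -> StudyDesign:
    kwargs = {}
    if "stages_prescreen" in d:
        kwargs["stages_prescreen"] = tuple(d["stages_prescreen"])
    if "stages_post" in d:
        kwargs["stages_post"] = tuple(d["stages_post"])
    arms = tuple(Arm(ion, float(dose), int(n)) for ion, dose, n in d["arms"])
    return StudyDesign(arms=arms, **kwargs)


def params_to_dict(params: GenerativeParams) -> dict:
    d = dataclasses.asdict(params)
    d["susceptibility"] = [[ion, stage, coef] for (ion, stage), coef in params.susceptibility.items()]
    d["dose_overrides"] = [
        [ion, stage, [[float(dose), dec] for dose, dec in ov.items()]]
        for (ion, stage), ov in params.dose_overrides.items()
    ]
    return d


def params_from_dict(d: Mapping) -> GenerativeParams:
    d = dict(d)
    if "susceptibility" in d:
        d["susceptibility"] = {(ion, st): float(c) for ion, st, c in d["susceptibility"]}
    if "dose_overrides" in d:
        d["dose_overrides"] = {
            (ion, st): {float(dose): float(dec) for dose, dec in ov}
            for ion, st, ov in d["dose_overrides"]
        }
    return GenerativeParams(**d)


# ---------------------------------------------------------------------------
# Dataset assembly


def subject_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Wide per-subject table: pre_<stage> and post_<stage> ATRC columns."""
    base = scores[["subject_id", "ion", "dose_cgy"]].drop_duplicates("subject_id")
    wide = base.set_index("subject_id")
    for phase, prefix in (("prescreen", "pre"), ("post", "post")):
        sub = scores[scores["phase"] == phase]
        piv = sub.pivot_table(
            index="subject_id", columns="stage", values="atrc", aggfunc="first"
        )
        piv.columns = [f"{prefix}_{c}" for c in piv.columns]
        wide = wide.join(piv)
    return wide.reset_index()


def filter_dataset(
    table: pd.DataFrame,
    ions: Sequence[str],
    doses: Sequence[float],
    required_columns: Sequence[str],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Subset a wide subject table; count exclusions by reason."""
    excluded = {"ion": 0, "dose": 0, "missing_stage": 0}
    keep_ion = table["ion"].isin(list(ions))
    excluded["ion"] = int((~keep_ion).sum())
    t = table[keep_ion]
    keep_dose = t["dose_cgy"].isin([float(d) for d in doses])
    excluded["dose"] = int((~keep_dose).sum())
    t = t[keep_dose]
    missing = [c for c in required_columns if c not in t.columns]
    if missing:
        excluded["missing_stage"] += len(t)
        return t.iloc[0:0], excluded
    complete = t[list(required_columns)].notna().all(axis=1)
    excluded["missing_stage"] = int((~complete).sum())
    return t[complete].copy(), excluded


def build_dataset(
    table: pd.DataFrame,
    rule: ImpairmentRule,
    ions: Sequence[str],
    doses: Sequence[float],
    feature_stages: Sequence[str] = PRESCREEN_STAGES,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, dict[str, int]]:
    """Features (dose + prescreen ATRCs), labels and the retained rows."""
    required = [f"pre_{s}" for s in feature_stages] + [f"post_{rule.stage}"]
    subset, excluded = filter_dataset(table, ions, doses, required)
    X = subset[["dose_cgy"] + [f"pre_{s}" for s in feature_stages]].to_numpy(float)
    y = np.array(
        [int(label_impairment(v, rule)) for v in subset[f"post_{rule.stage}"]]
    )
    return X, y, subset, excluded


# ---------------------------------------------------------------------------
# Report bundle


@dataclass
class ReportBundle:
    config: PipelineConfig
    scores: pd.DataFrame
    rules: dict[str, ImpairmentRule]
    summaries: dict[str, pd.DataFrame]
    comparisons: dict[str, pd.DataFrame]
    percent_impaired: dict[str, pd.DataFrame]
    metrics: pd.DataFrame
    curves: dict[str, dict[str, object]]
    notes: list[str]
    subjects: list[Subject] | None = None


METRICS_COLUMNS = [
    "stage",
    "ion",
    "threshold_rule",
    "classifier",
    "n",
    "n_impaired",
    "accuracy_pct",
    "auc_roc",
    "auc_pr",
    "mcc",
    "f1",
    "tp",
    "tn",
    "fp",
    "fn",
    "skipped_folds",
    "failed_folds",
]


def _acquire(config: PipelineConfig) -> tuple[list[Subject] | None, pd.DataFrame]:
    if config.source == "synthetic":
        subjects = generate_cohort(config.design, config.params, config.seed)
        return subjects, scores_table(subjects)
    if config.source == "trials_csv":
        subjects = read_trial_log_csv(config.input_path)
        return subjects, scores_table(subjects)
    return None, pd.read_csv(config.input_path)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> ReportBundle:
    subjects, scores = _acquire(config)
    post = scores[scores["phase"] == "post"]
    sham_post = post[post["ion"] == "sham"]
    if sham_post.empty:
        raise ValueError("no sham subjects: impairment thresholds cannot be derived")

    score_col = {"ATRC": "atrc", "MCL": "mcl_s"}[config.score_type]
    grid = "integer" if config.score_type == "ATRC" else "observed"
    rules: dict[str, ImpairmentRule] = {}
    summaries: dict[str, pd.DataFrame] = {}
    comparisons: dict[str, pd.DataFrame] = {}
    pct: dict[str, pd.DataFrame] = {}
    notes: list[str] = []
    analysis_ions = [i for i in config.ions if i != "sham"]

    for stage in config.stages:
        stage_post = post[post["stage"] == stage]
        sham_scores = sham_post.loc[sham_post["stage"] == stage, score_col].dropna()
        if sham_scores.empty:
            notes.append(f"stage {stage}: no sham scores; skipped")
            continue
        rules[stage] = derive_threshold(
            sham_scores,
            level=config.level,
            stage=stage,
            score_type=config.score_type,
            grid=grid,
            tie_rule=config.tie_rule,
        )
        vis = stage_post[
            stage_post["ion"].isin(["sham", *analysis_ions])
            & stage_post["dose_cgy"].isin(config.doses)
        ]
        summaries[stage] = summary_table(vis, score_col)
        comparisons[stage] = group_comparisons(vis, score_col)
        pct[stage] = percent_impaired(vis, rules[stage])

    table = subject_table(scores)
    metric_rows = []
    curves: dict[str, dict[str, object]] = {}
    for stage, rule in rules.items():
        for ion in analysis_ions:
            X, y, subset, excluded = build_dataset(
                table, rule, ["sham", ion], config.doses, config.feature_stages
            )
            tag = f"{stage}_{ion}"
            if subset.empty or (subset["ion"] == ion).sum() == 0:
                notes.append(
                    f"{tag}: no {ion} subjects after filtering; classification skipped"
                )
                continue
            if len(np.unique(y)) < 2:
                notes.append(
                    f"{tag}: single-class labels after thresholding; "
                    "classification skipped"
                )
                continue
            for name in config.classifiers:
                hyper = dict(config.hyperparams.get(name, {}))
                factory = lambda fs, _n=name, _h=hyper: make_classifier(_n, seed=fs, **_h)
                res = loocv_scores(X, y, factory, seed=config.seed)
                ok = res.evaluated
                report = metrics_report(res.labels[ok], res.scores[ok], config.cutoff)
                roc = roc_curve(res.labels[ok], res.scores[ok])
                pr = pr_curve(res.labels[ok], res.scores[ok])
                curves[f"{tag}_{name}"] = {"roc": roc, "pr": pr}
                metric_rows.append(
                    {
                        "stage": stage,
                        "ion": ion,
                        "threshold_rule": f"{stage} {config.score_type} >= {rule.threshold:g}",
                        "classifier": name,
                        "n": int(ok.sum()),
                        "n_impaired": int(res.labels[ok].sum()),
                        "accuracy_pct": 100.0 * report.accuracy,
                        "auc_roc": report.auc_roc,
                        "auc_pr": report.auc_pr,
                        "mcc": report.mcc,
                        "f1": report.f1,
                        "tp": report.counts.tp,
                        "tn": report.counts.tn,
                        "fp": report.counts.fp,
                        "fn": report.counts.fn,
                        "skipped_folds": len(res.skipped_folds),
                        "failed_folds": len(res.failed_folds),
                    }
                )
    metrics = pd.DataFrame(metric_rows, columns=METRICS_COLUMNS)
    bundle = ReportBundle(
        config=config,
        scores=scores,
        rules=rules,
        summaries=summaries,
        comparisons=comparisons,
        percent_impaired=pct,
        metrics=metrics,
        curves=curves,
        notes=notes,
        subjects=subjects,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "notes": bundle.notes,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=float))
    if bundle.subjects is not None:
        write_trial_log_csv(bundle.subjects, out / "trial_log.csv")
    bundle.scores.to_csv(out / "scores.csv", index=False)
    rules = {stage: r.to_dict() for stage, r in bundle.rules.items()}
    (out / "rules.json").write_text(json.dumps(rules, indent=2, sort_keys=True))
    for stage in bundle.summaries:
        bundle.summaries[stage].to_csv(out / f"group_summary_{stage}.csv", index=False)
        bundle.comparisons[stage].to_csv(out / f"mann_whitney_{stage}.csv", index=False)
        bundle.percent_impaired[stage].to_csv(out / f"percent_impaired_{stage}.csv", index=False)
    bundle.metrics.to_csv(out / "metrics.csv", index=False)
    (out / "metrics.json").write_text(
        json.dumps(bundle.metrics.to_dict("records"), indent=2, sort_keys=True, default=float)
    )
    for tag, cc in bundle.curves.items():
        for kind in ("roc", "pr"):
            curve = cc[kind]
            pd.DataFrame({"x": curve.x, "y": curve.y}).to_csv(
                out / f"curve_{kind}_{tag}.csv", index=False
            )
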