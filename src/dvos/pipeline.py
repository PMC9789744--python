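"""End-to-end orchestration: simulate -> reconstruct -> featurize -> analyze -> compare.

A run is fully described by a :class:`RunConfig` (one JSON document;
unknown keys are rejected so typos fail loudly).  Every artifact a run
writes carries the SHA-256 hash of its canonical config plus the seed, so
identical configs produce identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, CohortSpec, GroupLevels, generate_cohort
from .features import DEFAULT_SMOOTH_FRAMES
from .modality import (
    DEFAULT_RULES,
    CutoffRule,
    TruthTable,
    build_truth_table,
    load_truth_table,
    score_modalities,
)
from .optics import DEFAULT_BASELINE_WINDOW_S, DEFAULT_DPF, OpticalModelConfig
from .protocol import build_protocol
from .stats import (
    DEFAULT_BONFERRONI_M,
    roc_analysis,
    sample_size,
    spearman_screen,
    welch_test,
)

log = logging.getLogger("dvos")

DIFF_FEATURES = ("PostPreGen", "FU1PreGen", "FU1PostGen",
                 "PostPreLoc", "FU1PreLoc", "FU1PostLoc")


class ConfigError(ValueError):
    pass


def _strict(section: Mapping[str, Any], allowed: set[str], name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {name!r} config: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    seed: int = 0
    cohort: dict[str, Any] = field(default_factory=dict)
    protocol: dict[str, Any] = field(default_factory=dict)
    optics: dict[str, Any] = field(default_factory=dict)
    features: dict[str, Any] = field(default_factory=dict)
    stats: dict[str, Any] = field(default_factory=dict)
    modality_rules: dict[str, Any] = field(default_factory=dict)
    write_recordings: bool = False

    def __post_init__(self) -> None:
        _strict(self.cohort, {f for f in CohortSpec.__dataclass_fields__} - {"seed"},
                "cohort")
        _strict(self.protocol, {"phase_durations_s", "pressures_mmhg", "ramp_s"},
                "protocol")
        _strict(self.optics, {"detector", "dpf", "baseline_window_s"}, "optics")
        _strict(self.features, {"smooth_frames"}, "features")
        _strict(self.stats, {"bonferroni_m", "alpha", "beta"}, "stats")
        _strict(self.modality_rules, {"DVOS", "ABI", "ADUS"}, "modality_rules")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = json.load(fh)
        _strict(doc, set(cls.__dataclass_fields__), "run")
        return cls(**doc)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    # --- materialized components -------------------------------------
    def cohort_spec(self) -> CohortSpec:
        kw = dict(self.cohort)
        for key in ("levels_pos", "levels_neg"):
            if key in kw and isinstance(kw[key], (list, tuple)):
                kw[key] = GroupLevels(*kw[key])
            elif key in kw and isinstance(kw[key], Mapping):
                kw[key] = GroupLevels(**kw[key])
        return CohortSpec(seed=self.seed, **kw)

    def schedule(self):
        return build_protocol(
            self.protocol.get("phase_durations_s"),
            self.protocol.get("pressures_mmhg", (60.0, 100.0)),
            self.protocol.get("ramp_s", 10.0),
        )

    def optical_config(self) -> OpticalModelConfig:
        return OpticalModelConfig(
            detector=self.optics.get("detector", "far"),
            dpf=self.optics.get("dpf", DEFAULT_DPF),
            baseline_window_s=tuple(
                self.optics.get("baseline_window_s", DEFAULT_BASELINE_WINDOW_S)
            ),
        )

    def rules(self) -> dict[str, CutoffRule]:
        rules = dict(DEFAULT_RULES)
        for name, spec in self.modality_rules.items():
            rules[name] = CutoffRule(
                name, float(spec["cutoff"]), spec["predict_negative_when"]
            )
        return rules


def analyze_features(features: pd.DataFrame, config: RunConfig) -> dict[str, Any]:
    """Statistical layer on a patient feature table."""
    m = int(config.stats.get("bonferroni_m", DEFAULT_BONFERRONI_M))
    pos = features.loc[features["outcome"] == 1, "FU1PostGen"].dropna().to_numpy()
    neg = features.loc[features["outcome"] == 0, "FU1PostGen"].dropna().to_numpy()
    tt = welch_test(pos, neg, bonferroni_m=m)
    screen_cols = [c for c in DIFF_FEATURES if c in features.columns]
    screen = spearman_screen(features[screen_cols])
    scores = features["FU1PostGen"].to_numpy(dtype=float)
    labels = features["outcome"].to_numpy(dtype=int)
    roc = roc_analysis(scores, labels, direction="greater")
    cm_preds = roc.predict(scores)
    from .stats import confusion_metrics  # local import keeps module top tidy

    cm = confusion_metrics(cm_preds, labels)
    alpha = float(config.stats.get("alpha", 0.05))
    beta = float(config.stats.get("beta", 0.04))
    return {
        "welch": {
            "t": tt.t, "df": tt.df, "p_raw": tt.p_raw,
            "p_adjusted": tt.p_adjusted, "bonferroni_m": tt.bonferroni_m,
            "group_positive": {"mean": tt.mean_a, "sd": tt.sd_a, "n": tt.n_a},
            "group_negative": {"mean": tt.mean_b, "sd": tt.sd_b, "n": tt.n_b},
        },
        "spearman_flagged": [list(p) for p in screen.flagged_pairs],
        "roc": {
            "auc": roc.auc,
            "cutoff_s": roc.cutoff,
            "direction": "predict negative outcome when FU1PostGen < cutoff",
        },
        "confusion_at_cutoff": {
            "counts": {"TP": cm.tp, "FP": cm.fp, "TN": cm.tn, "FN": cm.fn},
            "rates_pct": cm.as_percentages(),
            "misclassified": cm.misclassified,
        },
        "sample_size": {
            "alpha": alpha, "beta": beta, "effect_sd": 1.0,
            "total_patients": sample_size(alpha, beta, 1.0),
        },
    }


def _report_lines(stats: dict[str, Any], modality: dict[str, Any]) -> list[str]:
    w = stats["welch"]
    lines = [
        "DVOS cuff-occlusion analysis report",
        "",
        f"FU1PostGen Welch t = {w['t']:.2f}, df = {w['df']:.1f}, "
        f"adjusted P = {w['p_adjusted']:.3f} (m = {w['bonferroni_m']})",
        f"  positive group: {w['group_positive']['mean']:.1f} +/- "
        f"{w['group_positive']['sd']:.1f} s (n={w['group_positive']['n']})",
        f"  negative group: {w['group_negative']['mean']:.1f} +/- "
        f"{w['group_negative']['sd']:.1f} s (n={w['group_negative']['n']})",
        f"ROC AUC = {stats['roc']['auc']:.2f}; Youden cutoff = "
        f"{stats['roc']['cutoff_s']:.1f} s ({stats['roc']['direction']})",
        "confusion at cutoff: "
        + ", ".join(f"{k} {v}%" for k, v in stats["confusion_at_cutoff"]["rates_pct"].items()),
        f"suggested follow-up study size: {stats['sample_size']['total_patients']} patients",
        "",
        "modality comparison (available patients):",
    ]
    for col, entry in modality.items():
        rates = ", ".join(f"{k} {v}%" for k, v in entry["rates"].items())
        lines.append(f"  {col:5s} n={entry['n']:2d}  {rates}  "
                     f"misclassified={entry['misclassified']}")
    return lines


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Any]:
    """Run all stages; returns the results bundle and writes it to disk."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    provenance = {"config_hash": chash, "seed": config.seed, "version": __version__}
    log.info("stage simulate: seed=%d hash=%s", config.seed, chash)
    try:
        cohort = generate_cohort(config.cohort_spec(), config.schedule())
        if config.write_recordings:
            cohort.write(out_dir / "recordings")
    except Exception as exc:  # pragma: no cover - defensive stage tagging
        raise RuntimeError(f"[simulate] {exc}") from exc

    log.info("stage reconstruct+featurize: %d patients", len(cohort.patients))
    try:
        features = cohort.realized_features(
            config.optical_config(),
            int(config.features.get("smooth_frames", DEFAULT_SMOOTH_FRAMES)),
        )
    except Exception as exc:
        raise RuntimeError(f"[featurize] {exc}") from exc

    log.info("stage analyze")
    try:
        stats = analyze_features(features, config)
    except Exception as exc:
        raise RuntimeError(f"[analyze] {exc}") from exc

    log.info("stage compare")
    try:
        table = build_truth_table(features, cohort.panel, config.rules())
        modality = score_modalities(table)
    except Exception as exc:
        raise RuntimeError(f"[compare] {exc}") from exc

    bundle = {
        "provenance": provenance,
        "stats": stats,
        "modality": modality,
        "n_patients": len(cohort.patients),
    }
    features.to_csv(out_dir / "features.csv", index=False)
    table.table.to_csv(out_dir / "truth_table.csv", index=False)
    with open(out_dir / "stats.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=_jsonify)
    report = _report_lines(stats, modality)
    (out_dir / "report.txt").write_text(
        "\n".join([f"# config_hash={chash} seed={config.seed}", *report]) + "\n"
    )
    return bundle


def fixture_mode(table_path: str | Path | None, out_dir: str | Path | None = None) -> dict[str, Any]:
    """Score a printed truth table alone, without any simulation."""
    table: TruthTable = load_truth_table(table_path)
    modality = score_modalities(table)
    pos, neg = table.outcome_counts()
    result = {
        "n_patients": len(table.table),
        "n_positive": pos,
        "n_negative": neg,
        "availability": {c: table.availability(c) for c in table.assignment_columns
                         if c in table.table},
        "modality": modality,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "fixture_report.json", "w") as fh:
            json.dump(result, fh, indent=2, default=_jsonify)
        lines = ["truth-table modality comparison", ""]
        for col, entry in modality.items():
            rates = ", ".join(f"{k} {v}%" for k, v in entry["rates"].items())
            lines.append(f"  {col:5s} n={entry['n']:2d}  {rates}  "
                         f"misclassified={entry['misclassified']}")
        (out_dir / "fixture_report.txt").write_text("\n".join(lines) + "\n")
    return result


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
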