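"""End-to-end orchestration: simulate -> space -> embed -> classify ->
evaluate -> regress -> word clouds -> report.

`run_pipeline` produces a JSON-serialisable report bundle shaped like the
study's result tables: overall and per-condition accuracies per feature
family, low/high narrator- and evaluator-alexithymia accuracy splits with
t-tests, confusion matrices and metric panels, scale-regression
predicted-vs-empirical correlations, subgroup mean/SD comparisons, and the
ranked word tables. Runs are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import scales as _scales
from .classification import (
    DEFAULT_GRID,
    DEFAULT_RIDGE,
    EmotionClassifier,
    make_feature_set,
)
from .evaluation import CLASS_ORDER, format_metric, two_sample_t
from .regression import ScaleRegression, subgroup_score_summary
from .representation import embed_table
from .semantic import build_space_from_corpus
from .synthetic import SyntheticConfig, generate_study, records_to_frame
from .wordclouds import paq_phq_cells, top_k, word_coefficients

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "write_report"]

_RS = ("PHQ9", "GAD7", "SWLS", "HILS")


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    k: int = 300
    n_folds: int = 10
    inner_folds: int = 5
    grid: tuple[int, ...] = DEFAULT_GRID
    ridge: float = DEFAULT_RIDGE
    feature_kinds: tuple[str, ...] = ("rs_totals", "rs_items", "words", "words_plus_rs")
    paq_threshold: int | None = _scales.PAQ_SPLIT_DEFAULT  # None -> sample median
    top_k_words: int = 25
    seed: int = 1


def _split_accuracy(results, paq_totals: np.ndarray, threshold: int):
    """Accuracy for low/high PAQ rows plus the pooled t-test p on correctness."""
    labels = _scales.paq_split(paq_totals, threshold)
    low = results.correct_flags(labels == "low")
    high = results.correct_flags(labels == "high")
    out = {
        "low": float(low.mean()) if low.size else None,
        "high": float(high.mean()) if high.size else None,
    }
    if low.size >= 2 and high.size >= 2:
        t = two_sample_t(low, high)
        out["p"] = None if np.isnan(t.p_value) else float(t.p_value)
    else:
        out["p"] = None
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis on freshly generated synthetic data."""
    syn = config.synthetic
    corpus, phase1, phase2 = generate_study(syn)
    records = records_to_frame(phase1, phase2)
    space = build_space_from_corpus(corpus, k=config.k)
    logger.info(
        "corpus: %d responses, %d unique words, %d tokens; space k=%d",
        len(corpus),
        len(corpus.vocabulary),
        corpus.n_tokens,
        space.k,
    )

    threshold = (
        config.paq_threshold
        if config.paq_threshold is not None
        else _scales.median_threshold(
            _scales.score_records(records, ("PAQ",))["PAQ_total"].to_numpy()
        )
    )

    report: dict = {
        "config": {
            "synthetic": syn.to_dict(),
            "k": space.k,
            "n_folds": config.n_folds,
            "inner_folds": config.inner_folds,
            "grid": list(config.grid),
            "ridge": config.ridge,
            "paq_threshold": threshold,
            "seed": config.seed,
        },
        "corpus": {
            "n_responses": len(corpus),
            "n_unique_words": len(corpus.vocabulary),
            "n_tokens": corpus.n_tokens,
        },
        "classification": {},
    }

    results_by_kind = {}
    for kind in config.feature_kinds:
        model = EmotionClassifier.from_dataframe(
            records,
            kind=kind,
            space=space if "words" in kind else None,
            n_folds=config.n_folds,
            grid=config.grid,
            ridge=config.ridge,
            inner_folds=config.inner_folds,
            eval_phase=2,
            seed=config.seed,
        )
        res = model.fit()
        results_by_kind[kind] = res
        rows = res.predictions.index
        narrator_paq = records.loc[rows, "narrator_paq"].to_numpy()
        own_paq = _scales.score_records(records.loc[rows], ("PAQ",))[
            "PAQ_total"
        ].reindex(rows)
        cm = res.confusion
        met = res.metrics
        entry = {
            "overall_accuracy": res.accuracy,
            "per_condition_accuracy": {
                c: float(met.per_class.loc["sensitivity", c]) for c in CLASS_ORDER
            },
            "narrator_paq": _split_accuracy(res, narrator_paq, threshold),
            "evaluator_paq": _split_accuracy(
                res, own_paq.to_numpy(), threshold
            ),
            "confusion": {
                "rows_predicted": list(CLASS_ORDER),
                "columns_true": list(CLASS_ORDER),
                "counts": cm.counts.tolist(),
            },
            "metrics": {
                m: {
                    c: (None if np.isnan(v) else float(v))
                    for c, v in met.per_class.loc[m].items()
                }
                for m in met.per_class.index
            },
            "d_per_fold": res.d_per_fold,
            "mean_d": None if np.isnan(res.mean_dimensions) else res.mean_dimensions,
            "n_scored": cm.total,
        }
        report["classification"][kind] = entry

    # language-based scale estimation + test-retest style correlations
    totals = _scales.score_records(records, _RS + ("PAQ",))
    kept = totals.index
    X, kept_pos, _ = embed_table(
        [records.loc[i, "words"].split(";") for i in kept], space
    )
    kept = kept[kept_pos]
    totals = totals.loc[kept]
    groups = records.loc[kept, "narrative_id"].to_numpy()

    regression_report = {}
    estimates = pd.DataFrame(index=kept)
    for scale in _RS:
        res = ScaleRegression(
            X,
            totals[f"{scale}_total"].to_numpy(float),
            groups,
            scale=scale,
            n_folds=config.n_folds,
            grid=config.grid,
            inner_folds=config.inner_folds,
            seed=config.seed,
        ).fit()
        estimates[scale] = res.oof_predictions
        regression_report[scale] = {
            "r_pred": None if np.isnan(res.r_oof) else res.r_oof,
            "p_pred": None if np.isnan(res.p_oof) else res.p_oof,
            "d_per_fold": res.d_per_fold,
            "d_final": res.predictor.d_selected,
        }
    report["scale_regression"] = regression_report

    # subgroup means/SDs by the respondent's own alexithymia group
    emp = totals[[f"{s}_total" for s in _RS]].rename(
        columns={f"{s}_total": s for s in _RS}
    )
    paq_groups = _scales.paq_split(totals["PAQ_total"].to_numpy(), threshold)
    summary = subgroup_score_summary(emp, estimates, paq_groups)
    report["subgroups"] = {
        scale: {
            col: (None if isinstance(v, float) and np.isnan(v) else
                  bool(v) if isinstance(v, (bool, np.bool_)) else float(v))
            for col, v in row.items()
        }
        for scale, row in summary.iterrows()
    }

    # word clouds: per-emotion (classifier logits) and PAQ x PHQ cells
    if "words" in results_by_kind:
        full = results_by_kind["words"].model.fit_full()
        scores = word_coefficients(space, full)
        report["word_clouds"] = {
            c: top_k(scores[[c, "frequency"]], k=config.top_k_words, target=c)
            .to_dict(orient="list")
            for c in CLASS_ORDER
        }
        report["paq_phq_clouds"] = {
            cell: cloud.to_dict(orient="list")
            for cell, cloud in paq_phq_cells(
                records, space, paq_threshold=threshold, k_words=config.top_k_words
            ).items()
        }
    return report


def write_report(report: dict, out_dir: str | Path) -> tuple[Path, Path]:
    """Serialise the bundle as sorted JSON plus a Markdown digest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(report, indent=1, sort_keys=True))

    lines = ["# QCLA analysis report", ""]
    lines.append("## Correct classification by feature family")
    lines.append("")
    lines.append("| features | overall | narrator PAQ low | high | p | evaluator PAQ low | high | p |")
    lines.append("|---|---|---|---|---|---|---|---|")
    for kind, entry in report.get("classification", {}).items():
        np_, ep_ = entry["narrator_paq"], entry["evaluator_paq"]

        def fmt(v):
            return "–" if v is None else f"{v:.3f}"

        lines.append(
            f"| {kind} | {fmt(entry['overall_accuracy'])} | {fmt(np_['low'])} | "
            f"{fmt(np_['high'])} | {fmt(np_['p'])} | {fmt(ep_['low'])} | "
            f"{fmt(ep_['high'])} | {fmt(ep_['p'])} |"
        )
    lines.append("")
    for kind, entry in report.get("classification", {}).items():
        lines.append(f"## Confusion matrix ({kind}; rows predicted, columns true)")
        lines.append("")
        frame = pd.DataFrame(
            entry["confusion"]["counts"],
            index=entry["confusion"]["rows_predicted"],
            columns=entry["confusion"]["columns_true"],
        )
        lines.append(frame.to_markdown())
        lines.append("")
        panel = pd.DataFrame(entry["metrics"]).T
        lines.append(f"## Metric panel ({kind})")
        lines.append("")
        lines.append(panel.map(lambda v: format_metric(v) if v is not None else "–").to_markdown())
        lines.append("")
    if "scale_regression" in report:
        lines.append("## Language-based scale estimation")
        lines.append("")
        lines.append("| scale | r(pred) | p | final d |")
        lines.append("|---|---|---|---|")
        for scale, entry in report["scale_regression"].items():
            r = entry["r_pred"]
            p = entry["p_pred"]
            lines.append(
                f"| {scale} | {'–' if r is None else f'{r:.3f}'} | "
                f"{'–' if p is None else f'{p:.4g}'} | {entry['d_final']} |"
            )
        lines.append("")
    md_path = out_dir / "report.md"
    md_path.write_text("\n".join(lines))
    return json_path, md_path
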