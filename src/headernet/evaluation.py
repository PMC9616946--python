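"""Confusion-matrix metrics and the balanced / unbalanced test scenarios.

Metrics follow the standard definitions

    sensitivity = TP / (TP + FN)        specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)        accuracy    = (TP + TN) / total
    F1 = 2 * sensitivity * precision / (sensitivity + precision)

with a zero denominator flagged as undefined, never coerced to 0.  Reports
print percentages rounded half-up to one decimal.

"Fivefold cross validation" here means five independent stratified random
49/21/30 re-partitions of the labeled dataset (the reference procedure
re-partitions rather than rotating disjoint folds): each fold freshly
augments its training and validation parts, trains a new network, and
evaluates all methods on the identical untouched test partition.  The
balanced scenario subsamples the test non-headers down to the header
count; the unbalanced scenario uses the full test partition (~1/21 ratio).
Fold-averaged metrics are the mean of per-fold metrics, and pooled metrics
(computed from summed counts) are reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import classifier, prep
from .io_formats import NH, VH, LabeledEvent

METRIC_NAMES = ("sensitivity", "specificity", "precision", "accuracy", "f1")
DEFAULT_METHODS = ("lstm", "thr10", "thr16")


@dataclass
class ConfusionCounts:
    """2x2 tally; fold-averaged counts may be non-integer."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)

    @property
    def positives(self) -> float:
        return self.tp + self.fn

    @property
    def negatives(self) -> float:
        return self.tn + self.fp


@dataclass
class MetricsReport:
    """The five metrics as fractions in [0, 1]; NaN where undefined."""

    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    f1: float
    undefined: frozenset = frozenset()

    def as_fractions(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def as_percent(self) -> dict[str, float]:
        """Percentages rounded half-up to one decimal; NaN stays NaN."""
        return {name: percent(value) for name, value in self.as_fractions().items()}


def percent(fraction: float, digits: int = 1) -> float:
    """Render a fraction as a percentage rounded half-up."""
    if isinstance(fraction, float) and math.isnan(fraction):
        return math.nan
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ScenarioSpec:
    """Which test composition to evaluate and with which methods."""

    scenario: str = "balanced"  # or "unbalanced"
    folds: int = 5
    methods: tuple[str, ...] = DEFAULT_METHODS

    def __post_init__(self) -> None:
        if self.scenario not in ("balanced", "unbalanced"):
            raise ValueError("scenario must be 'balanced' or 'unbalanced'")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        self.methods = tuple(self.methods)


def confusion(predicted: Sequence[str], truth: Sequence[str]) -> ConfusionCounts:
    """Exhaustive 2x2 tally of VH/NH predictions against truth labels."""
    if len(predicted) != len(truth):
        raise ValueError("predicted and true label sequences differ in length")
    tp = fp = tn = fn = 0
    for p, t in zip(predicted, truth):
        if p not in (VH, NH) or t not in (VH, NH):
            raise ValueError(f"labels must be {VH!r}/{NH!r}, got ({p!r}, {t!r})")
        if t == VH:
            tp += p == VH
            fn += p == NH
        else:
            tn += p == NH
            fp += p == VH
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """The five ratio metrics; zero-denominator metrics are flagged undefined."""
    sens = _ratio(counts.tp, counts.tp + counts.fn)
    spec = _ratio(counts.tn, counts.tn + counts.fp)
    prec = _ratio(counts.tp, counts.tp + counts.fp)
    acc = _ratio(counts.tp + counts.tn,
                 counts.tp + counts.fp + counts.tn + counts.fn)
    if math.isnan(sens) or math.isnan(prec) or sens + prec == 0:
        f1 = math.nan
    else:
        f1 = 2.0 * sens * prec / (sens + prec)
    values = dict(sensitivity=sens, specificity=spec, precision=prec,
                  accuracy=acc, f1=f1)
    undefined = frozenset(k for k, v in values.items() if math.isnan(v))
    return MetricsReport(**values, undefined=undefined)


# ---------------------------------------------------------------------------
# Scenario harness
# ---------------------------------------------------------------------------

def _evaluate_methods(methods: Sequence[str], test_events: list[LabeledEvent],
                      model_params: dict,
                      extra_methods: dict[str, Callable] | None) -> dict[str, ConfusionCounts]:
    truth = [le.label for le in test_events]
    out = {}
    for method in methods:
        if method == "lstm":
            X, _ = prep.traces_and_labels(test_events, normalized=True)
            pred_int = classifier.predict(model_params, X)
            pred = [VH if p else NH for p in pred_int]
        elif method.startswith("thr"):
            pred = classifier.threshold_classify(test_events, float(method[3:]))
        elif extra_methods and method in extra_methods:
            pred = extra_methods[method](test_events)
        else:
            raise ValueError(f"unknown evaluation method {method!r}")
        out[method] = confusion(pred, truth)
    return out


def run_scenario(labeled: Sequence[LabeledEvent], spec: ScenarioSpec,
                 net_cfg: "classifier.NetworkConfig | None" = None,
                 train_cfg: "classifier.TrainingConfig | None" = None,
                 split_spec: prep.SplitSpec | None = None,
                 aug_spec: prep.AugmentationSpec | None = None,
                 seed: int = 0,
                 extra_methods: dict[str, Callable] | None = None) -> dict:
    """Run the fold harness; returns per-method counts and averaged metrics.

    Each fold draws a fresh stratified 49/21/30 partition, augments train
    and validation only, trains a new network from a fold-specific seed and
    scores every method on the identical test partition.  The returned dict
    maps method name to ``{"folds": [ConfusionCounts...],
    "mean_metrics": MetricsReport, "pooled_metrics": MetricsReport,
    "mean_counts": ConfusionCounts}``.
    """
    net_cfg = net_cfg or classifier.NetworkConfig()
    train_cfg = train_cfg or classifier.TrainingConfig()
    split_spec = split_spec or prep.SplitSpec()
    aug_spec = aug_spec or prep.AugmentationSpec()
    labels = {le.label for le in labeled}
    if labels != {VH, NH}:
        raise ValueError("scenario needs both VH and NH events")

    needs_model = "lstm" in spec.methods
    results: dict[str, dict] = {m: {"folds": []} for m in spec.methods}
    fold_seeds = np.random.SeedSequence(seed).spawn(spec.folds)
    for fold, ss in enumerate(fold_seeds):
        rng = np.random.default_rng(ss)
        train_set, val_set, test_set = prep.split(labeled, split_spec, rng)
        model_params = None
        if needs_model:
            train_aug = prep.augment_balance(train_set, aug_spec, rng)
            val_aug = prep.augment_balance(val_set, aug_spec, rng)
            fold_train_cfg = classifier.TrainingConfig(
                **{**train_cfg.__dict__, "seed": int(rng.integers(2 ** 31))})
            model_params = classifier.init_model(net_cfg,
                                                 int(rng.integers(2 ** 31)))
            model_params, _ = classifier.train(
                model_params,
                prep.traces_and_labels(train_aug),
                prep.traces_and_labels(val_aug),
                fold_train_cfg)
        if spec.scenario == "balanced":
            vh_events = [le for le in test_set if le.label == VH]
            nh_events = [le for le in test_set if le.label == NH]
            if len(nh_events) > len(vh_events):
                keep = rng.choice(len(nh_events), size=len(vh_events),
                                  replace=False)
                nh_events = [nh_events[i] for i in sorted(keep)]
            test_events = vh_events + nh_events
        else:
            test_events = list(test_set)
        fold_counts = _evaluate_methods(spec.methods, test_events,
                                        model_params, extra_methods)
        for method, counts in fold_counts.items():
            results[method]["folds"].append(counts)

    for method, res in results.items():
        folds = res["folds"]
        per_fold = [metrics(c) for c in folds]
        mean_vals = {
            name: float(np.mean([getattr(m, name) for m in per_fold]))
            for name in METRIC_NAMES
        }
        res["mean_metrics"] = MetricsReport(
            **mean_vals,
            undefined=frozenset(k for k, v in mean_vals.items() if math.isnan(v)))
        pooled = folds[0]
        for c in folds[1:]:
            pooled = pooled + c
        res["pooled_metrics"] = metrics(pooled)
        res["mean_counts"] = ConfusionCounts(
            tp=float(np.mean([c.tp for c in folds])),
            fp=float(np.mean([c.fp for c in folds])),
            tn=float(np.mean([c.tn for c in folds])),
            fn=float(np.mean([c.fn for c in folds])),
        )
    return results


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def _fmt(value: float) -> str:
    return "n/a" if math.isnan(value) else f"{percent(value):.1f}"


def report_table(results: dict) -> pd.DataFrame:
    """One row per metric, one column per method, percentages to one decimal."""
    if not results:
        raise ValueError("no results to report")
    table = {}
    for method, res in results.items():
        table[method] = [_fmt(getattr(res["mean_metrics"], name))
                         for name in METRIC_NAMES]
    return pd.DataFrame(table, index=list(METRIC_NAMES))


def write_report(results: dict, out_dir: str | Path) -> None:
    """Write metrics.csv, per-method confusion_<method>.csv and report.md."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = report_table(results)
    table.to_csv(out_dir / "metrics.csv", index_label="metric")
    for method, res in results.items():
        c = res["mean_counts"]
        pd.DataFrame(
            {"predicted_VH": [c.tp, c.fp], "predicted_NH": [c.fn, c.tn]},
            index=["true_VH", "true_NH"],
        ).to_csv(out_dir / f"confusion_{method}.csv", index_label="")
    lines = ["# Classification report", "",
             "Fold-averaged metrics (%, half-up to one decimal):", "",
             "```", table.to_string(), "```"]
    (out_dir / "report.md").write_text("\n".join(lines) + "\n")
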