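"""Performance metrics for deletion call sets.

"Accuracy" follows the SV-filtering convention of precision: the fraction of
positive calls that match a truth deletion, tp/(tp+fp).  Sensitivity is
recall over the truth set, tp/(tp+fn), with fn counted over truth deletions
matched by no positive call.  The F-score is their harmonic mean,
2*A*S/(A+S).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .labeling import BenchmarkSet, split_indices
from .matching import MatchRule, get_match_rule

#: Reporting precision (decimal places) used in summary tables.
REPORT_DECIMALS = 4

LENGTH_BIN_EDGES = (50, 200, 500, 1000, 10000)


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class Metrics:
    accuracy: float
    sensitivity: float
    f_score: float


def f_score(accuracy: float, sensitivity: float) -> float:
    """2 * accuracy * sensitivity / (accuracy + sensitivity); 0 when both 0."""
    if accuracy + sensitivity == 0:
        return 0.0
    return 2 * accuracy * sensitivity / (accuracy + sensitivity)


def metrics(c: ConfusionCounts) -> Metrics:
    a = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    s = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    return Metrics(accuracy=a, sensitivity=s, f_score=f_score(a, s))


def confusion_from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Candidate-level confusion when truth is expressed as labels."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((y_pred == 1) & (y_true == 1))),
        fp=int(np.sum((y_pred == 1) & (y_true == 0))),
        fn=int(np.sum((y_pred == 0) & (y_true == 1))),
    )


def confusion(calls: Sequence, truth: BenchmarkSet | Sequence,
              match_rule: str | MatchRule = "breakpoint2pct") -> ConfusionCounts:
    """Interval-level confusion between positive calls and a truth set.

    tp: calls matching at least one truth deletion; fp: the rest; fn: truth
    deletions matched by no call.
    """
    rule = get_match_rule(match_rule)
    if not isinstance(truth, BenchmarkSet):
        truth = BenchmarkSet.from_intervals(truth)
    tp = fp = 0
    for c in calls:
        if truth.matches(c.chrom, c.start, c.end, rule):
            tp += 1
        else:
            fp += 1
    fn = sum(
        0 if _any_call_matches(calls, chrom, s, e, rule) else 1
        for chrom, s, e in truth.all_intervals()
    )
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


def _any_call_matches(calls, chrom, start, end, rule) -> bool:
    return any(
        c.chrom == chrom and rule(c.start, c.end, start, end) for c in calls
    )


def evaluate_by_length(calls: Sequence, truth: BenchmarkSet | Sequence,
                       bin_edges: Sequence[int] = LENGTH_BIN_EDGES,
                       match_rule: str | MatchRule = "breakpoint2pct"
                       ) -> pd.DataFrame:
    """Per-length-stratum confusion and accuracy.

    tp/fp are binned by call length, fn by truth-deletion length.  Bins are
    [e0, e1), [e1, e2), ..., [e_last, inf); edges must increase.
    """
    edges = list(bin_edges)
    if sorted(edges) != edges or len(set(edges)) != len(edges):
        raise ValueError("length bin edges must be strictly increasing")
    rule = get_match_rule(match_rule)
    if not isinstance(truth, BenchmarkSet):
        truth = BenchmarkSet.from_intervals(truth)

    def bin_of(length: int) -> int:
        return int(np.searchsorted(edges, length, side="right")) - 1

    n_bins = len(edges)
    tp = np.zeros(n_bins, int)
    fp = np.zeros(n_bins, int)
    fn = np.zeros(n_bins, int)
    for c in calls:
        b = bin_of(c.end - c.start)
        if b < 0:
            continue
        if truth.matches(c.chrom, c.start, c.end, rule):
            tp[b] += 1
        else:
            fp[b] += 1
    for chrom, s, e in truth.all_intervals():
        b = bin_of(e - s)
        if b >= 0 and not _any_call_matches(calls, chrom, s, e, rule):
            fn[b] += 1
    labels = [
        f"{edges[i]}-{edges[i + 1]}" if i + 1 < n_bins else f"{edges[i]}+"
        for i in range(n_bins)
    ]
    acc = [round(metrics(ConfusionCounts(int(t), int(f), int(n))).accuracy,
                 REPORT_DECIMALS)
           for t, f, n in zip(tp, fp, fn)]
    return pd.DataFrame({
        "length_bin": labels, "tp": tp, "fp": fp, "fn": fn, "accuracy": acc,
    })


def cross_validate(X: np.ndarray, y: np.ndarray, rounds: int = 10,
                   seed: int = 0, train_fraction: float = 2 / 3,
                   samples: Sequence[str] | None = None,
                   by_sample: bool = False,
                   architecture=None, train_config=None) -> pd.DataFrame:
    """Repeated random train/test resampling with the default classifier.

    Each round draws an independent split (2:1 by default, or 70/30 whole
    samples with ``by_sample``), normalizes on the training side, trains with
    the default settings, and scores the held-out side.  The last row holds
    the across-round means.
    """
    from .features import Normalizer
    from .labeling import split_train_test
    from .model import TrainConfig, build_model, train_sgd

    if rounds < 1:
        raise ValueError("rounds must be at least 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    base = train_config or TrainConfig()
    rows = []
    for r in range(rounds):
        round_seed = (seed * 65537 + r) % (2**31)
        if by_sample:
            idx = np.arange(len(y))
            tr_idx, te_idx = split_train_test(
                list(idx), train_fraction=train_fraction, seed=round_seed,
                by_sample=True, samples=list(samples))
            tr, te = np.asarray(tr_idx), np.asarray(te_idx)
        else:
            tr, te = split_indices(len(y), train_fraction, seed=round_seed)
        norm = Normalizer().fit(X[tr])
        cfg = TrainConfig(
            learning_rate=base.learning_rate,
            batch_size=min(base.batch_size, max(1, int(len(tr) * (1 - base.validation_fraction)))),
            max_epochs=base.max_epochs,
            early_stop_patience=base.early_stop_patience,
            validation_fraction=base.validation_fraction,
            shuffle_each_epoch=base.shuffle_each_epoch,
            seed=round_seed)
        m = build_model(architecture, seed=round_seed, normalizer=norm)
        m = train_sgd(m, norm.transform(X[tr]), y[tr], cfg)
        _, calls = m.predict(norm.transform(X[te]))
        mm = metrics(confusion_from_labels(y[te], calls))
        rows.append({"round": r, "accuracy": mm.accuracy,
                     "sensitivity": mm.sensitivity, "f_score": mm.f_score})
    df = pd.DataFrame(rows)
    mean_row = {"round": "mean",
                "accuracy": df["accuracy"].mean(),
                "sensitivity": df["sensitivity"].mean(),
                "f_score": df["f_score"].mean()}
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
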