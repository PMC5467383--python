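"""End-to-end pipeline: simulate -> merge -> featurize -> label -> train ->
predict -> evaluate.

:func:`build_synthetic_benchmark` produces the package's standard test bed: a
simulated chromosome with implanted deletions at realistic length strata and
low coverage, an emulated ensemble of caller outputs (true calls with
jittered breakpoints plus decoy calls), merged candidates, their 49-feature
vectors and truth labels.  :func:`run_filter` then trains the convolutional
filter on one side of a split and scores the held-out side, alongside the
unfiltered union for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import candidates as cand_mod
from . import evaluate as ev
from .features import FeatureConfig, Normalizer, extract_feature_matrix
from .labeling import BenchmarkSet, label_candidates, split_indices
from .model import CNNArchitecture, TrainConfig, build_model, train_sgd
from .simulator import SimConfig, simulate, simulate_caller_calls

log = logging.getLogger(__name__)


@dataclass
class SyntheticBenchmark:
    """Everything produced by one synthetic run."""

    config: SimConfig
    outdir: Path
    bam: Path
    truth_vcf: Path
    deletions: list
    candidates: list           # merged candidates
    X: np.ndarray              # raw features, one row per merged candidate
    y: np.ndarray              # labels against the implanted truth
    counts: dict


def build_synthetic_benchmark(
    outdir: str | Path,
    seed: int = 0,
    n_deletions: int = 300,
    n_decoys: int = 300,
    genome_length: int = 1_600_000,
    sim_config: SimConfig | None = None,
    feature_config: FeatureConfig | None = None,
) -> SyntheticBenchmark:
    """Simulate a sample and assemble labeled feature vectors for it."""
    cfg = sim_config or SimConfig(
        genome_length=genome_length, n_deletions=n_deletions, seed=seed)
    sim = simulate(cfg, outdir)
    calls = simulate_caller_calls(sim["deletions"], cfg, n_decoys=n_decoys)
    merged = cand_mod.merge_union(calls)
    log.info("merged %d caller calls into %d candidates", len(calls), len(merged))
    X = extract_feature_matrix(sim["bam"], merged, feature_config)
    benchmark = BenchmarkSet.from_intervals(sim["deletions"])
    y = label_candidates(merged, benchmark)
    return SyntheticBenchmark(
        config=cfg, outdir=Path(outdir), bam=Path(sim["bam"]),
        truth_vcf=Path(sim["truth_vcf"]), deletions=sim["deletions"],
        candidates=merged, X=X, y=y, counts=sim["counts"],
    )


@dataclass
class FilterResult:
    model: object
    train_idx: np.ndarray
    test_idx: np.ndarray
    union_metrics: ev.Metrics    # unfiltered candidate set on the held-out side
    cnn_metrics: ev.Metrics      # CNN-filtered calls on the held-out side
    probabilities: np.ndarray    # per held-out candidate


def run_filter(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    train_fraction: float = 2 / 3,
    architecture: CNNArchitecture | None = None,
    train_config: TrainConfig | None = None,
    threshold: float = 0.5,
) -> FilterResult:
    """Split 2:1, train the CNN filter, and score the held-out candidates.

    The union metrics treat every held-out candidate as a positive call (no
    filtering); the CNN metrics keep only candidates the model scores at or
    above ``threshold``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    tr, te = split_indices(len(y), train_fraction, seed=seed)
    norm = Normalizer().fit(X[tr])
    cfg = train_config or TrainConfig(seed=seed)
    cfg.batch_size = min(cfg.batch_size,
                         max(1, int(len(tr) * (1 - cfg.validation_fraction))))
    model = build_model(architecture, seed=seed, normalizer=norm)
    model = train_sgd(model, norm.transform(X[tr]), y[tr], cfg)
    probs, calls = model.predict(norm.transform(X[te]), threshold=threshold)
    union_m = ev.metrics(ev.confusion_from_labels(y[te], np.ones_like(y[te])))
    cnn_m = ev.metrics(ev.confusion_from_labels(y[te], calls))
    return FilterResult(model=model, train_idx=tr, test_idx=te,
                        union_metrics=union_m, cnn_metrics=cnn_m,
                        probabilities=probs)


def run_pipeline_config(config: dict, outdir: str | Path) -> dict:
    """Drive the whole chain from a plain config mapping (CLI ``run``)."""
    sim_keys = {k: config[k] for k in (
        "genome_length", "n_deletions", "mean_insert", "sd_insert",
        "read_length", "target_depth", "base_error_rate", "zygosity", "seed")
        if k in config}
    seed = int(config.get("seed", 0))
    bench = build_synthetic_benchmark(
        outdir, seed=seed,
        n_deletions=int(config.get("n_deletions", 300)),
        n_decoys=int(config.get("n_decoys", 300)),
        genome_length=int(config.get("genome_length", 1_600_000)),
        sim_config=SimConfig(**sim_keys) if sim_keys else None,
    )
    result = run_filter(bench.X, bench.y, seed=seed,
                        threshold=float(config.get("threshold", 0.5)))
    return {
        "n_candidates": len(bench.candidates),
        "n_true": int(bench.y.sum()),
        "union": vars(result.union_metrics),
        "cnn": vars(result.cnn_metrics),
        "read_counts": bench.counts,
    }
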