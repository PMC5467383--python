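"""Truth labels for candidates, and train/test splitting.

A candidate gets label 1 when a benchmark deletion on the same chromosome
matches it under the chosen rule (by default the same 2%-of-the-shorter-length
breakpoint rule used for de-duplicating caller output; a 50% reciprocal
overlap rule is available), otherwise 0.  One benchmark deletion may validate
several candidates.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .candidates import read_candidates
from .matching import MatchRule, get_match_rule


@dataclass
class BenchmarkSet:
    """Benchmark deletions indexed per chromosome, start-sorted."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, items: Sequence) -> "BenchmarkSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for it in items:
            if it.end <= it.start:
                raise ValueError(f"invalid benchmark interval {it}")
            by_chrom.setdefault(it.chrom, []).append((it.start, it.end))
        return cls({c: sorted(v) for c, v in by_chrom.items()})

    @classmethod
    def from_file(cls, path: str | Path) -> "BenchmarkSet":
        return cls.from_intervals(read_candidates(path, source="benchmark"))

    def __len__(self) -> int:
        return sum(len(v) for v in self.intervals.values())

    def all_intervals(self) -> list[tuple[str, int, int]]:
        return [(c, s, e) for c, ivs in sorted(self.intervals.items())
                for s, e in ivs]

    def matches(self, chrom: str, start: int, end: int,
                rule: MatchRule) -> bool:
        """True when some benchmark deletion matches the query interval."""
        ivs = self.intervals.get(chrom)
        if not ivs:
            return False
        length = end - start
        # under either rule a matching benchmark deletion is at most twice
        # the query length, so its start lies within 2x the query length.
        lo = bisect.bisect_left(ivs, (int(start - 2 * length) - 1, -1))
        for s, e in ivs[lo:]:
            if s > end:
                break
            if rule(start, end, s, e):
                return True
        return False


@dataclass
class LabeledExample:
    candidate_id: str
    features: np.ndarray
    label: int
    sample: str = "sample"

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


def label_candidates(candidates: Sequence, benchmark: BenchmarkSet,
                     match_rule: str | MatchRule = "breakpoint2pct") -> np.ndarray:
    """Binary labels per candidate: 1 iff a benchmark deletion matches."""
    rule = get_match_rule(match_rule)
    return np.array(
        [int(benchmark.matches(c.chrom, c.start, c.end, rule)) for c in candidates],
        dtype=int,
    )


def split_train_test(
    examples: Sequence,
    train_fraction: float = 2 / 3,
    seed: int = 0,
    by_sample: bool = False,
    samples: Sequence[str] | None = None,
) -> tuple[list, list]:
    """Random train/test split; default 2:1 train:test.

    With ``by_sample`` whole individuals land on one side, emulating
    cross-validation over per-individual call files; ``samples`` supplies the
    per-example sample ids (defaults to each example's ``sample`` attribute).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = len(examples)
    if n < 2:
        raise ValueError("need at least two examples to split")
    rng = np.random.default_rng(seed)
    if by_sample:
        if samples is None:
            samples = [getattr(e, "sample", "sample") for e in examples]
        uniq = sorted(set(samples))
        order = [uniq[i] for i in rng.permutation(len(uniq))]
        n_train_samples = round(train_fraction * len(uniq))
        train_samples = set(order[:n_train_samples])
        train = [e for e, s in zip(examples, samples) if s in train_samples]
        test = [e for e, s in zip(examples, samples) if s not in train_samples]
    else:
        idx = rng.permutation(n)
        n_train = round(train_fraction * n)
        train = [examples[i] for i in idx[:n_train]]
        test = [examples[i] for i in idx[n_train:]]
    return train, test


def split_indices(n: int, train_fraction: float = 2 / 3, seed: int = 0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Index variant of :func:`split_train_test` for array-shaped data."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    if n < 2:
        raise ValueError("need at least two examples to split")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    n_train = round(train_fraction * n)
    return idx[:n_train], idx[n_train:]
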