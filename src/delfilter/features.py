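"""Alignment-derived features for candidate deletions.

Every candidate is described by 49 numbers read off the BAM around its
breakpoints, grouped into five families:

==========  =====  ==================================================
indices     count  family
==========  =====  ==================================================
0           1      deletion length
1-8         8      spanning read pairs: (discordant | concordant) x
                   (error-free | with mismatches) x (unique | multi)
9-32        24     breakpoint reads: (fully mapped | soft-clip |
                   one-end-anchored) x (left | right breakpoint) x
                   (anchor upstream | downstream) x (unique | multi)
33-36       4      mean pileup depth in the region, the upstream
                   flank, the downstream flank, and the region/flank
                   depth ratio
37-48       12     mapped-read counts in (region | upstream flank |
                   downstream flank) x (error-free | with mismatches)
                   x (unique | multi)
==========  =====  ==================================================

A pair is discordant when its reference-implied insert is more than three
standard deviations from the library mean or its orientation is not
forward-reverse; a read is "multi" when MAPQ < 20 or it carries an
alternative-hit tag; "with mismatches" means NM > 0.  Before training, all
features are min-max scaled to [0, 1] with statistics fitted on the training
set; unseen values are clipped into the interval.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

N_FEATURES = 49
FAMILY_SIZES = (1, 8, 24, 4, 12)

PAIR_OFFSET = 1
SPLIT_OFFSET = 9
DEPTH_OFFSET = 33
STAT_OFFSET = 37

SPLIT_SORTS = ("fully_mapped", "soft_clip", "one_end_anchored")


def feature_names() -> list[str]:
    names = ["deletion_length"]
    for conc in ("discordant", "concordant"):
        for err in ("errfree", "mismatch"):
            for uq in ("unique", "multi"):
                names.append(f"pair_{conc}_{err}_{uq}")
    for sort in SPLIT_SORTS:
        for side in ("left", "right"):
            for anch in ("upstream", "downstream"):
                for uq in ("unique", "multi"):
                    names.append(f"split_{sort}_{side}_{anch}_{uq}")
    names += ["depth_region", "depth_upstream", "depth_downstream", "depth_ratio"]
    for region in ("region", "upstream", "downstream"):
        for err in ("errfree", "mismatch"):
            for uq in ("unique", "multi"):
                names.append(f"count_{region}_{err}_{uq}")
    assert len(names) == N_FEATURES
    return names


FEATURE_NAMES = feature_names()


@dataclass(frozen=True)
class AlignmentRecordView:
    """The per-read facts the extractor needs, decoupled from pysam."""

    ref_start: int
    ref_end: int
    cigar: tuple[tuple[int, int], ...]  # pysam op codes; 0=M, 4=S
    is_mapped: bool
    mate_mapped: bool
    mate_ref_start: int
    template_length: int
    n_mismatches: int
    mapq: int
    has_alt_hits: bool
    is_reverse: bool = False

    @classmethod
    def from_pysam(cls, r: pysam.AlignedSegment) -> "AlignmentRecordView":
        mapped = not r.is_unmapped
        return cls(
            ref_start=r.reference_start if mapped else (r.reference_start or 0),
            ref_end=r.reference_end if mapped else (r.reference_start or 0),
            cigar=tuple(r.cigartuples or ()),
            is_mapped=mapped,
            mate_mapped=r.is_paired and not r.mate_is_unmapped,
            mate_ref_start=r.next_reference_start,
            template_length=r.template_length,
            n_mismatches=int(r.get_tag("NM")) if r.has_tag("NM") else 0,
            mapq=r.mapping_quality,
            has_alt_hits=r.has_tag("XA") or r.has_tag("SA"),
            is_reverse=r.is_reverse,
        )

    @property
    def is_multi(self) -> bool:
        return self.mapq < 20 or self.has_alt_hits

    @property
    def has_mismatch(self) -> bool:
        return self.n_mismatches > 0


@dataclass(frozen=True)
class PairClass:
    concordance: str  # discordant | concordant
    error: str        # error_free | with_mismatch
    uniqueness: str   # unique | multi

    @property
    def index(self) -> int:
        i = (0 if self.concordance == "discordant" else 1)
        j = (0 if self.error == "error_free" else 1)
        k = (0 if self.uniqueness == "unique" else 1)
        return PAIR_OFFSET + 4 * i + 2 * j + k


@dataclass(frozen=True)
class SplitClass:
    sort: str             # fully_mapped | soft_clip | one_end_anchored
    breakpoint_side: str  # left | right
    anchor_side: str      # upstream | downstream
    uniqueness: str       # unique | multi

    @property
    def index(self) -> int:
        i = SPLIT_SORTS.index(self.sort)
        j = (0 if self.breakpoint_side == "left" else 1)
        k = (0 if self.anchor_side == "upstream" else 1)
        m = (0 if self.uniqueness == "unique" else 1)
        return SPLIT_OFFSET + 8 * i + 4 * j + 2 * k + m


@dataclass
class FeatureConfig:
    """Extraction parameters.

    ``insert_mean``/``insert_sd`` default to None, meaning "estimate from the
    BAM" (a sample of up to ``insert_sample_size`` well-formed pairs).
    """

    flank: int = 500
    breakpoint_tolerance: int = 10
    mapq_min: int = 20
    insert_mean: float | None = None
    insert_sd: float | None = None
    insert_sample_size: int = 10_000


def estimate_insert_model(bam: pysam.AlignmentFile,
                          sample_size: int = 10_000) -> tuple[float, float]:
    """Mean and SD of the outer insert over a sample of forward-reverse,
    both-mapped pairs."""
    tlens = []
    for r in bam.fetch(until_eof=True):
        if (r.is_unmapped or r.mate_is_unmapped or r.is_secondary
                or r.is_supplementary or not r.is_paired):
            continue
        if r.template_length <= 0 or r.is_reverse or not r.mate_is_reverse:
            continue
        tlens.append(r.template_length)
        if len(tlens) >= sample_size:
            break
    if len(tlens) < 2:
        raise ValueError("not enough proper pairs to estimate the insert model")
    arr = np.asarray(tlens, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1))


def classify_pair(r1: AlignmentRecordView, r2: AlignmentRecordView,
                  insert_model: tuple[float, float],
                  candidate=None) -> PairClass | None:
    """Classify a both-mapped pair; None if it does not span the candidate.

    The pair spans the candidate when its outer fragment interval contains
    both breakpoints.  With ``candidate=None`` the span requirement is waived.
    """
    if not (r1.is_mapped and r2.is_mapped):
        return None
    outer_start = min(r1.ref_start, r2.ref_start)
    outer_end = max(r1.ref_end, r2.ref_end)
    if candidate is not None:
        if not (outer_start < candidate.start and outer_end > candidate.end):
            return None
    mean, sd = insert_model
    insert = outer_end - outer_start
    left, right = (r1, r2) if r1.ref_start <= r2.ref_start else (r2, r1)
    fr = (not left.is_reverse) and right.is_reverse
    discordant = abs(insert - mean) > 3 * sd or not fr
    return PairClass(
        concordance="discordant" if discordant else "concordant",
        error="with_mismatch" if (r1.has_mismatch or r2.has_mismatch) else "error_free",
        uniqueness="multi" if (r1.is_multi or r2.is_multi) else "unique",
    )


def _clip_boundaries(r: AlignmentRecordView) -> list[int]:
    """Reference coordinates of soft-clip boundaries (leading clip -> at
    ref_start, trailing clip -> at ref_end)."""
    if not r.cigar:
        return []
    out = []
    if r.cigar[0][0] == 4:
        out.append(r.ref_start)
    if r.cigar[-1][0] == 4:
        out.append(r.ref_end)
    return out


def classify_split_read(r: AlignmentRecordView,
                        mate: AlignmentRecordView | None,
                        candidate,
                        insert_model: tuple[float, float],
                        breakpoint_tolerance: int = 10) -> SplitClass | None:
    """Classify one read against the candidate's breakpoints.

    Soft-clip: a clip boundary within +-tolerance of a breakpoint (the
    matched segment is the anchor).  One-end-anchored: the read is unmapped
    and its mapped mate lies within one mean insert of a breakpoint (the mate
    is the anchor).  Fully mapped: an unclipped alignment spanning a
    breakpoint.  ``anchor_side`` is upstream when the anchoring alignment's
    midpoint falls before the implicated breakpoint.
    """
    bps = (("left", candidate.start), ("right", candidate.end))
    mean_insert = insert_model[0]

    if r.is_mapped:
        boundaries = _clip_boundaries(r)
        best = None
        for b in boundaries:
            for side, bp in bps:
                d = abs(b - bp)
                if d <= breakpoint_tolerance and (best is None or d < best[0]):
                    best = (d, side, bp)
        if best is not None:
            _, side, bp = best
            mid = (r.ref_start + r.ref_end) / 2
            return SplitClass("soft_clip", side, "upstream" if mid < bp else "downstream",
                              "multi" if r.is_multi else "unique")
        if not boundaries:
            spanned = [(side, bp) for side, bp in bps
                       if r.ref_start < bp < r.ref_end]
            if spanned:
                mid = (r.ref_start + r.ref_end) / 2
                side, bp = min(spanned, key=lambda t: abs(t[1] - mid))
                return SplitClass("fully_mapped", side,
                                  "upstream" if mid < bp else "downstream",
                                  "multi" if r.is_multi else "unique")
        return None

    # unmapped read: one-end-anchored if the mapped mate anchors near a breakpoint
    if mate is None or not mate.is_mapped:
        return None
    mid = (mate.ref_start + mate.ref_end) / 2
    best = None
    for side, bp in bps:
        d = min(abs(mate.ref_start - bp), abs(mate.ref_end - bp))
        if d <= mean_insert and (best is None or d < best[0]):
            best = (d, side, bp)
    if best is None:
        return None
    _, side, bp = best
    return SplitClass("one_end_anchored", side,
                      "upstream" if mid < bp else "downstream",
                      "multi" if mate.is_multi else "unique")


def mean_depth(bam: pysam.AlignmentFile, chrom: str, start: int, end: int) -> float:
    """Mean per-base pileup depth over [start, end): sum(depth_i) / l."""
    if end <= start:
        raise ValueError("end must exceed start")
    contig_len = bam.get_reference_length(chrom)
    t_start, t_end = max(0, start), min(end, contig_len)
    if t_end <= t_start:
        raise ValueError(f"region {chrom}:{start}-{end} outside the contig")
    if (t_start, t_end) != (start, end):
        log.warning("region %s:%d-%d truncated to contig bounds", chrom, start, end)
    cov = bam.count_coverage(chrom, t_start, t_end, quality_threshold=0)
    total = int(np.asarray(cov).sum())
    return total / (t_end - t_start)


def _fetch_views(bam: pysam.AlignmentFile, chrom: str, start: int, end: int
                 ) -> dict[tuple[str, bool], AlignmentRecordView]:
    """Primary records overlapping the window, keyed by (name, is_read2)."""
    contig_len = bam.get_reference_length(chrom)
    out: dict[tuple[str, bool], AlignmentRecordView] = {}
    for r in bam.fetch(chrom, max(0, start), min(end, contig_len)):
        if r.is_secondary or r.is_supplementary:
            continue
        out[(r.query_name, r.is_read2)] = AlignmentRecordView.from_pysam(r)
    return out


def extract_features(bam: pysam.AlignmentFile, candidate,
                     config: FeatureConfig | None = None) -> np.ndarray:
    """The raw 49-feature vector for one candidate deletion.

    ``candidate`` needs ``chrom``/``start``/``end`` attributes.  Deterministic
    for a fixed BAM.
    """
    if config is None:
        config = FeatureConfig()
    if config.insert_mean is None or config.insert_sd is None:
        mean, sd = estimate_insert_model(bam, config.insert_sample_size)
        config.insert_mean = config.insert_mean or mean
        config.insert_sd = config.insert_sd or sd
    insert_model = (config.insert_mean, config.insert_sd)

    chrom, start, end = candidate.chrom, candidate.start, candidate.end
    if chrom not in bam.references:
        raise ValueError(f"contig {chrom!r} absent from the BAM header")
    contig_len = bam.get_reference_length(chrom)

    v = np.zeros(N_FEATURES)
    v[0] = end - start

    pad = int(insert_model[0] + 3 * insert_model[1] + 100)
    views = _fetch_views(bam, chrom, start - pad, end + pad)

    # --- spanning pair consistency (1-8)
    seen = set()
    for (name, is_read2), r in views.items():
        if name in seen:
            continue
        mate = views.get((name, not is_read2))
        if mate is None:
            continue
        seen.add(name)
        pc = classify_pair(r, mate, insert_model, candidate)
        if pc is not None:
            v[pc.index] += 1

    # --- breakpoint reads (9-32)
    tol = config.breakpoint_tolerance
    for (name, is_read2), r in views.items():
        mate = views.get((name, not is_read2))
        sc = classify_split_read(r, mate, candidate, insert_model, tol)
        if sc is not None:
            v[sc.index] += 1

    # --- read depth (33-36)
    up_start, up_end = start - config.flank, start
    dn_start, dn_end = end, end + config.flank
    d_region = mean_depth(bam, chrom, start, end)
    d_up = mean_depth(bam, chrom, up_start, up_end) if up_end > 0 else 0.0
    d_dn = (mean_depth(bam, chrom, dn_start, dn_end)
            if dn_start < contig_len else 0.0)
    flank_mean = (d_up + d_dn) / 2
    v[DEPTH_OFFSET:DEPTH_OFFSET + 4] = [
        d_region, d_up, d_dn,
        d_region / flank_mean if flank_mean > 0 else 0.0,
    ]

    # --- mapping read statistics (37-48)
    regions = ((start, end), (up_start, up_end), (dn_start, dn_end))
    for (name, is_read2), r in views.items():
        if not r.is_mapped:
            continue
        j = 0 if not r.has_mismatch else 1
        k = 0 if not r.is_multi else 1
        for ri, (rs, re) in enumerate(regions):
            if r.ref_start < re and r.ref_end > rs:
                v[STAT_OFFSET + 4 * ri + 2 * j + k] += 1
    return v


def extract_feature_matrix(bam_path: str | Path, candidates: Sequence,
                           config: FeatureConfig | None = None) -> np.ndarray:
    """Feature vectors for many candidates, sharing one insert-model fit."""
    if config is None:
        config = FeatureConfig()
    with pysam.AlignmentFile(str(bam_path)) as bam:
        if config.insert_mean is None or config.insert_sd is None:
            mean, sd = estimate_insert_model(bam, config.insert_sample_size)
            config.insert_mean = config.insert_mean or mean
            config.insert_sd = config.insert_sd or sd
        return np.vstack([extract_features(bam, c, config) for c in candidates])


class Normalizer:
    """Per-feature min-max scaler onto [0, 1].

    Constant features map to 0; transforming unseen values clips into [0, 1].
    """

    def __init__(self) -> None:
        self.min_: np.ndarray | None = None
        self.max_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.min_ is not None

    def fit(self, X: np.ndarray) -> "Normalizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("need a non-empty 2-D training matrix")
        self.min_ = X.min(axis=0)
        self.max_ = X.max(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("Normalizer used before fit()")
        X = np.asarray(X, dtype=float)
        span = self.max_ - self.min_
        safe = np.where(span > 0, span, 1.0)
        out = (X - self.min_) / safe
        out = np.where(span > 0, out, 0.0)
        return np.clip(out, 0.0, 1.0)

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def to_dict(self) -> dict:
        return {"min": self.min_.tolist(), "max": self.max_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        n = cls()
        n.min_ = np.asarray(d["min"], dtype=float)
        n.max_ = np.asarray(d["max"], dtype=float)
        return n

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "Normalizer":
        return cls.from_dict(json.loads(Path(path).read_text()))


def write_feature_table(path: str | Path, candidates: Sequence,
                        X: np.ndarray) -> None:
    df = pd.DataFrame(X, columns=FEATURE_NAMES)
    df.insert(0, "end", [c.end for c in candidates])
    df.insert(0, "start", [c.start for c in candidates])
    df.insert(0, "chrom", [c.chrom for c in candidates])
    df.insert(0, "id", [f"cand{i:06d}" for i in range(len(candidates))])
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
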