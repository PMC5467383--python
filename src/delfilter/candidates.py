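"""Candidate deletion ingestion and ensemble merging.

Deletion calls produced by several SV callers (converted to VCF or BED) are
read into a common 0-based half-open representation, then collapsed into a
union call set: calls whose breakpoints agree to within 2% of the shorter
deletion's length are treated as duplicates of one another, duplicate groups
are closed transitively, and each group is reported once.  When a group mixes
callers, the reported bounds are taken from a split-read caller if one
supports the group, because split-read breakpoints are base-accurate while
discordant-pair breakpoints are interpolated from insert sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pysam

from .matching import breakpoint_match

log = logging.getLogger(__name__)

MIN_DELETION_LENGTH = 50

METHOD_CLASSES = ("split_read", "discordant_pair", "other")

#: Callers whose breakpoints win ties when merged bounds disagree, in
#: priority order.  Configurable via ``merge_union(source_order=...)``.
DEFAULT_SOURCE_ORDER = ("pindel", "svseq2", "breakdancer", "delly")


@dataclass(frozen=True)
class CandidateDeletion:
    """One putative deletion from one caller, 0-based half-open."""

    chrom: str
    start: int
    end: int
    source: str = "unknown"
    method_class: str = "other"
    sample: str = "sample"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.method_class not in METHOD_CLASSES:
            raise ValueError(f"method_class must be one of {METHOD_CLASSES}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MergedCandidate:
    """A duplicate group collapsed to a single interval.

    ``chrom``/``start``/``end`` are copied verbatim from ``chosen_bound_source``'s
    call; all member calls are retained in ``supporters``.
    """

    chrom: str
    start: int
    end: int
    supporters: list[CandidateDeletion] = field(default_factory=list)
    chosen_bound_source: str = ""
    sample: str = "sample"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def sources(self) -> list[str]:
        return sorted({c.source for c in self.supporters})


def are_duplicates(a: CandidateDeletion, b: CandidateDeletion) -> bool:
    """Duplicate test: both breakpoint offsets under 2% of the shorter length.

    Calls on different chromosomes or samples are never duplicates.
    """
    if a.chrom != b.chrom or a.sample != b.sample:
        return False
    return breakpoint_match(a.start, a.end, b.start, b.end)


def read_candidates(
    path: str | Path,
    source: str = "unknown",
    method_class: str = "other",
    sample: str = "sample",
    min_length: int = MIN_DELETION_LENGTH,
) -> list[CandidateDeletion]:
    """Read deletion calls from a VCF (SVTYPE=DEL) or a BED file.

    Coordinates are normalised to 0-based half-open.  VCF deletion ends come
    from INFO/END when present, else from \\|SVLEN\\|; records with neither are
    skipped with a warning.  Calls shorter than ``min_length`` bases are
    dropped (the count is logged).
    """
    path = Path(path)
    if ".vcf" in path.suffixes or path.suffix in (".vcf", ".gz", ".bcf"):
        raw = _read_vcf(path)
    elif path.suffix == ".bed":
        raw = _read_bed(path)
    else:
        # sniff: VCF files start with ##fileformat
        with open(path) as fh:
            first = fh.readline()
        raw = _read_vcf(path) if first.startswith("##") else _read_bed(path)

    out: list[CandidateDeletion] = []
    n_short = 0
    for chrom, start, end in raw:
        if end - start < min_length:
            n_short += 1
            continue
        out.append(
            CandidateDeletion(chrom, start, end, source=source,
                              method_class=method_class, sample=sample)
        )
    if n_short:
        log.info("%s: dropped %d records shorter than %d bp", path, n_short, min_length)
    out.sort(key=lambda c: (c.chrom, c.start, c.end))
    return out


def _read_vcf(path: Path) -> list[tuple[str, int, int]]:
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf.fetch() if vcf.index is not None else vcf):
            svtype = rec.info.get("SVTYPE")
            alts = rec.alts or ()
            if svtype != "DEL" and "<DEL>" not in alts:
                continue
            start = rec.start  # pysam: 0-based POS
            end = None
            # explicit END wins; else derive the end from SVLEN (END = POS +
            # |SVLEN| in 1-based terms); rec.stop alone is a last resort since
            # htslib back-computes it from SVLEN with symbolic-allele padding
            if "END" in rec.info:
                end = rec.stop
            elif "SVLEN" in rec.info:
                svlen = rec.info["SVLEN"]
                if isinstance(svlen, (tuple, list)):
                    svlen = svlen[0]
                end = start + abs(int(svlen))
            elif rec.stop > start + 1:
                end = rec.stop
            if end is None or end <= start:
                log.warning("%s record %d: no usable END or SVLEN; skipped", path, i + 1)
                continue
            out.append((rec.chrom, start, end))
    return out


def _read_bed(path: Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path} line {lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path} line {lineno}: non-integer BED coordinates"
                ) from None
            out.append((fields[0], start, end))
    return out


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_union(
    candidates: Sequence[CandidateDeletion],
    source_order: Sequence[str] = DEFAULT_SOURCE_ORDER,
) -> list[MergedCandidate]:
    """Collapse duplicate calls into a union call set.

    Clustering is single linkage under :func:`are_duplicates` (duplicates of
    duplicates join the same group), so the result does not depend on input
    order.  Each group's bounds are copied from one supporter: a split-read
    caller when the group has one, preferring earlier entries of
    ``source_order``; otherwise the first supporter in that order.
    """
    cands = sorted(candidates, key=lambda c: (c.sample, c.chrom, c.start, c.end))
    n = len(cands)
    uf = _UnionFind(n)
    # sweep: a pair can only be duplicates if their starts differ by less
    # than 2% of either length, so comparisons stay within a short window
    # of the start-sorted list.
    for i in range(n):
        a = cands[i]
        reach = a.start + breakpoint_window(a)
        for j in range(i + 1, n):
            b = cands[j]
            if (b.sample, b.chrom) != (a.sample, a.chrom) or b.start >= reach:
                break
            if are_duplicates(a, b):
                uf.union(i, j)

    groups: dict[int, list[CandidateDeletion]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(cands[i])

    rank = {s: r for r, s in enumerate(source_order)}

    def priority(c: CandidateDeletion) -> tuple:
        return (
            0 if c.method_class == "split_read" else 1,
            rank.get(c.source, len(rank)),
            c.source,
            c.start,
            c.end,
        )

    merged = []
    for members in groups.values():
        best = min(members, key=priority)
        merged.append(
            MergedCandidate(
                chrom=best.chrom,
                start=best.start,
                end=best.end,
                supporters=members,
                chosen_bound_source=best.source,
                sample=best.sample,
            )
        )
    merged.sort(key=lambda m: (m.sample, m.chrom, m.start, m.end))
    return merged


def breakpoint_window(c: CandidateDeletion, fraction: float = 0.02) -> float:
    """Upper bound on the start-offset of any duplicate of ``c``."""
    return fraction * c.length


def write_merged_vcf(path: str | Path, merged: Sequence[MergedCandidate],
                     contigs: dict[str, int] | None = None) -> None:
    """Write a merged call set as VCF with SUPP/SOURCES INFO keys."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="Deletion end">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Deletion length">')
    header.add_line('##INFO=<ID=SUPP,Number=1,Type=Integer,Description="Supporting calls">')
    header.add_line('##INFO=<ID=SOURCES,Number=.,Type=String,Description="Supporting callers">')
    header.add_line('##ALT=<ID=DEL,Description="Deletion">')
    if contigs is None:
        contigs = {}
        for m in merged:
            contigs[m.chrom] = max(contigs.get(m.chrom, 0), m.end + 1)
    for chrom, length in contigs.items():
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for m in sorted(merged, key=lambda m: (m.chrom, m.start)):
            rec = vcf.new_record(
                contig=m.chrom, start=m.start, stop=m.end,
                alleles=("N", "<DEL>"),
            )
            rec.info["SVTYPE"] = "DEL"
            rec.info["SVLEN"] = -(m.end - m.start)
            rec.info["SUPP"] = len(m.supporters)
            rec.info["SOURCES"] = ",".join(m.sources)
            vcf.write(rec)


def write_merged_tsv(path: str | Path, merged: Sequence[MergedCandidate]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tlength\tsupporters\tsources\tbound_source\tsample\n")
        for m in merged:
            fh.write(
                f"{m.chrom}\t{m.start}\t{m.end}\t{m.length}\t{len(m.supporters)}\t"
                f"{','.join(m.sources)}\t{m.chosen_bound_source}\t{m.sample}\n"
            )
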