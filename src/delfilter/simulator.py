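"""Paired-end read simulator with implanted deletions.

The simulator stands in for real data and for the aligner: it generates a
random reference, removes deletion spans from donor haplotypes, draws
fragments on the donor with a Normal insert-size model, and emits
coordinate-sorted, indexed BAM records whose alignments are computed by exact
coordinate lift-over back to the reference.  Because the lift-over is exact,
pairs that straddle a deletion come out discordant (their reference-implied
insert is inflated by the deletion length), reads crossing a breakpoint come
out soft-clipped when their anchored segment is long enough and unmapped
(one-end-anchored pairs) otherwise, and the truth set is known to the base.

Defaults mirror a low-coverage human short-read library: 425 bp mean insert,
79 bp reads, 10.6x depth.  Deletion lengths are drawn by default from five
strata between 50 bp and 20 kb weighted towards the 200-500 bp and 1-10 kb
ranges seen in population call sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .candidates import CandidateDeletion
from .matching import breakpoint_match, reciprocal_overlap_match

log = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype="S1")

#: (length range, weight) strata for deletion lengths.  Weights follow the
#: length distribution of deletions >=50 bp in low-coverage population call
#: sets: short and medium deletions dominate, with a tail of CNV-scale events
#: (capped at 20 kb so a simulated chromosome stays small).
DELETION_LENGTH_STRATA: tuple[tuple[tuple[int, int], float], ...] = (
    ((50, 200), 147.0),
    ((200, 500), 275.0),
    ((500, 1000), 65.0),
    ((1000, 10000), 172.0),
    ((10000, 20000), 24.0),
)


class ConfigurationError(ValueError):
    """Raised when a simulation request cannot be satisfied."""


@dataclass
class SimConfig:
    """Parameters of one simulation.

    All randomness (reference bases, deletion placement, fragments, errors,
    repeat placement) derives from ``seed``.
    """

    genome_length: int = 1_600_000
    n_deletions: int = 300
    deletion_length_range: tuple[int, int] | None = None  # None -> strata
    mean_insert: float = 425.0
    sd_insert: float = 57.0  # +-3 sd spans roughly the 237-579 bp library range
    read_length: int = 79
    target_depth: float = 10.6
    base_error_rate: float = 0.001
    zygosity: str = "homozygous"  # homozygous | heterozygous | mixed
    repeat_fraction: float = 0.02  # genome fraction flagged multi-mapping
    min_anchor: int = 15  # shortest matched segment an aligner would keep
    chrom: str = "chrS"
    seed: int = 0

    def validate(self) -> None:
        if self.mean_insert <= 2 * self.read_length:
            raise ConfigurationError("mean_insert must exceed twice the read length")
        if self.target_depth <= 0:
            raise ConfigurationError("target_depth must be positive")
        if self.genome_length < 10 * self.mean_insert:
            raise ConfigurationError("genome_length below 10 mean inserts")
        if self.deletion_length_range is not None:
            lo, hi = self.deletion_length_range
            if lo < 50 or hi < lo:
                raise ConfigurationError("deletion lengths must be >=50 and ordered")
        if self.zygosity not in ("homozygous", "heterozygous", "mixed"):
            raise ConfigurationError(f"bad zygosity {self.zygosity!r}")

    def rngs(self) -> dict[str, np.random.Generator]:
        names = ("reference", "deletions", "fragments", "errors", "repeats", "callers")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass(frozen=True)
class ImplantedDeletion:
    """A truth deletion, 0-based half-open on the reference."""

    chrom: str
    start: int
    end: int
    zygosity: str = "homozygous"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Haplotype:
    """One donor haplotype: the reference minus its deletion spans."""

    deletions: list[ImplantedDeletion]
    # donor coordinates where a deletion was excised, ascending
    breakpoints: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    # cumulative deleted bases before each segment (len = len(deletions)+1)
    offsets: np.ndarray = field(default_factory=lambda: np.zeros(1, int))
    length: int = 0

    @classmethod
    def build(cls, deletions: Sequence[ImplantedDeletion], ref_length: int) -> "Haplotype":
        dels = sorted(deletions, key=lambda d: d.start)
        bps, offs, cum = [], [0], 0
        for d in dels:
            bps.append(d.start - cum)
            cum += d.length
            offs.append(cum)
        return cls(
            deletions=dels,
            breakpoints=np.asarray(bps, dtype=int),
            offsets=np.asarray(offs, dtype=int),
            length=ref_length - cum,
        )

    def to_reference(self, donor_pos: int) -> int:
        seg = int(np.searchsorted(self.breakpoints, donor_pos, side="right"))
        return donor_pos + int(self.offsets[seg])

    def segment_index(self, donor_pos: int) -> int:
        return int(np.searchsorted(self.breakpoints, donor_pos, side="right"))

    def sequence(self, reference: str) -> str:
        parts, prev = [], 0
        for d in self.deletions:
            parts.append(reference[prev:d.start])
            prev = d.end
        parts.append(reference[prev:])
        return "".join(parts)


def generate_reference(config: SimConfig, out_fasta: str | Path | None = None) -> str:
    """Random uppercase A/C/G/T sequence of ``genome_length`` bases."""
    config.validate()
    rng = config.rngs()["reference"]
    seq = BASES[rng.integers(0, 4, size=config.genome_length)].tobytes().decode()
    if out_fasta is not None:
        write_fasta(out_fasta, config.chrom, seq)
    return seq


def write_fasta(path: str | Path, name: str, seq: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")


def sample_deletion_lengths(n: int, rng: np.random.Generator,
                            length_range: tuple[int, int] | None = None) -> np.ndarray:
    """Draw deletion lengths, log-uniform within each stratum (or within the
    given range)."""
    if length_range is not None:
        lo, hi = length_range
        if hi == lo:
            return np.full(n, lo, dtype=int)
        u = rng.uniform(np.log(lo), np.log(hi + 1), size=n)
        return np.minimum(np.exp(u).astype(int), hi)
    ranges = [r for r, _ in DELETION_LENGTH_STRATA]
    weights = np.array([w for _, w in DELETION_LENGTH_STRATA])
    weights = weights / weights.sum()
    which = rng.choice(len(ranges), size=n, p=weights)
    out = np.empty(n, dtype=int)
    for i, k in enumerate(which):
        lo, hi = ranges[k]
        out[i] = min(int(np.exp(rng.uniform(np.log(lo), np.log(hi)))), hi)
    return np.maximum(out, 50)


def place_deletions(config: SimConfig, rng: np.random.Generator | None = None,
                    lengths: np.ndarray | None = None) -> list[ImplantedDeletion]:
    """Choose disjoint deletion intervals separated by more than one mean
    insert, with random zygosity assignment under ``config.zygosity``."""
    config.validate()
    if rng is None:
        rng = config.rngs()["deletions"]
    n = config.n_deletions
    if n == 0:
        return []
    if lengths is None:
        lengths = sample_deletion_lengths(n, rng, config.deletion_length_range)
    min_gap = int(config.mean_insert) + 1
    free = config.genome_length - int(lengths.sum()) - min_gap * (n + 1)
    if free < 0:
        raise ConfigurationError(
            f"genome_length {config.genome_length} too small for {n} deletions "
            f"totalling {int(lengths.sum())} bp with {min_gap} bp separation"
        )
    cuts = np.sort(rng.integers(0, free + 1, size=n))
    extra = np.diff(np.concatenate(([0], cuts)))  # n gap extensions
    out = []
    pos = min_gap + int(extra[0] if n else 0)
    for i in range(n):
        start = pos
        length = int(lengths[i])
        if config.zygosity == "mixed":
            zyg = "homozygous" if rng.random() < 0.5 else "heterozygous"
        else:
            zyg = config.zygosity
        out.append(ImplantedDeletion(config.chrom, start, start + length, zyg))
        nxt = min_gap + (int(extra[i + 1]) if i + 1 < n else 0)
        pos = start + length + nxt
    return out


def implant_deletions(
    reference: str,
    config: SimConfig,
    deletions: Sequence[ImplantedDeletion] | None = None,
    truth_vcf: str | Path | None = None,
) -> tuple[tuple[Haplotype, Haplotype], list[ImplantedDeletion]]:
    """Build the two donor haplotypes and (optionally) write the truth VCF.

    Homozygous deletions are removed from both haplotypes; heterozygous ones
    from haplotype 0 only.  Overlapping requested deletions are rejected.
    """
    config.validate()
    if deletions is None:
        deletions = place_deletions(config)
    dels = sorted(deletions, key=lambda d: d.start)
    for a, b in zip(dels, dels[1:]):
        if b.start < a.end:
            raise ConfigurationError(f"overlapping deletions {a} and {b}")
        if a.end - a.start < 50 or b.end - b.start < 50:
            raise ConfigurationError("deletions must be >=50 bp")
    if dels and (dels[0].start < 0 or dels[-1].end > len(reference)):
        raise ConfigurationError("deletion outside the reference")
    hap0 = Haplotype.build(dels, len(reference))
    hap1 = Haplotype.build([d for d in dels if d.zygosity == "homozygous"],
                           len(reference))
    if truth_vcf is not None:
        write_truth_vcf(truth_vcf, dels, config.chrom, len(reference))
    return (hap0, hap1), dels


def write_truth_vcf(path: str | Path, deletions: Sequence[ImplantedDeletion],
                    chrom: str, contig_length: int) -> None:
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="Deletion end">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Deletion length">')
    header.add_line('##INFO=<ID=ZYG,Number=1,Type=String,Description="Simulated zygosity">')
    header.add_line('##ALT=<ID=DEL,Description="Deletion">')
    header.add_line(f"##contig=<ID={chrom},length={contig_length}>")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for d in sorted(deletions, key=lambda d: d.start):
            rec = vcf.new_record(contig=chrom, start=d.start, stop=d.end,
                                 alleles=("N", "<DEL>"))
            rec.info["SVTYPE"] = "DEL"
            rec.info["SVLEN"] = -d.length
            rec.info["ZYG"] = d.zygosity
            vcf.write(rec)


def _repeat_intervals(config: SimConfig, rng: np.random.Generator,
                      tile: int = 2000) -> np.ndarray:
    """Reference intervals whose reads are flagged as multi-mapping."""
    n = int(config.repeat_fraction * config.genome_length / tile)
    if n == 0:
        return np.empty((0, 2), dtype=int)
    starts = np.sort(rng.integers(0, config.genome_length - tile, size=n))
    return np.stack([starts, starts + tile], axis=1)


def simulate_aligned_reads(
    reference: str,
    haplotypes: tuple[Haplotype, Haplotype],
    config: SimConfig,
    out_bam: str | Path,
) -> dict[str, int]:
    """Emit a coordinate-sorted, indexed BAM of simulated pairs.

    Fragments are drawn on each donor haplotype (half the target depth each)
    and lifted to reference coordinates.  Returns per-class counts.
    """
    config.validate()
    rngs = config.rngs()
    frag_rng, err_rng = rngs["fragments"], rngs["errors"]
    repeats = _repeat_intervals(config, rngs["repeats"])
    rep_starts, rep_ends = (repeats[:, 0], repeats[:, 1]) if len(repeats) else (
        np.empty(0, int), np.empty(0, int))

    ref_bytes = np.frombuffer(reference.encode(), dtype="S1")
    rl = config.read_length
    qual = pysam.qualitystring_to_array("I" * rl)

    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": config.chrom, "LN": config.genome_length}],
        "RG": [{"ID": "sim", "SM": "sim"}],
    })

    counts = {"fragments": 0, "concordant_pairs": 0, "discordant_pairs": 0,
              "soft_clipped_reads": 0, "one_end_anchored_reads": 0,
              "multimapped_reads": 0}

    out_bam = Path(out_bam)
    tmp = out_bam.with_suffix(".unsorted.bam")

    def in_repeat(start: int, end: int) -> bool:
        if not len(rep_starts):
            return False
        i = int(np.searchsorted(rep_ends, start, side="right"))
        return i < len(rep_starts) and rep_starts[i] < end

    with pysam.AlignmentFile(str(tmp), "wb", header=header) as bam:
        frag_id = 0
        for hap_idx, hap in enumerate(haplotypes):
            n_frag = round(config.target_depth / 2 * hap.length / (2 * rl))
            lengths = np.rint(frag_rng.normal(config.mean_insert, config.sd_insert,
                                              size=n_frag)).astype(int)
            # truncate at 3 sd, mirroring a size-selected library's range;
            # keeps deletion-free pairs inside the concordance window
            lengths = np.clip(lengths,
                              int(config.mean_insert - 3 * config.sd_insert),
                              int(config.mean_insert + 3 * config.sd_insert))
            lengths = np.clip(lengths, rl, hap.length)
            starts = frag_rng.integers(0, hap.length - lengths + 1)
            # donor sequence as byte array for fast slicing
            hap_seq = np.frombuffer(hap.sequence(reference).encode(), dtype="S1")
            n_errs = err_rng.binomial(rl, config.base_error_rate, size=(n_frag, 2))
            for k in range(n_frag):
                frag_id += 1
                fs, fl = int(starts[k]), int(lengths[k])
                name = f"sim{frag_id:08d}"
                r1 = _lift_read(hap, fs, rl, config)
                r2 = _lift_read(hap, fs + fl - rl, rl, config)
                segs = []
                for ri, (lift, is_read2) in enumerate(((r1, False), (r2, True))):
                    ds = fs if not is_read2 else fs + fl - rl
                    seq = hap_seq[ds:ds + rl].copy()
                    ne = int(n_errs[k, ri])
                    nm = 0
                    if ne:
                        pos_err = err_rng.choice(rl, size=ne, replace=False)
                        for p in pos_err:
                            cur = seq[p]
                            alt = BASES[err_rng.integers(0, 4)]
                            while alt == cur:
                                alt = BASES[err_rng.integers(0, 4)]
                            seq[p] = alt
                        nm = _mismatches_in_match(lift, pos_err)
                    segs.append((lift, seq.tobytes().decode(), nm, is_read2))
                _write_pair(bam, config, name, segs, qual, in_repeat, counts)
        counts["fragments"] = frag_id

    pysam.sort("-o", str(out_bam), str(tmp))
    tmp.unlink()
    pysam.index(str(out_bam))
    log.info("simulated %s: %s", out_bam, counts)
    return counts


def _lift_read(hap: Haplotype, ds: int, rl: int, config: SimConfig):
    """Lift a donor interval [ds, ds+rl) to the reference.

    Returns (mapped, ref_pos, cigartuples, match_slice) where match_slice is
    the read-coordinate slice that is aligned (M); None pos when unmapped.
    """
    seg_a = hap.segment_index(ds)
    seg_b = hap.segment_index(ds + rl - 1)
    if seg_a == seg_b:
        return (True, ds + int(hap.offsets[seg_a]), [(0, rl)], (0, rl))
    # the read crosses one breakpoint (or, for adjacent deletions, more);
    # an aligner keeps the longer flanking segment and clips the rest
    bp_first = int(hap.breakpoints[seg_a])
    bp_last = int(hap.breakpoints[seg_b - 1])
    left = bp_first - ds
    right = ds + rl - bp_last
    if max(left, right) < config.min_anchor:
        return (False, None, None, (0, 0))
    if left >= right:
        pos = ds + int(hap.offsets[seg_a])
        return (True, pos, [(0, left), (4, rl - left)], (0, left))
    pos = bp_last + int(hap.offsets[seg_b])  # deletion end on the reference
    return (True, pos, [(4, rl - right), (0, right)], (rl - right, rl))


def _mismatches_in_match(lift, err_positions) -> int:
    mapped, _, _, (m0, m1) = lift
    if not mapped:
        return 0
    return int(sum(1 for p in err_positions if m0 <= p < m1))


def _aligned_end(pos: int, cigar) -> int:
    return pos + sum(ln for op, ln in cigar if op == 0)


def _write_pair(bam, config, name, segs, qual, in_repeat, counts) -> None:
    recs = []
    infos = []
    for lift, seq, nm, is_read2 in segs:
        mapped, pos, cigar, _ = lift
        a = pysam.AlignedSegment(bam.header)
        a.query_name = name
        a.query_sequence = seq
        a.query_qualities = qual
        a.is_paired = True
        a.is_read1 = not is_read2
        a.is_read2 = is_read2
        if mapped:
            a.reference_id = 0
            a.reference_start = pos
            a.cigartuples = cigar
            a.mapping_quality = 60
            end = _aligned_end(pos, cigar)
            multi = in_repeat(pos, end)
            if multi:
                a.mapping_quality = 0
                a.set_tag("XA", f"{config.chrom},+{pos + 1},{config.read_length}M,1;")
                counts["multimapped_reads"] += 1
            a.set_tag("NM", nm)
            a.set_tag("RG", "sim")
            infos.append((True, pos, end, is_read2))
        else:
            a.is_unmapped = True
            a.mapping_quality = 0
            a.set_tag("RG", "sim")
            infos.append((False, None, None, is_read2))
        a.is_reverse = is_read2
        recs.append(a)

    (m1, p1, e1, _), (m2, p2, e2, _) = infos
    a1, a2 = recs
    a1.mate_is_reverse = True
    a2.mate_is_reverse = False
    if m1 and m2:
        outer_start, outer_end = min(p1, p2), max(e1, e2)
        tlen = outer_end - outer_start
        a1.next_reference_id = 0
        a1.next_reference_start = p2
        a2.next_reference_id = 0
        a2.next_reference_start = p1
        a1.template_length = tlen if p1 <= p2 else -tlen
        a2.template_length = -a1.template_length
        concordant = abs(tlen - config.mean_insert) <= 3 * config.sd_insert
        a1.is_proper_pair = a2.is_proper_pair = concordant
        counts["concordant_pairs" if concordant else "discordant_pairs"] += 1
    elif m1 or m2:
        mapped_rec, unmapped_rec = (a1, a2) if m1 else (a2, a1)
        pos = p1 if m1 else p2
        unmapped_rec.reference_id = 0
        unmapped_rec.reference_start = pos
        unmapped_rec.next_reference_id = 0
        unmapped_rec.next_reference_start = pos
        mapped_rec.next_reference_id = 0
        mapped_rec.next_reference_start = pos
        mapped_rec.mate_is_unmapped = True
        counts["one_end_anchored_reads"] += 1
    else:
        for a in recs:
            a.next_reference_id = -1
            a.next_reference_start = -1
            a.mate_is_unmapped = True
    for a in recs:
        if a.cigartuples and any(op == 4 for op, _ in a.cigartuples):
            counts["soft_clipped_reads"] += 1
        bam.write(a)


# ---------------------------------------------------------------------------
# Synthetic caller output

#: (caller name, method class, per-deletion detection probability,
#:  breakpoint jitter as a fraction of the deletion length).  Split-read
#: callers report near-exact breakpoints; discordant-pair callers are
#: noisier but all jitter stays inside the 2% duplicate window so every
#: true call still matches the truth set.
DEFAULT_CALLER_PANEL: tuple[tuple[str, str, float, float], ...] = (
    ("pindel", "split_read", 0.70, 0.005),
    ("svseq2", "split_read", 0.70, 0.005),
    ("breakdancer", "discordant_pair", 0.70, 0.015),
    ("delly", "discordant_pair", 0.70, 0.015),
)


def simulate_caller_calls(
    deletions: Sequence[ImplantedDeletion],
    config: SimConfig,
    n_decoys: int = 300,
    panel: Sequence[tuple[str, str, float, float]] = DEFAULT_CALLER_PANEL,
    sample: str = "sim",
    rng: np.random.Generator | None = None,
) -> list[CandidateDeletion]:
    """Emulate an ensemble of SV callers run on the simulated sample.

    Each truth deletion is detected independently by each caller with its
    panel probability, with breakpoints jittered within the duplicate window.
    ``n_decoys`` false calls with stratum-distributed lengths are added at
    positions that neither duplicate nor substantially overlap any truth
    deletion.
    """
    if rng is None:
        rng = config.rngs()["callers"]
    calls: list[CandidateDeletion] = []
    for d in deletions:
        detected = False
        for name, mclass, p_det, jit in panel:
            if rng.random() >= p_det:
                continue
            j = int(jit * d.length)
            s = d.start + int(rng.integers(-j, j + 1)) if j else d.start
            e = d.end + int(rng.integers(-j, j + 1)) if j else d.end
            if e - s < 50:
                s, e = d.start, d.end
            calls.append(CandidateDeletion(config.chrom, s, e, source=name,
                                           method_class=mclass, sample=sample))
            detected = True
        if not detected:  # guarantee every truth deletion is a candidate
            name, mclass, _, _ = panel[int(rng.integers(0, len(panel)))]
            calls.append(CandidateDeletion(config.chrom, d.start, d.end,
                                           source=name, method_class=mclass,
                                           sample=sample))
    decoys = 0
    attempts = 0
    while decoys < n_decoys and attempts < 50 * n_decoys:
        attempts += 1
        length = int(sample_deletion_lengths(1, rng, config.deletion_length_range)[0])
        if length >= config.genome_length - 100:
            continue
        s = int(rng.integers(0, config.genome_length - length))
        e = s + length
        bad = any(
            breakpoint_match(s, e, d.start, d.end)
            or reciprocal_overlap_match(s, e, d.start, d.end)
            for d in deletions
        )
        if bad:
            continue
        name, mclass, _, _ = panel[int(rng.integers(0, len(panel)))]
        calls.append(CandidateDeletion(config.chrom, s, e, source=name,
                                       method_class=mclass, sample=sample))
        decoys += 1
    if decoys < n_decoys:
        raise ConfigurationError("could not place the requested decoy calls")
    calls.sort(key=lambda c: (c.chrom, c.start, c.end))
    return calls


def simulate(config: SimConfig, outdir: str | Path) -> dict:
    """Run the full simulation into ``outdir``; returns paths and truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref_fa = outdir / "reference.fa"
    truth_vcf = outdir / "truth.vcf"
    bam = outdir / "alignments.bam"
    reference = generate_reference(config, ref_fa)
    haps, dels = implant_deletions(reference, config, truth_vcf=truth_vcf)
    counts = simulate_aligned_reads(reference, haps, config, bam)
    return {"reference_fasta": ref_fa, "truth_vcf": truth_vcf, "bam": bam,
            "deletions": dels, "haplotypes": haps, "reference": reference,
            "counts": counts}
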