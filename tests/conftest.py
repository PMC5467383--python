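"""Shared fixtures and independent oracles for the test suite.

All BAM/VCF fixtures are generated at test time; nothing binary is stored in
the repository.  The oracle helpers here deliberately re-derive quantities by
brute force (per-base interval arithmetic, all-pairs transitive closure,
central finite differences) so they stay independent of the library code they
check.
"""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from delfilter.candidates import CandidateDeletion, are_duplicates
from delfilter.features import AlignmentRecordView
from delfilter.pipeline import build_synthetic_benchmark
from delfilter.simulator import SimConfig, generate_reference, implant_deletions, \
    simulate_aligned_reads


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small simulated sample with a mix of hom/het deletions."""
    outdir = tmp_path_factory.mktemp("small_sim")
    cfg = SimConfig(genome_length=120_000, n_deletions=12, seed=5,
                    zygosity="mixed")
    reference = generate_reference(cfg, outdir / "ref.fa")
    haps, dels = implant_deletions(reference, cfg, truth_vcf=outdir / "truth.vcf")
    counts = simulate_aligned_reads(reference, haps, cfg, outdir / "sim.bam")
    return {
        "config": cfg, "reference": reference, "haplotypes": haps,
        "deletions": dels, "bam": outdir / "sim.bam",
        "truth_vcf": outdir / "truth.vcf", "counts": counts,
        "outdir": outdir,
    }


@pytest.fixture(scope="session")
def bench(tmp_path_factory):
    """The standard synthetic benchmark: 300 implanted deletions across the
    realistic length strata at 10.6x plus 300 decoy candidates."""
    outdir = tmp_path_factory.mktemp("bench")
    return build_synthetic_benchmark(outdir, seed=7, n_deletions=300,
                                     n_decoys=300, genome_length=1_600_000)


def make_view(ref_start=0, ref_end=None, cigar=None, is_mapped=True,
              mate_mapped=True, mate_ref_start=0, template_length=0,
              n_mismatches=0, mapq=60, has_alt_hits=False, is_reverse=False,
              read_length=79):
    """Convenience constructor for AlignmentRecordView."""
    if cigar is None:
        cigar = ((0, read_length),)
    if ref_end is None:
        ref_end = ref_start + sum(ln for op, ln in cigar if op == 0)
    return AlignmentRecordView(
        ref_start=ref_start, ref_end=ref_end, cigar=tuple(cigar),
        is_mapped=is_mapped, mate_mapped=mate_mapped,
        mate_ref_start=mate_ref_start, template_length=template_length,
        n_mismatches=n_mismatches, mapq=mapq, has_alt_hits=has_alt_hits,
        is_reverse=is_reverse,
    )


def make_bam(path, reads, contig="chrT", contig_length=10_000):
    """Write a tiny coordinate-sorted indexed BAM from (pos, cigar) specs.

    ``reads`` is a list of dicts with keys pos, cigar (pysam tuples) and
    optional name/mapq/nm/seq_len.
    """
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": contig, "LN": contig_length}],
    })
    recs = []
    for i, spec in enumerate(reads):
        a = pysam.AlignedSegment(header)
        a.query_name = spec.get("name", f"r{i:04d}")
        cigar = spec["cigar"]
        qlen = sum(ln for op, ln in cigar if op in (0, 1, 4))
        a.query_sequence = "A" * qlen
        a.query_qualities = pysam.qualitystring_to_array("I" * qlen)
        a.reference_id = 0
        a.reference_start = spec["pos"]
        a.cigartuples = cigar
        a.mapping_quality = spec.get("mapq", 60)
        a.set_tag("NM", spec.get("nm", 0))
        recs.append(a)
    recs.sort(key=lambda r: r.reference_start)
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for r in recs:
            bam.write(r)
    pysam.index(str(path))
    return path


# ---------------------------------------------------------------------------
# independent oracles

def brute_force_clusters(cands) -> list[frozenset]:
    """Transitive closure of the pairwise duplicate relation, O(n^2)."""
    n = len(cands)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j and are_duplicates(cands[i], cands[j]):
                adj[i][j] = True
    seen, clusters = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(j for j in range(n) if adj[k][j] and j not in comp)
        seen |= comp
        clusters.append(frozenset((cands[k].chrom, cands[k].start, cands[k].end,
                                   cands[k].source) for k in comp))
    return sorted(clusters, key=lambda c: sorted(c))


def brute_force_mean_depth(bam_path, contig, start, end) -> float:
    """Per-base overlap counting over aligned (M) blocks."""
    depth = np.zeros(end - start, dtype=int)
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for r in bam.fetch(until_eof=True):
            if r.is_unmapped or r.is_secondary or r.is_supplementary:
                continue
            for bs, be in r.get_blocks():
                lo, hi = max(bs, start), min(be, end)
                if hi > lo:
                    depth[lo - start:hi - start] += 1
    return float(depth.mean())


def numerical_gradient(model, X, y, eps=1e-5) -> dict[str, np.ndarray]:
    """Central finite differences of the mean binary cross-entropy."""
    grads = {}
    for key, w in model.params.items():
        g = np.zeros_like(np.atleast_1d(w), dtype=float)
        flat = np.atleast_1d(model.params[key]).reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            lp = model.loss(X, y)
            flat[i] = orig - eps
            lm = model.loss(X, y)
            flat[i] = orig
            g.reshape(-1)[i] = (lp - lm) / (2 * eps)
        grads[key] = g.reshape(np.shape(w))
    return grads


def random_candidates(rng, n, chrom="chrT", sample="s", sources=("a", "b", "c")):
    """Random candidate sets with deliberate near-duplicates."""
    out = []
    anchors = rng.integers(0, 50_000, size=max(1, n // 3))
    for _ in range(n):
        if rng.random() < 0.6:
            start = int(rng.choice(anchors))
        else:
            start = int(rng.integers(0, 50_000))
        length = int(rng.integers(50, 3000))
        start += int(rng.integers(-30, 31))
        start = max(0, start)
        out.append(CandidateDeletion(
            chrom, start, start + length,
            source=str(rng.choice(list(sources))),
            method_class=str(rng.choice(["split_read", "discordant_pair"])),
            sample=sample))
    return out
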