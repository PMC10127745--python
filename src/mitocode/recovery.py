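"""Mitochondrial contig identification and bait-and-extend finishing.

Single-cell assemblies of amoeboid protists are mini-metagenomes: host
nuclear fragments, symbiont organelles and bacteria all co-assemble.  The
mitochondrial genome is nevertheless recoverable because it is present in
many copies per cell (orders-of-magnitude-higher read coverage) and is
AT-rich (much lower GC) relative to most contaminants.  This module

* computes per-contig coverage/GC blob statistics from raw reads,
* seeds mitochondrial candidates by translated protein homology against a
  reference orthologue panel,
* classifies remaining contigs by their proximity to the seeds in
  coverage/GC space, and
* finishes genomes by iterative read baiting: reads overlapping a growing
  consensus by >= 100 bp with <= 1% mismatches and no gaps are recruited and
  the consensus extended by majority vote, repeated to a fixpoint, with
  circularity detected from a duplicated terminus.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import reverse_complement

from ._align import six_frame_translations, windowed_local_hit
from .codes import GeneticCode, table4

logger = logging.getLogger(__name__)


def gc_content(seq: str) -> float:
    """GC fraction over unambiguous bases (N ignored)."""
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


@dataclass
class Contig:
    id: str
    seq: str
    coverage: float | None = None
    circular: bool = False

    def __post_init__(self):
        self.seq = self.seq.upper()
        if self.coverage is not None and self.coverage < 0:
            raise ValueError(f"contig {self.id}: negative coverage")

    @property
    def gc(self) -> float:
        return gc_content(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


def _normalize_reads(reads: Iterable) -> list:
    """Accept (id, seq) tuples, plain strings, or objects with .id/.seq."""
    out = []
    for i, r in enumerate(reads):
        if isinstance(r, str):
            out.append((f"read{i}", r.upper()))
        elif isinstance(r, tuple):
            out.append((r[0], r[1].upper()))
        else:
            out.append((r.id, str(r.seq).upper()))
    return out


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


class _KmerIndex:
    """Exact k-mer positions over one or more sequences."""

    def __init__(self, k: int = 21):
        self.k = k
        self.index: dict = {}

    def add(self, name, seq: str):
        k = self.k
        idx = self.index
        for i in range(len(seq) - k + 1):
            idx.setdefault(seq[i:i + k], []).append((name, i))

    def lookup(self, kmer: str) -> list:
        return self.index.get(kmer, [])


def _sample_offsets(length: int, k: int, step: int = 25) -> list:
    offs = list(range(0, max(1, length - k + 1), step))
    last = length - k
    if last > 0 and last not in offs:
        offs.append(last)
    return offs


def _best_ungapped_placement(read: str, target: str, index: _KmerIndex,
                             min_overlap: int, max_mismatch_frac: float,
                             name=None):
    """Best ungapped placement of ``read`` on ``target`` anchored by shared
    k-mers; returns (mismatch_frac, mismatches, delta) or None.  ``delta`` is
    the target coordinate of read position 0 (may be negative / overhang)."""
    k = index.k
    deltas = set()
    for off in _sample_offsets(len(read), k):
        for hit_name, pos in index.lookup(read[off:off + k]):
            if name is None or hit_name == name:
                deltas.add(pos - off)
    best = None
    for delta in sorted(deltas):
        t0, t1 = max(0, delta), min(len(target), delta + len(read))
        overlap = t1 - t0
        if overlap < min_overlap:
            continue
        r0 = t0 - delta
        mism = _hamming(read[r0:r0 + overlap], target[t0:t1])
        frac = mism / overlap
        if frac <= max_mismatch_frac and (best is None or (frac, delta) < (best[0], best[2])):
            best = (frac, mism, delta)
    return best


# ---------------------------------------------------------------------------
# Blob statistics and classification
# ---------------------------------------------------------------------------

def contig_stats(contigs: Sequence[Contig], reads: Iterable, k: int = 21,
                 min_overlap: int = 30, max_mismatch_frac: float = 0.05) -> dict:
    """Per-contig mean read coverage and GC.

    Coverage is total mapped bases / contig length; a read mapping equally
    well to n contigs contributes 1/n of its bases to each, so shared
    repeats do not inflate depth.  Updates ``contig.coverage`` in place.
    """
    index = _KmerIndex(k)
    by_name = {}
    for c in contigs:
        index.add(c.id, c.seq)
        by_name[c.id] = c
    mapped = {c.id: 0.0 for c in contigs}
    for _rid, seq in _normalize_reads(reads):
        placements = {}
        for oriented in (seq, reverse_complement(seq)):
            deltas: dict = {}
            for off in _sample_offsets(len(oriented), k):
                for name, pos in index.lookup(oriented[off:off + k]):
                    deltas.setdefault(name, set()).add(pos - off)
            for name, ds in deltas.items():
                target = by_name[name].seq
                for delta in sorted(ds):
                    t0, t1 = max(0, delta), min(len(target), delta + len(oriented))
                    overlap = t1 - t0
                    if overlap < min_overlap:
                        continue
                    mism = _hamming(oriented[t0 - delta:t0 - delta + overlap], target[t0:t1])
                    frac = mism / overlap
                    if frac > max_mismatch_frac:
                        continue
                    prev = placements.get(name)
                    if prev is None or (frac, delta) < (prev[0], prev[2]):
                        placements[name] = (frac, mism, delta)
        if not placements:
            continue
        best_frac = min(h[0] for h in placements.values())
        ties = [name for name, h in placements.items() if h[0] == best_frac]
        for name in ties:
            delta = placements[name][2]
            t0 = max(0, delta)
            t1 = min(len(by_name[name].seq), delta + len(seq))
            mapped[name] += (t1 - t0) / len(ties)
    stats = {}
    for c in contigs:
        cov = mapped[c.id] / len(c.seq)
        c.coverage = cov
        stats[c.id] = (cov, c.gc)
    return stats


@dataclass
class SeedHit:
    gene: str
    taxon: str
    score: float
    frame: int
    strand: str
    start: int
    end: int


def seed_mito_contigs(contigs: Sequence[Contig], panel_proteins: Mapping,
                      code: GeneticCode | None = None, min_score: float = 80.0,
                      min_identity: float = 0.4, kmer: int = 5, min_shared: int = 2) -> dict:
    """Identify putative mitochondrial contigs by translated homology.

    ``panel_proteins`` maps gene -> {taxon: protein}.  A contig is a seed if
    any six-frame translation aligns locally to any panel protein with score
    >= ``min_score``; per gene the first passing taxon suffices.  Returns
    {contig_id: [SeedHit, ...]} for seeds only.
    """
    if not panel_proteins:
        raise ValueError("panel is empty")
    code = code or table4()
    seeds: dict = {}
    for contig in contigs:
        frames = six_frame_translations(contig.seq, code)
        hits = []
        for gene, by_taxon in panel_proteins.items():
            gene_hit = None
            for taxon, prot in by_taxon.items():
                for ft in frames:
                    lh = windowed_local_hit(ft.protein, prot, k=kmer, min_shared=min_shared)
                    if lh is not None and lh.score >= min_score and lh.identity >= min_identity:
                        s, e = ft.nt_span(lh.q_start, lh.q_end)
                        cand = SeedHit(gene, taxon, lh.score, ft.frame, ft.strand, s, e)
                        if gene_hit is None or cand.score > gene_hit.score:
                            gene_hit = cand
                if gene_hit is not None:
                    break
            if gene_hit is not None:
                hits.append(gene_hit)
        if hits:
            seeds[contig.id] = hits
    if not seeds:
        logger.info("no mitochondrial seed contigs found")
    return seeds


def blob_classify(contigs: Sequence[Contig], seeds: Mapping, cov_factor: float = 2.0,
                  gc_window: float = 0.08) -> dict:
    """Label contigs {mito, other} from the seed contigs' coverage/GC.

    A non-seed contig is mito iff its coverage is within a multiplicative
    ``cov_factor`` band of the median seed coverage and its GC within
    +/- ``gc_window`` of the median seed GC.  Seeds are always mito.
    """
    if not seeds:
        raise ValueError("blob_classify requires at least one seed contig")
    seed_contigs = [c for c in contigs if c.id in seeds]
    if any(c.coverage is None for c in contigs):
        raise ValueError("contig coverage not set; run contig_stats first")
    if len(seed_contigs) == 1:
        logger.warning("single seed contig; coverage/GC band from one value")
    med_cov = statistics.median(c.coverage for c in seed_contigs)
    med_gc = statistics.median(c.gc for c in seed_contigs)
    labels = {}
    for c in contigs:
        if c.id in seeds:
            labels[c.id] = "mito"
            continue
        cov_ok = med_cov / cov_factor <= c.coverage <= med_cov * cov_factor
        gc_ok = abs(c.gc - med_gc) <= gc_window
        labels[c.id] = "mito" if (cov_ok and gc_ok) else "other"
    return labels


def blob_table(contigs: Sequence[Contig], labels: Mapping | None = None):
    """Blob-plot table (contig_id, length, coverage, gc, label)."""
    import pandas as pd

    rows = [{
        "contig_id": c.id, "length": len(c.seq),
        "coverage": c.coverage if c.coverage is not None else float("nan"),
        "gc": round(c.gc, 4),
        "label": (labels or {}).get(c.id, ""),
    } for c in contigs]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bait-and-extend assembly
# ---------------------------------------------------------------------------

@dataclass
class AssemblyState:
    consensus: str
    recruited_read_ids: set
    round: int
    converged: bool
    placements: dict = field(default_factory=dict)  # read_id -> global offset


def bait_extend_iterate(reads: Iterable, seed_seq: str, min_overlap: int = 100,
                        max_mismatch_frac: float = 0.01, allow_gaps: bool = False,
                        max_rounds: int = 2000, k: int = 21) -> AssemblyState:
    """Iterative read baiting from a seed sequence.

    Each round recruits every unrecruited read (either orientation) whose
    best ungapped placement on the round-start consensus overlaps by
    >= ``min_overlap`` bases with mismatches/overlap <= ``max_mismatch_frac``.
    Recruits are applied after the scan, so the result is independent of read
    input order.  The consensus is then re-called per column by majority vote
    over all recruited reads (the seed votes once; ties keep the previous
    base, new columns break ties alphabetically), which also extends it
    across overhanging read bases.  Iteration stops at a fixpoint (no new
    recruits) or at ``max_rounds``.
    """
    if allow_gaps:
        raise NotImplementedError("gapped recruitment is not supported")
    seed_seq = seed_seq.upper()
    if len(seed_seq) < min_overlap:
        raise ValueError("seed shorter than min_overlap")
    read_list = _normalize_reads(reads)
    if not read_list:
        raise ValueError("no reads supplied")

    votes: dict = {}
    for i, b in enumerate(seed_seq):
        votes[i] = {b: 1}
    left = 0
    consensus = seed_seq
    recruited: set = set()
    placements: dict = {}
    rnd = 0
    converged = False

    while rnd < max_rounds:
        rnd += 1
        index = _KmerIndex(k)
        index.add("cons", consensus)
        new_hits = []
        for rid, seq in read_list:
            if rid in recruited:
                continue
            best = None
            for orient, oseq in (("+", seq), ("-", reverse_complement(seq))):
                hit = _best_ungapped_placement(oseq, consensus, index, min_overlap,
                                               max_mismatch_frac)
                if hit is not None and (best is None or hit[:1] < best[0][:1]):
                    best = (hit, oseq)
            if best is not None:
                (frac, mism, delta), oseq = best
                new_hits.append((rid, oseq, delta))
        if not new_hits:
            converged = True
            break
        touched = set()
        for rid, oseq, delta in new_hits:
            recruited.add(rid)
            g0 = left + delta
            placements[rid] = g0
            for i, b in enumerate(oseq):
                col = g0 + i
                votes.setdefault(col, {})
                votes[col][b] = votes[col].get(b, 0) + 1
                touched.add(col)
        new_left = min(left, min(touched))
        new_right = max(left + len(consensus), max(touched) + 1)
        cons = list(consensus)
        # prepend / append new columns, then re-call touched columns
        cons = ["?"] * (left - new_left) + cons + ["?"] * (new_right - (left + len(consensus)))
        for col in touched:
            counts = votes[col]
            top = max(counts.values())
            winners = sorted(b for b, n in counts.items() if n == top)
            prev = cons[col - new_left]
            cons[col - new_left] = prev if prev in winners else winners[0]
        left = new_left
        consensus = "".join(cons)

    return AssemblyState(consensus, recruited, rnd, converged, placements)


def circularize(consensus: str, min_end_overlap: int = 50) -> tuple:
    """Detect a circular molecule from an exactly duplicated terminus.

    Circular iff a suffix of length >= ``min_end_overlap`` equals a prefix;
    the longest such duplication is trimmed once.  Returns
    ``(is_circular, trimmed_seq)``.  The default matches what bait-and-extend
    guarantees at convergence: with recruitment overlap m and read length L,
    the two ends of a finished circle overlap by at least 2m - L (50 bp at
    the 100/150 defaults), so requiring more would miss genuine circles.
    """
    L = len(consensus)
    if L < 2 * min_end_overlap:
        raise ValueError("consensus shorter than twice min_end_overlap")
    for klen in range(L - 1, min_end_overlap - 1, -1):
        if consensus[:klen] == consensus[L - klen:]:
            return True, consensus[:L - klen]
    return False, consensus


def _least_rotation(s: str) -> str:
    """Booth's algorithm: lexicographically smallest rotation, O(n)."""
    ss = s + s
    f = [-1] * len(ss)
    k = 0
    for j in range(1, len(ss)):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return ss[k:k + len(s)]


def canonical_rotation(seq: str) -> str:
    """Reproducible representation of a circular sequence: the smaller of the
    least rotations of the two strands."""
    return min(_least_rotation(seq), _least_rotation(reverse_complement(seq)))
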