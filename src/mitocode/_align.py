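"""Pairwise-alignment engine shared by the homology stages.

A thin, pluggable layer over Biopython's ``PairwiseAligner`` (Smith-Waterman
local / Needleman-Wunsch global with affine gaps and BLOSUM62).  Translated
searches are made tractable by an exact peptide k-mer prefilter plus windowed
alignment around the matching diagonal band, so full-length contig frames are
never aligned end-to-end against every panel protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .codes import GeneticCode, translate

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def make_protein_aligner(mode: str = "local", open_gap: float = -11.0,
                         extend_gap: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    aligner.mode = mode
    return aligner


def make_overlap_aligner() -> Align.PairwiseAligner:
    """Global aligner with free end gaps (semi-global / overlap mode)."""
    aligner = make_protein_aligner(mode="global")
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # Biopython < 1.86 naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


@dataclass(frozen=True)
class LocalHit:
    """Best local alignment of ``query`` vs ``ref`` (aa coordinates,
    0-based half-open, spanning first to last aligned block)."""

    score: float
    q_start: int
    q_end: int
    r_start: int
    r_end: int
    identity: float = 0.0
    n_columns: int = 0


def best_local_hit(query: str, ref: str, aligner=None,
                   trim_level: float = 0.45) -> LocalHit | None:
    """Best local hit trimmed to its maximum-identity core.

    AT-rich DNA translates into Leu/Ile/Phe-heavy peptides that score
    positively against hydrophobic membrane proteins under BLOSUM62 despite
    being unrelated, so raw Smith-Waterman spans overshoot gene boundaries
    and spurious hits arise from composition alone.  The aligned columns are
    therefore re-scored as ``match - trim_level`` and the hit is cut to the
    maximum-sum stretch (Kadane), which discards any flank whose sustained
    identity falls below ``trim_level`` however long it is.  Pass
    ``trim_level=0`` for the raw local alignment extent.
    """
    if not query or not ref:
        return None
    aligner = aligner or make_protein_aligner("local")
    alns = aligner.align(query, ref)
    if alns.score <= 0:
        return None
    aln = alns[0]
    qblocks, rblocks = aln.aligned
    if len(qblocks) == 0:
        return None
    cols = []
    for (q0, q1), (r0, r1) in zip(qblocks, rblocks):
        for off in range(q1 - q0):
            qp, rp = q0 + off, r0 + off
            cols.append((qp, rp, query[qp] == ref[rp]))
    i0, i1 = 0, len(cols)
    if trim_level > 0:
        best_sum = cur = 0.0
        best = None
        start = 0
        for i, (_qp, _rp, m) in enumerate(cols):
            cur += (1.0 if m else 0.0) - trim_level
            if cur <= 0:
                cur = 0.0
                start = i + 1
            elif cur > best_sum:
                best_sum, best = cur, (start, i + 1)
        if best is None:
            return None
        i0, i1 = best
    kept = cols[i0:i1]
    if not kept:
        return None
    ident = sum(m for *_x, m in kept) / len(kept)
    return LocalHit(float(aln.score), kept[0][0], kept[-1][0] + 1,
                    kept[0][1], kept[-1][1] + 1, ident, len(kept))


def shared_kmer_positions(query: str, ref: str, k: int = 5) -> list:
    """Positions in ``query`` of k-mers occurring exactly in ``ref``."""
    if len(query) < k or len(ref) < k:
        return []
    ref_kmers = {ref[i:i + k] for i in range(len(ref) - k + 1)}
    return [i for i in range(len(query) - k + 1) if query[i:i + k] in ref_kmers]


@lru_cache(maxsize=2048)
def _ref_kmer_index(ref: str, k: int) -> dict:
    index: dict = {}
    for i in range(len(ref) - k + 1):
        index.setdefault(ref[i:i + k], []).append(i)
    return index


def codiagonal_seeds(query: str, ref: str, k: int = 5, band: int = 20):
    """Largest cluster of exact k-mer seeds on nearby diagonals.

    Low-complexity/compositionally biased sequence pairs share scattered
    k-mers on random diagonals; genuine homology puts several seeds on the
    same diagonal (within ``band``).  Returns ``(cluster_size, (q_lo, q_hi))``
    for the best cluster, or ``(0, None)``.
    """
    if len(query) < k or len(ref) < k:
        return 0, None
    ref_index = _ref_kmer_index(ref, k)
    seeds = []  # (diagonal, query position)
    for qi in range(len(query) - k + 1):
        for ri in ref_index.get(query[qi:qi + k], ()):
            seeds.append((qi - ri, qi))
    if not seeds:
        return 0, None
    seeds.sort()
    best_n, best_span = 0, None
    j = 0
    for i in range(len(seeds)):
        if j < i:
            j = i
        while j + 1 < len(seeds) and seeds[j + 1][0] - seeds[i][0] <= band:
            j += 1
        n = j - i + 1
        if n > best_n:
            qs = [q for _d, q in seeds[i:j + 1]]
            best_n, best_span = n, (min(qs), max(qs) + k)
    return best_n, best_span


def windowed_local_hit(query: str, ref: str, k: int = 5, min_shared: int = 2,
                       aligner=None, trim_level: float = 0.45) -> LocalHit | None:
    """Local alignment restricted to the query window flagged by co-diagonal
    peptide k-mer seeds; returns None when the prefilter finds no candidate
    band.  Coordinates are reported on the full query."""
    n_seeds, span = codiagonal_seeds(query, ref, k=k)
    if span is None or n_seeds < min_shared:
        return None
    pad = len(ref)
    lo = max(0, span[0] - pad)
    hi = min(len(query), span[1] + pad)
    hit = best_local_hit(query[lo:hi], ref, aligner=aligner, trim_level=trim_level)
    if hit is None:
        return None
    return LocalHit(hit.score, hit.q_start + lo, hit.q_end + lo, hit.r_start,
                    hit.r_end, hit.identity, hit.n_columns)


@dataclass(frozen=True)
class FrameTranslation:
    """One of the six conceptual translations of a nucleotide sequence."""

    frame: int
    strand: str
    protein: str
    seq_len: int

    def nt_span(self, aa_start: int, aa_end: int) -> tuple:
        """Map an aa interval of this frame to forward-strand nt coordinates
        (0-based half-open)."""
        s = self.frame + 3 * aa_start
        e = self.frame + 3 * aa_end
        if self.strand == "+":
            return s, e
        return self.seq_len - e, self.seq_len - s


def six_frame_translations(seq: str, code: GeneticCode) -> list:
    """All six frame translations with stop codons rendered as X, so peptides
    stay alignable across in-frame stops."""
    from Bio.Seq import reverse_complement

    out = []
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        for frame in range(3):
            n = (len(s) - frame) // 3
            if n <= 0:
                continue
            sub = s[frame:frame + 3 * n]
            prot = translate(sub, code, readthrough="all_stops_as_X").protein
            out.append(FrameTranslation(frame, strand, prot, len(seq)))
    return out
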