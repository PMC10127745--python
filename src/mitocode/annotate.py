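"""Gene annotation and intergenic-feature scans on mitochondrial contigs.

Protein-coding genes are located by translated local alignment of the six
contig frames against per-gene reference consensi; in-frame stop codons are
rendered as X before aligning, so heavily recoded genes still produce
contiguous hits.  On top of the gene calls this module detects

* split genes (two same-gene annotations covering complementary parts of
  the reference),
* pseudogene fragments in intergenic space, annotated only when at least
  four distinct panel taxa hit the same region for the same gene,
* ~50-bp pseudorepeat families (approximate repeats within two mismatches
  of a family consensus), and
* single-nucleotide-insertion frameshift repairs: positions where inserting
  one N restores a continuous reading frame spanning the reference protein.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from ._align import (best_local_hit, make_protein_aligner, six_frame_translations,
                     windowed_local_hit)
from .codes import STOP, GeneticCode, translate

logger = logging.getLogger(__name__)


@dataclass
class GeneAnnotation:
    gene: str
    contig_id: str
    start: int              # 0-based half-open, forward strand
    end: int
    strand: str
    frame: int
    score: float
    coverage_of_reference: float
    ref_start: int = 0      # aa interval covered on the reference protein
    ref_end: int = 0
    split_part: int = 0     # 0 = none

    def __post_init__(self):
        if not 0 < self.coverage_of_reference <= 1:
            raise ValueError(f"{self.gene}: coverage_of_reference outside (0, 1]")


@dataclass
class FragmentHit:
    gene: str
    contig_id: str
    start: int
    end: int
    n_supporting_taxa: int
    mean_score: float
    supporting_taxa: list = field(default_factory=list)

    def __post_init__(self):
        if self.n_supporting_taxa < 1:
            raise ValueError("fragment hit without supporting taxa")


@dataclass
class RepeatFamily:
    consensus: str
    occurrences: list       # (start, end) tuples
    max_mismatches_observed: int

    @property
    def unit_length(self) -> int:
        return len(self.consensus)


@dataclass
class FrameshiftCall:
    gene: str
    position: int           # best insertion offset within the region
    window: tuple           # (lo, hi) contiguous equivalent insertion offsets
    score: float
    ref_coverage: float
    restored_span: tuple    # codon interval of the restored ORF
    ambiguous: bool = False


def panel_consensus(by_taxon: dict) -> str:
    """Majority residue per column of a pre-aligned orthologue set (gap wins
    only if no residue is present)."""
    seqs = list(by_taxon.values())
    length = max(len(s) for s in seqs)
    cols = []
    for i in range(length):
        counts = Counter(s[i] for s in seqs if i < len(s) and s[i] != "-")
        cols.append(counts.most_common(1)[0][0] if counts else "X")
    return "".join(cols)


# ---------------------------------------------------------------------------
# Homology annotation
# ---------------------------------------------------------------------------

def annotate_by_homology(contig, panel_proteins: dict, code: GeneticCode,
                         min_score: float = 80.0, min_identity: float = 0.4,
                         min_columns: int = 20, max_project: int = 15,
                         kmer: int = 5, min_shared: int = 2) -> list:
    """Best-scoring translated local alignments per gene, as annotations.

    For every gene the reference is the panel consensus; each of the six
    frames is searched, and after a hit the matched stretch is masked and the
    frame searched once more, so two-part genes (splits, frameshift halves)
    are both recovered even within one frame.  Because local alignment
    clips divergent first/last residues, boundaries are projected outward to
    the full reference extent when the missing margin is small
    (<= ``max_project`` codons).  Overlapping same-frame calls of different
    genes are resolved by score.
    """
    annotations: list = []
    frames = six_frame_translations(contig.seq, code)
    for gene, by_taxon in panel_proteins.items():
        ref = panel_consensus(by_taxon)
        found_any = False
        # short references can lack exact 5-mer seeds by chance; retry with
        # a smaller seed word before declaring the gene absent
        for k, shared in ((kmer, min_shared), (kmer - 1, min_shared)):
            for ft in frames:
                prot = ft.protein
                for _pass in range(2):
                    hit = windowed_local_hit(prot, ref, k=k, min_shared=shared)
                    if (hit is None or hit.score < min_score
                            or hit.identity < min_identity
                            or hit.n_columns < min_columns):
                        break
                    found_any = True
                    # project clipped boundaries out to the reference extent
                    ext_s = min(hit.r_start, max_project, hit.q_start)
                    ext_e = min(len(ref) - hit.r_end, max_project,
                                len(prot) - hit.q_end)
                    qs, qe = hit.q_start - ext_s, hit.q_end + ext_e
                    rs, re_ = hit.r_start - ext_s, hit.r_end + ext_e
                    s, e = ft.nt_span(qs, qe)
                    annotations.append(GeneAnnotation(
                        gene=gene, contig_id=contig.id, start=s, end=e,
                        strand=ft.strand, frame=ft.frame, score=hit.score,
                        coverage_of_reference=(re_ - rs) / len(ref),
                        ref_start=rs, ref_end=re_,
                    ))
                    prot = prot[:qs] + "X" * (qe - qs) + prot[qe:]
            if found_any:
                break
    # resolve same-frame overlaps between different genes by score
    annotations.sort(key=lambda a: -a.score)
    kept: list = []
    for ann in annotations:
        clash = any(
            k.gene != ann.gene and k.strand == ann.strand and k.frame == ann.frame
            and min(k.end, ann.end) - max(k.start, ann.start) > 0.5 * (ann.end - ann.start)
            for k in kept
        )
        if not clash:
            kept.append(ann)
    kept.sort(key=lambda a: (a.start, a.end))
    return kept


def detect_split_genes(annotations: list, combined_min: float = 0.8,
                       ref_overlap_max: float = 0.1) -> list:
    """Flag pairs of same-gene annotations with complementary reference
    coverage (combined >= ``combined_min``, overlap on the reference
    <= ``ref_overlap_max``) as split parts 1/2 in reference order.
    Full-length duplicates fail the overlap rule and stay unflagged."""
    by_gene = defaultdict(list)
    for a in annotations:
        by_gene[a.gene].append(a)
    for gene, anns in by_gene.items():
        if len(anns) < 2:
            continue
        anns = sorted(anns, key=lambda a: -a.score)[:4]
        best_pair = None
        for i in range(len(anns)):
            for j in range(i + 1, len(anns)):
                a, b = sorted((anns[i], anns[j]), key=lambda x: x.ref_start)
                ref_len = max(a.ref_end, b.ref_end)
                if ref_len == 0:
                    continue
                overlap = max(0, min(a.ref_end, b.ref_end) - max(a.ref_start, b.ref_start))
                # alignment boundary fuzz: a modest reference overlap between
                # otherwise complementary parts is clipped from the second
                # part, not treated as duplication
                clip = 0
                if 0 < overlap / ref_len <= 0.25 and b.ref_end > a.ref_end:
                    clip = overlap
                cov_b = b.coverage_of_reference - clip / ref_len
                eff_overlap = overlap - clip
                combined = a.coverage_of_reference + cov_b - eff_overlap / ref_len
                if combined >= combined_min and eff_overlap / ref_len <= ref_overlap_max:
                    score = a.score + b.score
                    if best_pair is None or score > best_pair[0]:
                        best_pair = (score, a, b, clip)
        if best_pair is not None:
            _, a, b, clip = best_pair
            a.split_part, b.split_part = 1, 2
            if clip:
                span = b.ref_end - b.ref_start
                b.coverage_of_reference *= (span - clip) / span
                b.ref_start += clip
                if b.strand == "+":
                    b.start += 3 * clip
                else:
                    b.end -= 3 * clip
    return annotations


# ---------------------------------------------------------------------------
# Intergenic fragment scan (the >= 4-distinct-taxa rule)
# ---------------------------------------------------------------------------

def full_gene_annotations(annotations: list, full_cov: float = 0.7) -> list:
    """Annotations that represent genes rather than fragment candidates:
    reference coverage >= ``full_cov``, or a flagged split part (split-gene
    halves individually cover less than a full reference)."""
    return [a for a in annotations
            if a.coverage_of_reference >= full_cov or a.split_part]


def intergenic_regions(contig_length: int, annotations: list, min_len: int = 60) -> list:
    """Complement of the annotated spans, as (start, end) intervals."""
    spans = sorted((a.start, a.end) for a in annotations)
    merged: list = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    regions = []
    prev = 0
    for s, e in merged + [[contig_length, contig_length]]:
        if s - prev >= min_len:
            regions.append((prev, s))
        prev = max(prev, e)
    return regions


def calibrate_null_threshold(region_seq: str, panel_proteins: dict, code: GeneticCode,
                             seed: int = 0, n_null: int = 60,
                             quantile: float = 0.99, floor: float = 60.0) -> float:
    """Empirical score threshold from shuffled-sequence null alignments.

    The region is shuffled (seeded), translated in a random frame and locally
    aligned against randomly drawn panel proteins; the threshold is the given
    quantile of the null scores, scaled by a 10% safety margin, but never
    below ``floor``.
    """
    rng = np.random.default_rng(seed)
    all_prots = [p for by_taxon in panel_proteins.values() for p in by_taxon.values()]
    if not all_prots:
        return floor
    aligner = make_protein_aligner("local")
    scores = []
    chars = np.array(list(region_seq))
    for _ in range(n_null):
        rng.shuffle(chars)
        shuffled = "".join(chars)
        frames = six_frame_translations(shuffled, code)
        ft = frames[int(rng.integers(0, len(frames)))]
        prot = all_prots[int(rng.integers(0, len(all_prots)))]
        hit = best_local_hit(ft.protein, prot, aligner=aligner)
        scores.append(hit.score if hit else 0.0)
    return max(floor, 1.1 * float(np.quantile(scores, quantile)))


def scan_intergenic_fragments(contig, annotations: list, panel_proteins: dict,
                              code: GeneticCode, min_taxa: int = 4,
                              threshold: float | None = None, min_identity: float = 0.5,
                              seed: int = 0, kmer: int = 5, min_shared: int = 3) -> list:
    """Six-frame translated search of intergenic regions against every panel
    taxon; a region is annotated for gene g iff >= ``min_taxa`` *distinct*
    panel taxa hit it for g above threshold.  Distinctness is by panel source
    label, so one taxon with repeated domains cannot satisfy the rule."""
    hits: list = []
    regions = intergenic_regions(len(contig.seq), full_gene_annotations(annotations))
    if not regions:
        return []
    thr = threshold
    if thr is None:
        # calibrate once per contig on the longest region: null score scale
        # grows with region length, so this is conservative for the others
        longest = max(regions, key=lambda r: r[1] - r[0])
        thr = calibrate_null_threshold(contig.seq[longest[0]:longest[1]],
                                       panel_proteins, code, seed=seed)
    for rs, re_ in regions:
        region = contig.seq[rs:re_]
        frames = six_frame_translations(region, code)
        for gene, by_taxon in panel_proteins.items():
            taxa_hit = {}
            envelope = None
            for taxon, prot in by_taxon.items():
                best = None
                for ft in frames:
                    lh = windowed_local_hit(ft.protein, prot, k=kmer, min_shared=min_shared)
                    if (lh is not None and lh.score >= thr
                            and lh.identity >= min_identity and lh.n_columns >= 20):
                        if best is None or lh.score > best[0].score:
                            best = (lh, ft)
                if best is not None:
                    lh, ft = best
                    taxa_hit[taxon] = lh.score
                    s, e = ft.nt_span(lh.q_start, lh.q_end)
                    span = (rs + s, rs + e)
                    envelope = span if envelope is None else (
                        min(envelope[0], span[0]), max(envelope[1], span[1]))
            if len(taxa_hit) >= min_taxa:
                hits.append(FragmentHit(
                    gene=gene, contig_id=contig.id, start=envelope[0], end=envelope[1],
                    n_supporting_taxa=len(taxa_hit),
                    mean_score=float(np.mean(list(taxa_hit.values()))),
                    supporting_taxa=sorted(taxa_hit),
                ))
    hits.sort(key=lambda h: (h.start, h.gene))
    return hits


# ---------------------------------------------------------------------------
# Pseudorepeat families
# ---------------------------------------------------------------------------

def _extend_pair(seq: str, i: int, j: int, anchor_len: int, unit_len: int,
                 unit_tol: int, max_mismatch: int):
    """Grow an exact anchor at (i, j) into an approximately repeated unit of
    about ``unit_len`` bp with <= ``max_mismatch`` pairwise mismatches.

    Exact search on the (j - i) diagonal: among all windows containing the
    anchor, of length between ``unit_len - unit_tol`` and
    ``unit_len + unit_tol`` (capped at the offset, keeping the two
    occurrences disjoint), the longest one within the mismatch budget wins.
    """
    d = j - i
    max_len = min(unit_len + unit_tol, d)
    min_len = unit_len - unit_tol
    if max_len < min_len:
        return None
    lo = max(0, i + anchor_len - max_len)
    hi = min(len(seq) - d, i + max_len)
    if hi - lo < min_len:
        return None
    mism = [0]
    for x in range(lo, hi):
        mism.append(mism[-1] + (seq[x] != seq[x + d]))
    for length in range(max_len, min_len - 1, -1):
        best = None
        s_min = max(lo, i + anchor_len - length)
        s_max = min(i, hi - length)
        for s in range(s_min, s_max + 1):
            mm = mism[s - lo + length] - mism[s - lo]
            if mm <= max_mismatch and (best is None or mm < best[0]):
                best = (mm, s)
        if best is not None:
            mm, s = best
            return (s, s + length), (s + d, s + d + length), mm
    return None


def detect_pseudorepeats(seq: str, unit_len: int = 50, unit_tol: int = 10,
                         max_mismatch: int = 2, anchor_k: int = 14) -> list:
    """Families of >= 2 approximately repeated ~``unit_len``-bp units.

    Candidate pairs are seeded by exact ``anchor_k``-mers shared between two
    positions (two mismatches in 50 bp leave a >= 16-bp exact stretch, so
    every qualifying unit pair shares an anchor) and extended under a budget
    of ``2 * max_mismatch`` pairwise mismatches - two occurrences each
    ``max_mismatch`` away from the family consensus can differ pairwise by
    twice that.  Overlapping candidate occurrences are clustered into
    families; each member is then re-anchored against the family consensus
    (allowing small offset shifts), kept only if within ``max_mismatch`` of
    it, and placed greedily without overlap.
    """
    seq = seq.upper()
    if len(seq) < unit_len:
        return []
    anchors: dict = {}
    for i in range(len(seq) - anchor_k + 1):
        anchors.setdefault(seq[i:i + anchor_k], []).append(i)

    pair_budget = 2 * max_mismatch
    occ_pairs = []
    seen_pairs = set()
    for positions in anchors.values():
        if len(positions) < 2:
            continue
        for ai in range(len(positions)):
            for aj in range(ai + 1, len(positions)):
                i, j = positions[ai], positions[aj]
                if j - i < unit_len - unit_tol:
                    continue
                ext = _extend_pair(seq, i, j, anchor_k, unit_len, unit_tol, pair_budget)
                if ext is None:
                    continue
                (s1, e1), (s2, e2), mism = ext
                key = (s1 // 10, s2 // 10)
                if key in seen_pairs:
                    continue
                seen_pairs.add(key)
                occ_pairs.append(((s1, e1), (s2, e2), mism))

    if not occ_pairs:
        return []

    # cluster occurrences into families: paired or overlapping occurrences
    # belong together
    occs = []
    for a, b, _m in occ_pairs:
        occs.extend([a, b])
    occs = sorted(set(occs))
    parent = list(range(len(occs)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    idx = {o: i for i, o in enumerate(occs)}
    for a, b, _m in occ_pairs:
        union(idx[a], idx[b])
    for i in range(1, len(occs)):
        if occs[i][0] < occs[i - 1][1]:  # overlapping occurrences: same family
            union(i - 1, i)

    fam_pairs: dict = defaultdict(list)
    for a, b, _m in occ_pairs:
        fam_pairs[find(idx[a])].append((a, b))

    out = []
    for pairs in fam_pairs.values():
        fam = _refine_family(seq, pairs, unit_len, unit_tol, max_mismatch)
        if fam is not None:
            out.append(fam)
    out.sort(key=lambda f: f.occurrences[0])
    return out


def _refine_family(seq: str, pairs: list, unit_len: int, unit_tol: int,
                   max_mismatch: int):
    """Locate the unit within a family from its pair diagonals.

    Pair extension drags unrelated flanking bases into candidate occurrence
    intervals, but the *diagonal* (offset between the two occurrences of a
    pair) is exact.  Members are therefore placed on diagonal-consistent
    relative coordinates; per-column agreement across members then shows a
    plateau over the true unit and noise outside it, and the window (width
    ``unit_len`` +/- ``unit_tol``) maximizing threshold-adjusted agreement
    is taken as the unit.  Members within ``max_mismatch`` of the window
    consensus are kept and placed greedily without overlap.
    """
    # 1. collapse candidate intervals describing the same physical
    # occurrence: substantial overlap required, so adjacent tandem copies
    # (which may abut or overlap by a few junk bases) stay separate
    nodes = sorted({o for a, b in pairs for o in (a, b)})
    cluster_of: dict = {}
    cluster_id = -1
    last_end = -1
    for occ in nodes:
        if occ[0] > last_end - unit_len // 2:
            cluster_id += 1
        cluster_of[occ] = cluster_id
        last_end = max(last_end, occ[1])

    # 2. exact alignment diagonals between occurrences: every extension pair
    # lies on one diagonal (b = a + d columnwise); between two occurrences
    # take the modal diagonal, outvoting chance-shifted anchors
    votes: dict = defaultdict(list)
    for a, b in pairs:
        ka, kb = cluster_of[a], cluster_of[b]
        if ka != kb:
            votes[(ka, kb)].append(b[0] - a[0])
    edges: dict = defaultdict(list)
    for (ka, kb), ds in votes.items():
        d = Counter(ds).most_common(1)[0][0]
        edges[ka].append((kb, d))
        edges[kb].append((ka, -d))

    # 3. propagate a consistent base per occurrence from the diagonals
    root = cluster_of[nodes[0]]
    rel = {root: 0}
    queue = [root]
    while queue:
        cur = queue.pop()
        for nxt, d in edges[cur]:
            if nxt not in rel:
                rel[nxt] = rel[cur] + d
                queue.append(nxt)
    if len(rel) < 2:
        return None
    starts = sorted(nodes[0][0] + r for r in rel.values())

    # agreement profile over relative columns around the anchor region
    span_lo, span_hi = -unit_len, 2 * unit_len
    agree = {}
    for c in range(span_lo, span_hi):
        bases = [seq[s + c] for s in starts if 0 <= s + c < len(seq)]
        if len(bases) < 2:
            agree[c] = 0.0
        else:
            agree[c] = Counter(bases).most_common(1)[0][1] / len(bases)

    candidates = []
    for width in range(unit_len - unit_tol, unit_len + unit_tol + 1):
        for c0 in range(span_lo, span_hi - width):
            score = sum(agree[c] - 0.6 for c in range(c0, c0 + width))
            if score > 0:
                candidates.append((score, c0, width))
    candidates.sort(reverse=True)

    def _validate(c0, width):
        consensus = "".join(
            Counter(seq[s + c] for s in starts if 0 <= s + c < len(seq)).most_common(1)[0][0]
            for c in range(c0, c0 + width))
        placed = []
        for s in starts:
            u0 = s + c0
            if u0 < 0 or u0 + width > len(seq):
                continue
            mm = sum(seq[u0 + ci] != consensus[ci] for ci in range(width))
            if mm > max_mismatch:
                continue
            if placed and u0 < placed[-1][0] + width:
                continue
            placed.append((u0, mm))
        return consensus, placed

    # agreement ranks the windows; the final choice is by how many members
    # actually validate against the window consensus
    best = None
    for _score, c0, width in candidates[:300]:
        consensus, placed = _validate(c0, width)
        if len(placed) < 2:
            continue
        key = (len(placed), -sum(m for _s, m in placed), width)
        if best is None or key > best[0]:
            best = (key, consensus, placed, width)
    if best is None:
        return None
    _key, consensus, placed, width = best
    return RepeatFamily(
        consensus=consensus,
        occurrences=[(s, s + width) for s, _m in placed],
        max_mismatches_observed=max(m for _s, m in placed),
    )


# ---------------------------------------------------------------------------
# Single-insertion frameshift repair
# ---------------------------------------------------------------------------

def _longest_stop_free_run(seq: str, code: GeneticCode) -> tuple:
    """Longest run of codons without a hard stop in frame 0 (trailing stop
    allowed); returns (start_codon, end_codon).  Dual-role codons are sense
    internally and do not break the run."""
    n = len(seq) // 3
    best = (0, 0)
    run_start = 0
    for ci in range(n + 1):
        codon = seq[3 * ci: 3 * ci + 3] if ci < n else None
        terminates = (codon is not None and "N" not in codon
                      and code.table[codon] == STOP)
        if ci == n or terminates:
            if ci - run_start > best[1] - best[0]:
                best = (run_start, ci)
            run_start = ci + 1
    return best


def repair_single_insertion_frameshift(region: str, reference_protein: str,
                                       code: GeneticCode, min_ref_cov: float = 0.9,
                                       min_score: float = 40.0) -> list:
    """Exhaustive single-N insertion scan restoring a full-length ORF.

    Every insertion offset p for which ``region[:p] + N + region[p:]``
    contains a stop-free frame-0 ORF of >= ``min_ref_cov`` of the reference
    length *and* whose translation locally aligns to >= ``min_ref_cov`` of
    the reference is reported.  Contiguous equivalent offsets are grouped
    into one call (within a homopolymer the exact position is unknowable);
    disjoint windows are all returned, best score first and flagged
    ambiguous.  An intact region yields no calls.
    """
    region = region.upper()
    ref_len = len(reference_protein)
    min_codons = min_ref_cov * ref_len
    aligner = make_protein_aligner("local")

    def _passes(seq: str):
        lo, hi = _longest_stop_free_run(seq, code)
        if hi - lo < min_codons:
            return None
        prot = translate(seq[3 * lo: 3 * hi], code, readthrough="all_stops_as_X").protein
        hit = best_local_hit(prot, reference_protein, aligner=aligner)
        if hit is None or hit.score < min_score:
            return None
        if (hit.r_end - hit.r_start) / ref_len < min_ref_cov:
            return None
        return (hit.score, (lo, hi))

    # pre-check: already intact?
    if len(region) >= 3 and _passes(region[: 3 * (len(region) // 3)]):
        return []

    passing: dict = {}
    trimmed_len = 3 * ((len(region) + 1) // 3)
    for p in range(len(region) + 1):
        cand = (region[:p] + "N" + region[p:])[:trimmed_len]
        lo, hi = _longest_stop_free_run(cand, code)
        if hi - lo < min_codons:
            continue
        res = _passes(cand)
        if res is not None:
            passing[p] = res

    if not passing:
        return []

    calls = []
    window: list = []
    for p in sorted(passing):
        if window and p != window[-1] + 1:
            calls.append(window)
            window = []
        window.append(p)
    calls.append(window)

    out = []
    for window in calls:
        scored = [(passing[p][0], p) for p in window]
        best_score, best_p = max(scored)
        out.append(FrameshiftCall(
            gene="", position=best_p, window=(window[0], window[-1] + 1),
            score=float(best_score), ref_coverage=min_ref_cov,
            restored_span=passing[best_p][1], ambiguous=len(calls) > 1,
        ))
    out.sort(key=lambda c: -c.score)
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def coding_summary(contig, annotations: list) -> dict:
    """Gene order, coding fraction and intergenic spans of one contig."""
    anns = sorted(annotations, key=lambda a: a.start)
    covered = 0
    prev_end = 0
    intergenic = []
    for s, e in _merge_spans(anns):
        covered += e - s
        if s > prev_end:
            intergenic.append((prev_end, s))
        prev_end = e
    if prev_end < len(contig.seq):
        intergenic.append((prev_end, len(contig.seq)))
    return {
        "contig_id": contig.id,
        "gene_order": [a.gene for a in anns],
        "coding_fraction": covered / len(contig.seq) if len(contig.seq) else 0.0,
        "intergenic_spans": intergenic,
        "intergenic_lengths": [e - s for s, e in intergenic],
    }


def _merge_spans(annotations: list) -> list:
    merged: list = []
    for a in sorted(annotations, key=lambda x: x.start):
        if merged and a.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], a.end)
        else:
            merged.append([a.start, a.end])
    return [(s, e) for s, e in merged]
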