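"""Gene annotation, split/fragment/repeat detection and frameshift repair."""

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from mitocode.annotate import (GeneAnnotation,
                               annotate_by_homology, coding_summary,
                               detect_pseudorepeats, detect_split_genes,
                               full_gene_annotations, intergenic_regions,
                               panel_consensus,
                               repair_single_insertion_frameshift,
                               scan_intergenic_fragments)
from mitocode.codes import table4
from mitocode.recovery import Contig
from mitocode.simulate import _random_dna


# ---------------------------------------------------------------------------
# homology annotation (session fixtures: default synthetic genome, seed 1)
# ---------------------------------------------------------------------------

def test_all_planted_genes_annotated_with_tight_boundaries(annotations, truth,
                                                           default_cfg):
    truth_names = {g["gene"] for g in truth.genes}
    full = full_gene_annotations(annotations)
    assert {a.gene for a in full} == truth_names
    for g in truth.genes:
        if g["split_part"] or g["gene"] == default_cfg.frameshift_gene:
            continue
        best = max((a for a in annotations if a.gene == g["gene"]),
                   key=lambda a: a.score)
        assert abs(best.start - g["start"]) <= 15
        # the annotation excludes the 3-nt terminator at the CDS end
        assert abs(best.end - (g["end"] - 3)) <= 15
        assert best.strand == g["strand"]


def test_fragment_candidate_is_not_a_full_gene(annotations, truth):
    frag_gene = truth.fragments[0]["gene"]
    cands = [a for a in annotations if a.gene == frag_gene]
    assert cands, "pseudogene fragment should still produce a weak annotation"
    assert all(a.coverage_of_reference < 0.7 for a in cands)
    assert frag_gene not in {a.gene for a in full_gene_annotations(annotations)}


def test_empty_contig_yields_no_annotations(panel_proteins):
    contig = Contig("empty", _random_dna(np.random.default_rng(0), 3000, 0.25))
    assert annotate_by_homology(contig, panel_proteins, table4()) == []


def test_split_gene_flagged_in_reference_order(annotations, default_cfg, truth):
    parts = sorted((a.split_part, a.ref_start) for a in annotations
                   if a.gene == default_cfg.split_gene and a.split_part)
    assert [p for p, _ in parts] == [1, 2]
    assert parts[0][1] < parts[1][1]


def _ann(gene, ref_start, ref_end, ref_len=300, score=500, start=0):
    return GeneAnnotation(gene=gene, contig_id="c", start=start,
                          end=start + 3 * (ref_end - ref_start), strand="+",
                          frame=0, score=score,
                          coverage_of_reference=(ref_end - ref_start) / ref_len,
                          ref_start=ref_start, ref_end=ref_end)


def test_split_rule_on_handmade_annotations():
    # complementary halves -> flagged
    a, b = _ann("g", 0, 150), _ann("g", 150, 300, start=2000)
    detect_split_genes([a, b])
    assert (a.split_part, b.split_part) == (1, 2)
    # single full-length gene -> untouched
    c = _ann("g", 0, 300)
    detect_split_genes([c])
    assert c.split_part == 0
    # two full-length copies -> duplicates, not split
    d, e = _ann("g", 0, 300), _ann("g", 0, 300, start=5000)
    detect_split_genes([d, e])
    assert d.split_part == e.split_part == 0


def test_intergenic_regions_complement_annotations():
    anns = [_ann("g", 0, 100, start=500), _ann("h", 0, 100, start=1000)]
    regions = intergenic_regions(2000, anns, min_len=60)
    assert regions == [(0, 500), (800, 1000), (1300, 2000)]


# ---------------------------------------------------------------------------
# fragment scan and the >= 4 distinct taxa rule
# ---------------------------------------------------------------------------

def test_planted_fragment_annotated_with_many_supporting_taxa(
        mito_contig, annotations, panel_proteins, truth):
    frags = scan_intergenic_fragments(mito_contig, annotations, panel_proteins,
                                      table4(), seed=0)
    tf = truth.fragments[0]
    match = [f for f in frags if f.gene == tf["gene"]
             and f.start < tf["end"] and f.end > tf["start"]]
    assert len(match) == 1
    assert match[0].n_supporting_taxa >= 4
    assert all(f.gene == tf["gene"] for f in frags), "no spurious fragment calls"


def test_fragment_rule_threshold_is_monotone(mito_contig, annotations,
                                             panel_proteins):
    lo = scan_intergenic_fragments(mito_contig, annotations, panel_proteins,
                                   table4(), min_taxa=4, seed=0)
    hi = scan_intergenic_fragments(mito_contig, annotations, panel_proteins,
                                   table4(), min_taxa=6, seed=0)
    lo_keys = {(f.gene, f.start, f.end) for f in lo}
    assert {(f.gene, f.start, f.end) for f in hi} <= lo_keys


@pytest.mark.parametrize("n_taxa_with_gene, expect_hit", [(3, False), (4, True)])
def test_fragment_rule_boundary_three_vs_four_taxa(
        mito_contig, annotations, panel_proteins, truth, n_taxa_with_gene,
        expect_hit):
    """The four-distinct-taxa rule exactly at its boundary: a panel in which
    only 3 taxa carry (and hit) the fragment's gene never annotates it; with
    4 it always does."""
    gene = truth.fragments[0]["gene"]
    full = scan_intergenic_fragments(mito_contig, annotations, panel_proteins,
                                     table4(), seed=0)
    supporting = next(f.supporting_taxa for f in full if f.gene == gene)
    assert len(supporting) >= 4
    reduced = dict(panel_proteins)
    reduced[gene] = {t: panel_proteins[gene][t]
                     for t in supporting[:n_taxa_with_gene]}
    frags = scan_intergenic_fragments(mito_contig, annotations, reduced,
                                      table4(), seed=0)
    hits = [f for f in frags if f.gene == gene]
    assert bool(hits) is expect_hit
    if hits:
        assert hits[0].n_supporting_taxa == 4


def test_random_intergenic_sequence_has_no_fragment_hits(panel_proteins):
    contig = Contig("junk", _random_dna(np.random.default_rng(5), 4000, 0.25))
    assert scan_intergenic_fragments(contig, [], panel_proteins, table4(),
                                     seed=0) == []


# ---------------------------------------------------------------------------
# pseudorepeats
# ---------------------------------------------------------------------------

def _repeat_oracle(seq, unit_len=50, max_mismatch=2):
    """Brute-force all-pairs scan for approximately repeated unit_len-mers."""
    hits = set()
    for i in range(len(seq) - unit_len + 1):
        for j in range(i + unit_len, len(seq) - unit_len + 1):
            mm = sum(a != b for a, b in zip(seq[i:i + unit_len], seq[j:j + unit_len]))
            if mm <= 2 * max_mismatch:
                hits.add(i)
                hits.add(j)
    return hits


def test_planted_three_copy_family_found_and_matches_bruteforce():
    rng = np.random.default_rng(17)
    unit = _random_dna(rng, 50, 0.5)

    def one_mismatch(u):
        p = int(rng.integers(0, len(u)))
        return u[:p] + {"A": "C", "C": "G", "G": "T", "T": "A"}[u[p]] + u[p + 1:]

    seq = (_random_dna(rng, 150, 0.5) + one_mismatch(unit) + _random_dna(rng, 200, 0.5)
           + one_mismatch(unit) + _random_dna(rng, 200, 0.5) + one_mismatch(unit)
           + _random_dna(rng, 150, 0.5))
    fams = detect_pseudorepeats(seq)
    assert len(fams) == 1
    fam = fams[0]
    assert len(fam.occurrences) == 3
    assert fam.max_mismatches_observed <= 2
    assert 40 <= fam.unit_length <= 60
    oracle_positions = _repeat_oracle(seq)
    for s, _e in fam.occurrences:
        assert any(abs(s - p) <= 10 for p in oracle_positions)


def test_exact_tandem_duplication_is_a_zero_mismatch_family():
    rng = np.random.default_rng(18)
    unit = _random_dna(rng, 50, 0.5)
    seq = _random_dna(rng, 80, 0.5) + unit + unit + _random_dna(rng, 80, 0.5)
    fams = detect_pseudorepeats(seq)
    assert len(fams) == 1
    assert len(fams[0].occurrences) == 2
    assert fams[0].max_mismatches_observed == 0


def test_all_distinct_sequence_has_no_family():
    assert detect_pseudorepeats(_random_dna(np.random.default_rng(19), 200, 0.5)) == []


def test_planted_genome_repeats_recovered(mito_contig, truth, default_cfg):
    fams = detect_pseudorepeats(mito_contig.seq,
                                unit_len=default_cfg.repeat_unit_len,
                                max_mismatch=default_cfg.repeat_max_mismatch)
    found = [o[0] for f in fams for o in f.occurrences]
    for r in truth.repeats:
        assert any(abs(s - r["start"]) <= 10 for s in found)
    for fam in fams:
        width = fam.unit_length
        for s, e in fam.occurrences:
            mm = sum(a != b for a, b in zip(mito_contig.seq[s:e], fam.consensus))
            assert mm <= default_cfg.repeat_max_mismatch


# ---------------------------------------------------------------------------
# frameshift repair
# ---------------------------------------------------------------------------

def _frameshift_region(truth, contig):
    fs = truth.frameshift
    region = contig.seq[fs["start"]:fs["end"]]
    if fs["strand"] == "-":
        region = reverse_complement(region)
    return region, fs["cds_pos"]


def test_planted_deletion_repaired_within_window(mito_contig, truth,
                                                 panel_proteins, default_cfg):
    region, d = _frameshift_region(truth, mito_contig)
    ref = panel_consensus(panel_proteins[default_cfg.frameshift_gene])
    calls = repair_single_insertion_frameshift(region, ref, truth.code)
    assert calls
    assert any(c.window[0] <= d < c.window[1] for c in calls)


def test_intact_cds_yields_no_repair_calls(truth, panel_proteins):
    intact = next(g["cds_seq"] for g in truth.genes if g["gene"] == "cob")
    ref = panel_consensus(panel_proteins["cob"])
    assert repair_single_insertion_frameshift(intact, ref, truth.code) == []


def test_two_deletions_cannot_be_fixed_by_one_insertion(truth, panel_proteins):
    intact = next(g["cds_seq"] for g in truth.genes if g["gene"] == "cob")
    broken = intact[:200] + intact[201:800] + intact[801:]
    ref = panel_consensus(panel_proteins["cob"])
    assert repair_single_insertion_frameshift(broken, ref, truth.code) == []


def test_repair_equals_bruteforce_scan_on_small_region(panel_proteins):
    """Exhaustiveness: the module agrees with a literal insert-everywhere scan
    (independent translation + alignment path) on a region under 2 kb."""
    from Bio.Align import PairwiseAligner, substitution_matrices
    from mitocode.codes import translate

    code = table4()
    ref = panel_consensus(panel_proteins["nad3"])  # short gene, small region
    # build a divergent CDS for nad3 from one panel taxon and delete one base
    taxon_prot = list(panel_proteins["nad3"].values())[0]
    from mitocode.codes import back_translate
    cds = back_translate(taxon_prot, code) + "TAA"
    d = 181
    region = cds[:d] + cds[d + 1:]

    calls = repair_single_insertion_frameshift(region, ref, code)
    got = set()
    for c in calls:
        got.update(range(c.window[0], c.window[1]))

    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score, aligner.extend_gap_score = -11, -1
    aligner.mode = "local"

    expected = set()
    for p in range(len(region) + 1):
        cand = region[:p] + "N" + region[p:]
        cand = cand[:3 * (len(cand) // 3)]
        codons = [cand[i:i + 3] for i in range(0, len(cand), 3)]
        # longest run without a hard stop, trailing stop allowed
        runs, cur = [], [0, 0]
        for ci, codon in enumerate(codons + ["TAA"]):
            if ci == len(codons) or ("N" not in codon and code.table.get(codon) == "*"):
                runs.append((cur[0], ci))
                cur = [ci + 1, ci + 1]
        lo, hi = max(runs, key=lambda r: r[1] - r[0])
        if hi - lo < 0.9 * len(ref):
            continue
        prot = translate("".join(codons[lo:hi]), code, "all_stops_as_X").protein
        alns = aligner.align(prot, ref)
        if alns.score < 40:
            continue
        qb, rb = alns[0].aligned
        cols = [(q0 + off, r0 + off) for (q0, q1), (r0, r1) in zip(qb, rb)
                for off in range(q1 - q0)]
        # independent re-derivation of the documented max-identity-core trim
        best_sum = cur = 0.0
        core = None
        start = 0
        for i, (qp, rp) in enumerate(cols):
            cur += (1.0 if prot[qp] == ref[rp] else 0.0) - 0.45
            if cur <= 0:
                cur, start = 0.0, i + 1
            elif cur > best_sum:
                best_sum, core = cur, (start, i + 1)
        if core is None:
            continue
        r_lo, r_hi = cols[core[0]][1], cols[core[1] - 1][1] + 1
        if (r_hi - r_lo) / len(ref) >= 0.9:
            expected.add(p)
    assert got == expected
    assert d in got


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def test_coding_summary_extremes():
    contig = Contig("c", "ATG" * 100)
    full = [_ann("g", 0, 100)]
    assert coding_summary(contig, full)["coding_fraction"] == pytest.approx(1.0)
    assert coding_summary(contig, [])["coding_fraction"] == 0.0


def test_coding_summary_matches_truth_within_two_percent(mito_contig, annotations,
                                                         truth):
    summary = coding_summary(mito_contig, full_gene_annotations(annotations))
    truth_coding = sum(g["end"] - g["start"] for g in truth.genes)
    expected = truth_coding / len(mito_contig.seq)
    assert abs(summary["coding_fraction"] - expected) <= 0.02
    assert summary["gene_order"]
    assert sum(summary["intergenic_lengths"]) + truth_coding == pytest.approx(
        len(mito_contig.seq), rel=0.03)
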