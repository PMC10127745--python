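"""Stop-site mapping, consensus tallies, terminal profiling and the code call."""

from collections import Counter

import pytest

from mitocode.codes import CDSRecord, back_translate, radiolarian_mito_code, table4
from mitocode.pipeline import infer_from_cds
from mitocode.recoding import (DEFAULT_PROPERTY_CLASSES,
                               InferenceParams, StopSite, TallyTable,
                               TerminalProfile, build_gene_msa, column_consensus,
                               infer_code, map_stop_sites, pairwise_stop_profile,
                               stop_placeholder_peptide, tally,
                               terminal_stop_profile, validate_property_classes)


# ---------------------------------------------------------------------------
# column consensus
# ---------------------------------------------------------------------------

def test_consensus_majority_residue():
    cc = column_consensus(list("YYYF"))
    assert cc.aa == "Y" and cc.n_residues == 4


def test_consensus_tie_is_none():
    assert column_consensus(list("YYFF")).aa is None


def test_mostly_gap_column_has_no_consensus():
    cc = column_consensus(list("Y" + "-" * 9))
    assert cc.aa is None
    assert cc.gap_fraction == pytest.approx(0.9)


def test_property_classes_cover_all_amino_acids():
    classes = validate_property_classes(DEFAULT_PROPERTY_CLASSES)
    assert len(classes) == 20
    with pytest.raises(ValueError):
        validate_property_classes({"A": "nonpolar"})


# ---------------------------------------------------------------------------
# MSA threading
# ---------------------------------------------------------------------------

def test_msa_identity_mapping_for_identical_query():
    rows = {f"t{i}": "MKLYWF" for i in range(4)}
    msa = build_gene_msa("g", "MKLYWF", rows)
    assert msa.col_of_codon == list(range(6))
    assert msa.query_row == "MKLYWF"


def test_query_insertion_creates_panel_gap_columns():
    rows = {f"t{i}": "MKLF" for i in range(4)}
    msa = build_gene_msa("g", "MKWWWLF", rows)  # 3-residue insertion
    gap_cols = [c for c in range(msa.n_columns)
                if all(r[c] == "-" for r in msa.panel_rows.values())]
    assert len(gap_cols) == 3
    assert sorted(msa.col_of_codon) == msa.col_of_codon  # monotone, invertible


def test_ragged_panel_is_rejected():
    with pytest.raises(ValueError, match="not aligned"):
        build_gene_msa("g", "MKL", {"a": "MKL", "b": "MK"})


# ---------------------------------------------------------------------------
# stop-site mapping
# ---------------------------------------------------------------------------

def _toy_msa_and_cds(panel_prot, cds_seq, gene="g", n=4):
    cds = CDSRecord(gene=gene, seq=cds_seq)
    pep, _ = stop_placeholder_peptide(cds, table4())
    rows = {f"t{i}": panel_prot for i in range(n)}
    return cds, {(gene, 0): build_gene_msa(gene, pep, rows)}


def test_toy_cds_maps_one_internal_stop():
    cds, msas = _toy_msa_and_cds("MWF", "ATGTGATTTTAA")
    sites = map_stop_sites([cds], msas, table4())
    assert len(sites) == 1
    site = sites[0]
    assert (site.codon, site.codon_index, site.status) == ("TGA", 1, "counted")
    assert site.consensus_aa == "W" and site.property_class == "aromatic"


def test_stop_in_query_insertion_is_excluded_as_gap():
    # query carries an extra stop-containing stretch absent from the panel
    cds, msas = _toy_msa_and_cds("MKLF", "ATGAAATGATTATTT" + "TAA")
    sites = map_stop_sites([cds], msas, table4())
    assert len(sites) == 1
    assert sites[0].status == "excluded_gap"


def test_synthetic_stop_sites_match_planted_counts(truth, panel_proteins):
    sites, tab, _profile, _call, _code, _msas = infer_from_cds(
        truth.cds_records(), panel_proteins, table4())
    for codon in ("TGA", "TAG", "TAA"):
        assert tab.total[codon] == truth.internal_stop_count(codon)


def test_conservation_counted_plus_excluded_equals_total(truth, panel_proteins):
    sites, tab, *_ = infer_from_cds(truth.cds_records(), panel_proteins, table4())
    for codon in ("TGA", "TAG", "TAA"):
        assert tab.counted[codon] + sum(tab.excluded[codon].values()) == tab.total[codon]
    statuses = {s.status for s in sites}
    assert statuses <= {"counted", "excluded_gap", "excluded_sparse",
                        "excluded_no_consensus"}


# ---------------------------------------------------------------------------
# tallies
# ---------------------------------------------------------------------------

def _site(codon, aa, status="counted", gene="g"):
    return StopSite(gene=gene, codon=codon, codon_index=1, alignment_column=1,
                    consensus_aa=aa if status == "counted" else None,
                    property_class=DEFAULT_PROPERTY_CLASSES.get(aa) if status == "counted" else None,
                    status=status)


def test_tally_handcrafted_sites():
    sites = [_site("TGA", "W")] * 8 + [_site("TGA", "L")] * 2
    tab = tally(sites)
    assert tab.by_aa["TGA"] == Counter({"W": 8, "L": 2})
    assert tab.by_class["TGA"] == Counter({"aromatic": 8, "nonpolar": 2})
    assert tab.top_aa("TGA") == ("W", 0.8)


def test_empty_tally_is_all_zero():
    tab = tally([])
    assert all(tab.total[c] == 0 and tab.counted[c] == 0 for c in ("TGA", "TAG", "TAA"))


def test_tally_equals_independent_recount(truth, panel_proteins):
    """The table must equal a direct recount from raw CDSs and MSAs."""
    sites, tab, _p, _c, _g, msas = infer_from_cds(truth.cds_records(),
                                                  panel_proteins, table4())
    recount = {c: Counter() for c in ("TGA", "TAG", "TAA")}
    totals = {c: 0 for c in ("TGA", "TAG", "TAA")}
    for cds in truth.cds_records():
        codons = cds.codons()
        msa = msas[(cds.gene, cds.split_part)]
        for i, codon in enumerate(codons):
            if codon not in ("TGA", "TAG", "TAA") or i == len(codons) - 1:
                continue
            totals[codon] += 1
            col = msa.col_of_codon[i]
            cc = column_consensus([row[col] for row in msa.panel_rows.values()])
            if cc.aa is not None and cc.occupancy >= 0.5:
                recount[codon][cc.aa] += 1
    for codon in ("TGA", "TAG", "TAA"):
        assert tab.total[codon] == totals[codon]
        assert tab.by_aa[codon] == recount[codon]


# ---------------------------------------------------------------------------
# terminal profile
# ---------------------------------------------------------------------------

def _cds_from_protein(protein, terminator="TAA", gene="g"):
    return CDSRecord(gene=gene, seq=back_translate(protein, table4()) + terminator)


def test_all_genes_terminated_by_taa():
    cds_set = [_cds_from_protein("MKLF" * 20, gene=f"g{i}") for i in range(5)]
    prof = terminal_stop_profile(cds_set, {f"g{i}": 80 for i in range(5)})
    assert prof.fraction("TAA") == 1.0
    assert prof.no_terminator == []


def test_runthrough_genes_reported_without_terminator():
    cds_set = [_cds_from_protein("MKLF" * 20, gene=f"g{i}") for i in range(12)]
    for i in (12, 13):  # stop-free genes running into the next ORF
        cds_set.append(CDSRecord(gene=f"g{i}", seq=back_translate("MKLF" * 21, table4())))
    prof = terminal_stop_profile(cds_set, {f"g{i}": 80 for i in range(14)})
    assert prof.fraction("TAA") == pytest.approx(12 / 14)
    assert sorted(prof.no_terminator) == ["g12", "g13"]


def test_zero_window_counts_only_exact_end_terminators():
    short = CDSRecord(gene="g", seq=back_translate("M" + "K" * 59, table4()) + "TAA")
    # reference says the protein should be 80 aa; a stop at 60 is premature
    prof = terminal_stop_profile([short], {"g": 80}, window_frac=0.0)
    assert prof.terminators["g"] is None
    prof2 = terminal_stop_profile([short], {"g": 60}, window_frac=0.0)
    assert prof2.terminators["g"] == "TAA"


# ---------------------------------------------------------------------------
# pairwise profile
# ---------------------------------------------------------------------------

def test_pairwise_profile_handcrafted():
    core = "MKELVDSRGWNQITPHAFCY" * 3
    a = core[:10] + "X" + core[10:20] + "X" + core[20:30] + "X" + core[30:40] + "X" + core[40:]
    b = core[:10] + "Y" + core[10:20] + "F" + core[20:30] + "L" + core[30:40] + core[40:]
    stops = [10, 21, 32, 43]
    prof = pairwise_stop_profile(a, stops, b)
    assert prof.n_internal_stops == 4
    assert prof.aromatic_yfw == 2          # Y and F
    assert prof.hydrophobic == 3           # Y, F and L
    assert prof.gap_excluded == 1          # the fourth X sits opposite a gap


def test_pairwise_profile_no_stops_is_zero():
    prof = pairwise_stop_profile("MKLF", [], "MKLF")
    assert (prof.n_internal_stops, prof.aromatic_yfw, prof.hydrophobic) == (0, 0, 0)


# ---------------------------------------------------------------------------
# the code call
# ---------------------------------------------------------------------------

def _make_tally(counts_by_codon):
    tab = TallyTable()
    for codon, aa_counts in counts_by_codon.items():
        for aa, n in aa_counts.items():
            tab.by_aa[codon][aa] += n
            tab.by_class[codon][DEFAULT_PROPERTY_CLASSES[aa]] += n
            tab.counted[codon] += n
            tab.total[codon] += n
    return tab


def _make_profile(usage):
    return TerminalProfile(usage=usage, n_genes=14, terminators={}, no_terminator=[])


def test_infer_code_recovers_recoded_pattern():
    tab = _make_tally({"TGA": {"W": 20, "L": 1}, "TAG": {"Y": 25},
                       "TAA": {"Y": 3}})
    prof = _make_profile({"TGA": 0.0, "TAG": 0.0, "TAA": 1.0})
    call, code = infer_code(tab, prof)
    assert call.verdicts["TGA"].verdict == "sense" and call.verdicts["TGA"].amino_acid == "W"
    assert call.verdicts["TAG"].verdict == "sense" and call.verdicts["TAG"].amino_acid == "Y"
    assert call.verdicts["TAA"].verdict == "dual_role" and call.verdicts["TAA"].amino_acid == "Y"
    assert code.table["TAG"] == "Y" and code.dual_role == {"TAA"}
    assert code.source == "inferred"


def test_codon_with_no_internal_sites_and_full_terminal_usage_is_stop():
    tab = _make_tally({})
    prof = _make_profile({"TGA": 0.0, "TAG": 0.0, "TAA": 1.0})
    call, code = infer_code(tab, prof)
    assert call.verdicts["TAA"].verdict == "stop"
    assert code.table["TAA"] == "*"
    # no internal evidence and no terminal usage: undecidable, never sense
    assert call.verdicts["TGA"].verdict == "insufficient_data"


def test_contradictory_evidence_is_flagged_not_called():
    # many counted internal sites without a coherent residue, plus heavy
    # terminal usage
    tab = _make_tally({"TAA": {"Y": 3, "L": 3, "K": 2}})
    prof = _make_profile({"TGA": 0.0, "TAG": 0.0, "TAA": 0.9})
    call, _code = infer_code(tab, prof, InferenceParams(min_sites=5))
    v = call.verdicts["TAA"]
    assert v.verdict == "insufficient_data"
    assert v.flags


def test_concatenated_alignment_export_is_gap_free_and_rectangular(truth, panel_proteins):
    from mitocode.recoding import export_concatenated_alignment

    *_, msas = infer_from_cds(truth.cds_records(), panel_proteins, table4())
    whole = {k: m for k, m in msas.items() if k[1] == 0}
    records = export_concatenated_alignment(whole)
    names = [n for n, _s in records]
    assert "query" in names and len(names) == 31  # 30 panel taxa + query
    lengths = {len(s) for _n, s in records}
    assert len(lengths) == 1 and lengths.pop() > 1000
    assert all("-" not in s for _n, s in records)


def test_code_recovery_on_default_synthetic_run(truth, panel_proteins):
    _s, _t, _p, call, inferred, _m = infer_from_cds(truth.cds_records(),
                                                    panel_proteins, table4())
    want = radiolarian_mito_code()
    for codon in ("TGA", "TAG", "TAA"):
        assert inferred.table[codon] == want.table[codon]
    assert inferred.dual_role == want.dual_role
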