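"""Stop-codon reassignment inference from in-frame stop mapping.

The core analysis: every in-frame TGA/TAG/TAA of the query coding sequences
is mapped onto a column of a reference orthologue alignment.  Columns with a
strict >50% consensus among the reference rows vote for what the codon
encodes; columns that are mostly gap, sparsely occupied (alignment ends), or
without a consensus are excluded but accounted for.  Tallies per codon -
by consensus amino acid and by biochemical property class - together with a
terminal-codon usage profile drive the genetic-code call: a stop codon is
declared sense when it recurs at consensus columns of one amino acid and is
not used as a terminator; dual-role when it both terminates most genes and
recurs internally at columns with a coherent consensus; stop otherwise.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field

from ._align import make_overlap_aligner
from .codes import CDSRecord, GeneticCode, STOP, table4

logger = logging.getLogger(__name__)

STOP_TRIPLETS = ("TGA", "TAG", "TAA")

#: biochemical property classes (His grouped with the aromatics); the
#: membership is configuration, not biology fixed by the method
DEFAULT_PROPERTY_CLASSES = {
    **{aa: "aromatic" for aa in "FWYH"},
    **{aa: "charged" for aa in "DEKR"},
    **{aa: "polar" for aa in "STNQC"},
    **{aa: "nonpolar" for aa in "GAVLIPM"},
}

HYDROPHOBIC = set("AVLIMFWYC")


def validate_property_classes(classes: dict) -> dict:
    missing = set("ACDEFGHIKLMNPQRSTVWY") - set(classes)
    if missing:
        raise ValueError(f"property classes missing amino acids: {sorted(missing)}")
    bad = set(classes.values()) - {"nonpolar", "polar", "charged", "aromatic"}
    if bad:
        raise ValueError(f"unknown property classes: {sorted(bad)}")
    return dict(classes)


# ---------------------------------------------------------------------------
# Gene MSAs with codon -> column mapping
# ---------------------------------------------------------------------------

@dataclass
class GeneMSA:
    """Reference alignment of one gene plus the threaded query row.

    ``col_of_codon[i]`` is the alignment column of query codon ``i`` (exact
    and invertible for every non-gap query position); panel rows all have the
    same aligned length as the query row.
    """

    gene: str
    query_row: str
    panel_rows: dict            # taxon -> aligned protein
    col_of_codon: list

    @property
    def n_columns(self) -> int:
        return len(self.query_row)

    def panel_column(self, col: int) -> list:
        return [row[col] for row in self.panel_rows.values()]

    def codon_of_col(self, col: int) -> int | None:
        try:
            return self.col_of_codon.index(col)
        except ValueError:
            return None


def build_gene_msa(gene: str, query_protein: str, panel_rows: dict,
                   aligner=None) -> GeneMSA:
    """Thread a query peptide (internal stops rendered as X) into a
    pre-aligned orthologue set.

    The query is aligned semi-globally against the panel consensus; panel
    columns are preserved, and query residues falling between them become
    insertion columns where every panel row carries a gap.
    """
    from .annotate import panel_consensus

    rows = dict(panel_rows)
    if not rows:
        raise ValueError(f"gene {gene!r}: empty panel")
    widths = {len(s) for s in rows.values()}
    if len(widths) != 1:
        raise ValueError(f"gene {gene!r}: panel rows are not aligned (unequal lengths)")
    consensus = panel_consensus(rows)
    aligner = aligner or make_overlap_aligner()
    try:
        aln = aligner.align(query_protein, consensus)[0]
    except Exception as exc:  # pragma: no cover - aligner failure is exotic
        raise RuntimeError(f"aligner failed for gene {gene!r}: {exc}") from exc
    qblocks, cblocks = aln.aligned

    # walk the alignment, emitting columns; query positions aligned to a
    # consensus position reuse that panel column, unaligned query positions
    # create panel-gap columns, unaligned consensus positions create
    # query-gap columns.
    events = []  # (query_pos or None, cons_pos or None)
    qi, ci = 0, 0
    for (qs, qe), (cs, ce) in zip(qblocks, cblocks):
        while qi < qs:
            events.append((qi, None))
            qi += 1
        while ci < cs:
            events.append((None, ci))
            ci += 1
        for off in range(qe - qs):
            events.append((qs + off, cs + off))
        qi, ci = qe, ce
    while qi < len(query_protein):
        events.append((qi, None))
        qi += 1
    while ci < len(consensus):
        events.append((None, ci))
        ci += 1

    query_row = []
    new_panel: dict = {t: [] for t in rows}
    col_of_codon = [-1] * len(query_protein)
    for col, (qp, cp) in enumerate(events):
        query_row.append(query_protein[qp] if qp is not None else "-")
        if qp is not None:
            col_of_codon[qp] = col
        for taxon, seq in rows.items():
            new_panel[taxon].append(seq[cp] if cp is not None else "-")
    return GeneMSA(
        gene=gene,
        query_row="".join(query_row),
        panel_rows={t: "".join(v) for t, v in new_panel.items()},
        col_of_codon=col_of_codon,
    )


# ---------------------------------------------------------------------------
# Column consensus with exclusion bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class ColumnConsensus:
    aa: str | None
    gap_fraction: float       # internal gaps among rows spanning the column
    occupancy: float          # fraction of rows whose sequence spans the column
    n_residues: int


def _row_spans(panel_rows: dict) -> dict:
    spans = {}
    for taxon, row in panel_rows.items():
        first = next((i for i, c in enumerate(row) if c != "-"), None)
        if first is None:
            spans[taxon] = (0, -1)
        else:
            last = len(row) - 1 - next(i for i, c in enumerate(reversed(row)) if c != "-")
            spans[taxon] = (first, last)
    return spans


def column_consensus(column_residues: list, threshold: float = 0.5,
                     n_spanning: int | None = None, n_total: int | None = None) -> ColumnConsensus:
    """Strict >``threshold`` consensus over non-gap residues of a column.

    ``column_residues`` are the panel residues of rows spanning the column
    (gaps included as '-'); the query row never votes.  ``n_spanning`` /
    ``n_total`` give occupancy context (default: all rows span).
    """
    residues = [c for c in column_residues if c != "-"]
    n_span = n_spanning if n_spanning is not None else len(column_residues)
    n_tot = n_total if n_total is not None else len(column_residues)
    occupancy = n_span / n_tot if n_tot else 0.0
    gap_fraction = 1 - (len(residues) / n_span) if n_span else 1.0
    aa = None
    if residues:
        counts = Counter(residues).most_common()
        top_aa, top_n = counts[0]
        unique = len(counts) == 1 or counts[1][1] < top_n
        if unique and top_n / len(residues) > threshold:
            aa = top_aa
    if n_tot and len(residues) / n_tot < 0.5:
        aa = None  # majority of panel rows not present: no usable consensus
    return ColumnConsensus(aa, gap_fraction, occupancy, len(residues))


# ---------------------------------------------------------------------------
# Stop-site mapping and tallies
# ---------------------------------------------------------------------------

@dataclass
class StopSite:
    gene: str
    codon: str
    codon_index: int
    alignment_column: int
    consensus_aa: str | None
    property_class: str | None
    status: str               # counted | excluded_gap | excluded_sparse |
                              # excluded_no_consensus
    split_part: int = 0


def stop_placeholder_peptide(cds: CDSRecord, code: GeneticCode) -> tuple:
    """Peptide for alignment with every standard stop triplet rendered as X.

    The three triplets are placeholdered regardless of what ``code`` reads
    them as, so the aligner is not biased toward any candidate amino acid
    and the peptide is the same whichever baseline code is searched with.
    Returns ``(peptide, internal_stop_indices)``; a terminal terminator
    (stop triplet or STOP-valued codon in last position) is dropped, keeping
    peptide index == codon index everywhere else.
    """
    codons = cds.codons()
    last = len(codons) - 1
    peptide: list = []
    internal: list = []
    for i, codon in enumerate(codons):
        is_triplet = codon in STOP_TRIPLETS
        if i == last and (is_triplet or ("N" not in codon and code.table[codon] == STOP)):
            break
        if is_triplet:
            internal.append(i)
            peptide.append("X")
        elif "N" in codon:
            peptide.append("X")
        else:
            aa = code.table[codon]
            peptide.append("X" if aa == STOP else aa)
    return "".join(peptide), internal


def map_stop_sites(cds_set: list, msas: dict, code: GeneticCode,
                   classes: dict | None = None, threshold: float = 0.5,
                   min_occupancy: float = 0.5) -> list:
    """One :class:`StopSite` per internal TGA/TAG/TAA of every CDS.

    The terminal terminator codon is excluded.  Exclusion rules: columns
    spanned by fewer than ``min_occupancy`` of panel rows (alignment
    beginnings/ends) are ``excluded_sparse``; columns where most spanning
    rows carry a gap are ``excluded_gap``; columns without a strict majority
    consensus are ``excluded_no_consensus``; the rest are ``counted``.
    """
    classes = validate_property_classes(classes or DEFAULT_PROPERTY_CLASSES)
    sites: list = []
    for cds in cds_set:
        key = (cds.gene, cds.split_part)
        msa = msas.get(key) or msas.get(cds.gene)
        if msa is None:
            raise KeyError(f"no MSA for CDS {cds.gene!r} (part {cds.split_part})")
        spans = _row_spans(msa.panel_rows)
        n_rows = len(msa.panel_rows)
        codons = cds.codons()
        _pep, internal = stop_placeholder_peptide(cds, code)
        for i in internal:
            codon = codons[i]
            col = msa.col_of_codon[i]
            spanning = [t for t, (f, l) in spans.items() if f <= col <= l]
            residues = [msa.panel_rows[t][col] for t in spanning]
            cc = column_consensus(residues, threshold=threshold,
                                  n_spanning=len(spanning), n_total=n_rows)
            if cc.occupancy < min_occupancy:
                status, aa = "excluded_sparse", None
            elif cc.gap_fraction > 0.5 or (cc.n_residues == 0):
                status, aa = "excluded_gap", None
            elif cc.aa is None:
                status, aa = "excluded_no_consensus", None
            else:
                status, aa = "counted", cc.aa
            sites.append(StopSite(
                gene=cds.gene, codon=codon, codon_index=i, alignment_column=col,
                consensus_aa=aa,
                property_class=classes.get(aa) if aa else None,
                status=status, split_part=cds.split_part,
            ))
    return sites


@dataclass
class TallyTable:
    """Per-codon aggregation of counted stop sites (the figure-style table)."""

    total: dict = field(default_factory=lambda: {c: 0 for c in STOP_TRIPLETS})
    counted: dict = field(default_factory=lambda: {c: 0 for c in STOP_TRIPLETS})
    excluded: dict = field(default_factory=lambda: {c: Counter() for c in STOP_TRIPLETS})
    by_aa: dict = field(default_factory=lambda: {c: Counter() for c in STOP_TRIPLETS})
    by_class: dict = field(default_factory=lambda: {c: Counter() for c in STOP_TRIPLETS})

    def top_aa(self, codon: str):
        """(amino acid, fraction of counted) of the unique most frequent
        consensus residue, or (None, 0.0)."""
        counts = self.by_aa[codon].most_common()
        if not counts or self.counted[codon] == 0:
            return None, 0.0
        aa, n = counts[0]
        if len(counts) > 1 and counts[1][1] == n:
            return None, 0.0
        return aa, n / self.counted[codon]

    def to_frame(self):
        import pandas as pd

        rows = []
        for codon in STOP_TRIPLETS:
            row = {"codon": codon, "total_internal": self.total[codon],
                   "counted": self.counted[codon]}
            row.update({f"aa_{aa}": n for aa, n in sorted(self.by_aa[codon].items())})
            row.update({f"class_{c}": n for c, n in sorted(self.by_class[codon].items())})
            row.update({k: v for k, v in sorted(self.excluded[codon].items())})
            rows.append(row)
        return pd.DataFrame(rows).fillna(0)


def tally(stop_sites: list, classes: dict | None = None) -> TallyTable:
    """Aggregate counted sites per codon by consensus residue and property
    class; totals and exclusions are preserved so that
    counted + sum(excluded) == total internal occurrences, per codon."""
    classes = validate_property_classes(classes or DEFAULT_PROPERTY_CLASSES)
    table = TallyTable()
    for site in stop_sites:
        if site.codon not in STOP_TRIPLETS:
            continue
        table.total[site.codon] += 1
        if site.status == "counted":
            table.counted[site.codon] += 1
            table.by_aa[site.codon][site.consensus_aa] += 1
            table.by_class[site.codon][classes[site.consensus_aa]] += 1
        else:
            table.excluded[site.codon][site.status] += 1
    return table


def export_concatenated_alignment(msas: dict, query_name: str = "query") -> list:
    """Concatenated trimmed protein alignment for external phylogenetics.

    Per-gene MSAs (panel rows + query row) are concatenated over the taxa
    shared by all genes; columns containing any gap are dropped, as is usual
    before concatenated-matrix tree inference.  Returns ``(name, sequence)``
    tuples ready for FASTA export.
    """
    msa_list = list(msas.values())
    if not msa_list:
        raise ValueError("no MSAs to export")
    taxa = set(msa_list[0].panel_rows)
    for msa in msa_list[1:]:
        taxa &= set(msa.panel_rows)
    if not taxa:
        raise ValueError("no taxa shared by all gene alignments")
    names = sorted(taxa) + [query_name]
    parts = {n: [] for n in names}
    for msa in msa_list:
        rows = [msa.panel_rows[t] for t in sorted(taxa)] + [msa.query_row]
        for col in range(msa.n_columns):
            column = [r[col] for r in rows]
            if "-" in column:
                continue
            for n, c in zip(names, column):
                parts[n].append(c)
    return [(n, "".join(parts[n])) for n in names]


# ---------------------------------------------------------------------------
# Terminal codon usage
# ---------------------------------------------------------------------------

@dataclass
class TerminalProfile:
    usage: dict               # codon -> fraction of genes it terminates
    n_genes: int
    terminators: dict         # gene key -> codon or None
    no_terminator: list       # gene keys lacking any terminator near the end

    def fraction(self, codon: str) -> float:
        return self.usage.get(codon, 0.0)


def terminal_stop_profile(cds_set: list, ref_lengths: dict,
                          window_frac: float = 0.1) -> dict:
    """Which codon terminates each gene, near the predicted protein end.

    A CDS's terminator is its final codon, provided that codon is a stop
    triplet lying at a reference-relative position >=
    ``(1 - window_frac) * ref_length`` (i.e. near where homology predicts
    the protein to end).  A stop triplet that is merely *internal* - even
    one inside the window - terminates nothing and is never attributed
    here; recoded sense codons near the 3' end would otherwise masquerade
    as terminators.  Genes whose frame runs through into downstream
    sequence are reported separately.
    """
    terminators: dict = {}
    for cds in cds_set:
        key = (cds.gene, cds.split_part) if cds.split_part else cds.gene
        ref_len = ref_lengths.get(cds.gene, cds.n_codons)
        if cds.split_part:
            # a split part's own length is the relevant scale for its end
            ref_len = cds.n_codons
        cutoff = (1 - window_frac) * ref_len - 1e-9
        codons = cds.codons()
        found = None
        if codons and codons[-1] in STOP_TRIPLETS and len(codons) - 1 >= cutoff:
            found = codons[-1]
        terminators[key] = found
    n = len(terminators)
    usage = {c: (sum(1 for v in terminators.values() if v == c) / n if n else 0.0)
             for c in STOP_TRIPLETS}
    return TerminalProfile(
        usage=usage, n_genes=n, terminators=terminators,
        no_terminator=[k for k, v in terminators.items() if v is None],
    )


# ---------------------------------------------------------------------------
# Pairwise stop profile
# ---------------------------------------------------------------------------

@dataclass
class PairwiseStopProfile:
    n_internal_stops: int
    aromatic_yfw: int         # opposite Y, F or W
    hydrophobic: int          # opposite the hydrophobic set
    gap_excluded: int


def pairwise_stop_profile(protein_a: str, stops_a: list, protein_b: str,
                          hydrophobic: set | None = None, aligner=None) -> PairwiseStopProfile:
    """Count where the internal stops of protein A land in a pairwise
    alignment with protein B.

    ``protein_a`` carries X placeholders at its internal stops; ``stops_a``
    are their residue indices.  Stops aligned to a gap in B are excluded from
    both numerators and reported separately.
    """
    hydrophobic = hydrophobic if hydrophobic is not None else HYDROPHOBIC
    aligner = aligner or make_overlap_aligner()
    aln = aligner.align(protein_a, protein_b)[0]
    ablocks, bblocks = aln.aligned
    partner = {}
    for (a0, a1), (b0, b1) in zip(ablocks, bblocks):
        for off in range(a1 - a0):
            partner[a0 + off] = protein_b[b0 + off]
    yfw = hyd = gaps = 0
    for i in stops_a:
        res = partner.get(i)
        if res is None:
            gaps += 1
        else:
            if res in "YFW":
                yfw += 1
            if res in hydrophobic:
                hyd += 1
    return PairwiseStopProfile(len(stops_a), yfw, hyd, gaps)


# ---------------------------------------------------------------------------
# The code call
# ---------------------------------------------------------------------------

@dataclass
class InferenceParams:
    min_sites: int = 5        # counted sites needed for a sense call
    f_sense: float = 0.5      # top-aa fraction of counted needed for sense
    t_stop: float = 0.2       # terminal usage at/above which a codon is a terminator
    min_dual: int = 2         # counted sites needed for a dual-role call


@dataclass
class CodonVerdict:
    codon: str
    verdict: str              # sense | stop | dual_role | insufficient_data
    amino_acid: str | None
    counted: int
    top_aa_fraction: float
    terminal_fraction: float
    flags: list = field(default_factory=list)


@dataclass
class CodeCall:
    verdicts: dict            # codon -> CodonVerdict

    def to_json(self) -> str:
        return json.dumps({
            c: {
                "verdict": v.verdict, "amino_acid": v.amino_acid,
                "counted": v.counted, "top_aa_fraction": round(v.top_aa_fraction, 4),
                "terminal_fraction": round(v.terminal_fraction, 4), "flags": v.flags,
            } for c, v in self.verdicts.items()
        }, indent=2)


def infer_code(tally_table: TallyTable, terminal_profile: TerminalProfile,
               params: InferenceParams | None = None,
               baseline: GeneticCode | None = None) -> tuple:
    """Call each stop codon sense / stop / dual-role from the evidence.

    Per codon: *sense(aa)* when it recurs at counted consensus columns
    (>= ``min_sites``) with a coherent top residue and is rarely terminal;
    *dual_role(aa)* when it is the common terminator yet also recurs
    internally (>= ``min_dual`` counted) with a coherent top residue;
    *stop* when it terminates genes and shows (almost) no counted internal
    sites; anything contradictory is flagged ``insufficient_data`` rather
    than silently called.  Returns ``(CodeCall, GeneticCode)`` where the code
    overlays the verdicts on the baseline (translation table 4 by default;
    an insufficient-data codon keeps its baseline meaning).
    """
    params = params or InferenceParams()
    baseline = baseline or table4()
    verdicts = {}
    overrides = {}
    dual = set()
    for codon in STOP_TRIPLETS:
        counted = tally_table.counted[codon]
        top_aa, top_frac = tally_table.top_aa(codon)
        term = terminal_profile.fraction(codon)
        flags: list = []
        if term >= params.t_stop:
            if counted >= params.min_dual and top_aa is not None and top_frac >= 0.5:
                verdict, aa = "dual_role", top_aa
            elif counted < params.min_sites:
                verdict, aa = "stop", None
            else:
                verdict, aa = "insufficient_data", None
                flags.append("high_internal_and_terminal_with_incoherent_consensus")
        else:
            if counted >= params.min_sites and top_aa is not None and top_frac >= params.f_sense:
                verdict, aa = "sense", top_aa
            else:
                verdict, aa = "insufficient_data", None
                if counted < params.min_sites:
                    flags.append("too_few_counted_sites")
                else:
                    flags.append("no_coherent_consensus")
        verdicts[codon] = CodonVerdict(codon, verdict, aa, counted, top_frac, term, flags)
        if verdict == "sense":
            overrides[codon] = aa
        elif verdict == "stop":
            overrides[codon] = STOP
        elif verdict == "dual_role":
            overrides[codon] = aa
            dual.add(codon)
    code = baseline.with_overrides("inferred", overrides, dual_role=dual, source="inferred")
    return CodeCall(verdicts), code
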