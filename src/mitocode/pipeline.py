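"""End-to-end orchestration: recovery -> annotation -> code inference.

Stages are independently skippable given their inputs; every run writes a
machine-readable ``report.json`` with per-stage provenance (parameters, seed,
input digests) next to the standard-format outputs (blob table TSV, GFF3,
presence/absence TSV, tally TSV, stop-site TSV, code-call and genetic-code
JSON).  Identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotate as ann_mod
from . import io as mio
from . import recoding as rec_mod
from . import recovery as cov_mod
from .codes import CDSRecord, GeneticCode, table4

logger = logging.getLogger(__name__)

STOP_TRIPLETS = rec_mod.STOP_TRIPLETS


@dataclass
class PipelineConfig:
    contigs: str | None = None
    reads1: str | None = None
    reads2: str | None = None
    panel_dir: str | None = None
    out_dir: str = "mitocode_out"
    seed: int = 0
    search_code: GeneticCode = field(default_factory=table4)
    min_score: float = 80.0
    fragment_min_taxa: int = 4
    inference: rec_mod.InferenceParams = field(default_factory=rec_mod.InferenceParams)
    do_recovery: bool = True
    do_annotation: bool = True
    do_inference: bool = True
    repair_frameshifts: bool = True
    detect_repeats: bool = True

    def validate(self):
        if self.contigs is None:
            raise ValueError("contigs FASTA is required")
        for p in (self.contigs, self.reads1, self.reads2):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if (self.do_annotation or self.do_inference) and self.panel_dir is None:
            raise ValueError("a reference panel directory is required for "
                             "annotation and code inference")
        if self.panel_dir is not None and not Path(self.panel_dir).exists():
            raise FileNotFoundError(self.panel_dir)


def _ensure_aligned(panel: dict) -> dict:
    """Panels must be per-gene alignments; equal-length rows pass through,
    ragged rows are aligned with mafft when available."""
    out = {}
    for gene, by_taxon in panel.items():
        widths = {len(s) for s in by_taxon.values()}
        if len(widths) == 1:
            out[gene] = by_taxon
            continue
        out[gene] = _mafft_align(gene, by_taxon)
    return out


def _mafft_align(gene: str, by_taxon: dict) -> dict:
    import shutil
    import subprocess
    import tempfile

    if shutil.which("mafft") is None:
        raise RuntimeError(
            f"panel for gene {gene!r} is unaligned and mafft is not on PATH")
    with tempfile.NamedTemporaryFile("w", suffix=".fa", delete=False) as fh:
        for t, s in by_taxon.items():
            fh.write(f">{t}\n{s}\n")
        tmp = fh.name
    res = subprocess.run(["mafft", "--auto", "--quiet", tmp],
                         capture_output=True, text=True, check=True)
    aligned = {}
    name = None
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            aligned[name] = ""
        elif name:
            aligned[name] += line.strip().upper()
    return aligned


def extract_cds(contig: cov_mod.Contig, annotation, max_extend_codons: int = 20,
                back_codons: int = 12) -> CDSRecord:
    """Cut an in-frame CDS from the contig at an annotation.

    The terminator is rarely inside the aligned span, and alignment boundary
    fuzz can overshoot a few codons into intergenic junk, so the 3' end is
    re-anchored on the first in-frame stop triplet found from ``back_codons``
    before the annotation end up to ``max_extend_codons`` past it (the stop
    codon is kept in the record).  Without a stop in that window the record
    ends at the annotation end (a run-through gene).
    """
    from Bio.Seq import reverse_complement

    seq = contig.seq
    s, e = annotation.start, annotation.end
    if annotation.strand == "+":
        cds = seq[s:e]
        ext_src = seq[e:e + 3 * max_extend_codons]
    else:
        cds = reverse_complement(seq[s:e])
        ext_src = reverse_complement(seq[max(0, s - 3 * max_extend_codons):s])
    cds = cds[: 3 * (len(cds) // 3)]
    joint = cds + ext_src[: 3 * (len(ext_src) // 3)]
    n_codons = len(cds) // 3
    stops = [ci for ci in range(max(0, n_codons - back_codons), len(joint) // 3)
             if joint[3 * ci: 3 * ci + 3] in STOP_TRIPLETS]
    if stops:
        # the terminator is the stop nearest the homology-predicted end;
        # recoded sense stops further inside and chance stops further out
        # both lose to it
        stop_at = min(stops, key=lambda ci: (abs(ci - n_codons), -ci))
        cds = joint[: 3 * (stop_at + 1)]
    if annotation.strand == "+":
        s2, e2 = s, s + len(cds)
    else:
        s2, e2 = e - len(cds), e
    return CDSRecord(gene=annotation.gene, seq=cds, contig_id=annotation.contig_id,
                     start=s2, end=e2, strand=annotation.strand,
                     split_part=annotation.split_part)


def infer_from_cds(cds_set: list, panel: dict, code_for_stops: GeneticCode | None = None,
                   params: rec_mod.InferenceParams | None = None,
                   classes: dict | None = None):
    """Library-level core: CDSs + aligned panel -> (stop sites, tally,
    terminal profile, CodeCall, inferred GeneticCode, MSAs)."""
    code_for_stops = code_for_stops or table4()
    msas = {}
    for cds in cds_set:
        prot, _internal = rec_mod.stop_placeholder_peptide(cds, code_for_stops)
        msas[(cds.gene, cds.split_part)] = rec_mod.build_gene_msa(
            cds.gene, prot, panel[cds.gene])
    sites = rec_mod.map_stop_sites(cds_set, msas, code_for_stops, classes=classes)
    tab = rec_mod.tally(sites, classes=classes)
    ref_lengths = {g: len(ann_mod.panel_consensus(by_t)) for g, by_t in panel.items()}
    profile = rec_mod.terminal_stop_profile(cds_set, ref_lengths)
    call, inferred = rec_mod.infer_code(tab, profile, params=params)
    return sites, tab, profile, call, inferred, msas


def export_presence_matrix(annotations_by_species: dict, genes: list | None = None) -> pd.DataFrame:
    """Gene x species matrix with cells in {present, fragment, absent}.

    ``annotations_by_species`` maps species -> (gene annotations, fragment
    hits); fragments count as half-presence.
    """
    if not annotations_by_species:
        raise ValueError("no annotated species")
    all_genes = set(genes or [])
    for anns, frags in annotations_by_species.values():
        all_genes.update(a.gene for a in anns)
        all_genes.update(f.gene for f in frags)
    rows = {}
    for gene in sorted(all_genes):
        row = {}
        for sp, (anns, frags) in annotations_by_species.items():
            if any(a.gene == gene for a in anns):
                row[sp] = "present"
            elif any(f.gene == gene for f in frags):
                row[sp] = "fragment"
            else:
                row[sp] = "absent"
        rows[gene] = row
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene")


def _gff_features(annotations, fragments, repeats, frameshift_calls):
    feats = []
    for a in annotations:
        attrs = {"ID": f"{a.gene}.{a.start}", "Name": a.gene,
                 "reference_coverage": f"{a.coverage_of_reference:.3f}"}
        if a.split_part:
            attrs["part"] = str(a.split_part)
        feats.append({"seqid": a.contig_id, "type": "gene", "start": a.start,
                      "end": a.end, "score": a.score, "strand": a.strand,
                      "attributes": attrs})
    for fhit in fragments:
        feats.append({"seqid": fhit.contig_id, "type": "pseudogene_fragment",
                      "start": fhit.start, "end": fhit.end, "score": fhit.mean_score,
                      "attributes": {"Name": fhit.gene,
                                     "supporting_taxa": str(fhit.n_supporting_taxa)}})
    for contig_id, fam_i, (s, e) in repeats:
        feats.append({"seqid": contig_id, "type": "repeat_region", "start": s,
                      "end": e, "attributes": {"family": str(fam_i)}})
    for contig_id, call in frameshift_calls:
        feats.append({"seqid": contig_id, "type": "frameshift", "start": call.position,
                      "end": call.position + 1, "score": call.score,
                      "attributes": {"Name": call.gene or "unknown",
                                     "window": f"{call.window[0]}-{call.window[1]}"}})
    feats.sort(key=lambda f: (f["seqid"], f["start"], f["type"]))
    return feats


def run_pipeline(config: PipelineConfig) -> dict:
    """Run recovery -> annotation -> inference and write the report bundle."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "inputs": {},
        "parameters": {
            "min_score": config.min_score,
            "fragment_min_taxa": config.fragment_min_taxa,
            "inference": dataclasses.asdict(config.inference),
        },
        "stages": {},
    }
    for key in ("contigs", "reads1", "reads2"):
        p = getattr(config, key)
        if p:
            report["inputs"][key] = {"path": str(p), "sha256": mio.sha256_of(p)}

    contigs = [cov_mod.Contig(cid, seq) for cid, seq in mio.read_fasta(config.contigs)]
    if not contigs:
        raise ValueError("contig input is empty")
    panel = None
    if config.panel_dir:
        panel = _ensure_aligned(mio.read_panel_dir(config.panel_dir))

    reads = []
    if config.reads1:
        reads = mio.read_fastq(config.reads1)
        if config.reads2:
            reads += mio.read_fastq(config.reads2)

    # ---- recovery -----------------------------------------------------
    mito_contigs = contigs
    if config.do_recovery:
        if panel is None:
            raise ValueError("recovery requires a reference panel")
        if reads:
            cov_mod.contig_stats(contigs, reads)
        else:
            for c in contigs:
                if c.coverage is None:
                    c.coverage = 0.0
        seeds = cov_mod.seed_mito_contigs(contigs, panel, code=config.search_code,
                                          min_score=config.min_score)
        if seeds:
            labels = cov_mod.blob_classify(contigs, seeds)
        else:
            labels = {c.id: "other" for c in contigs}
        table = cov_mod.blob_table(contigs, labels)
        table.to_csv(out / "blob_table.tsv", sep="\t", index=False)
        mito_contigs = [c for c in contigs if labels[c.id] == "mito"]
        mio.write_fasta([(c.id, c.seq) for c in mito_contigs], out / "mito_contigs.fasta")
        report["stages"]["recovery"] = {
            "n_contigs": len(contigs), "n_mito": len(mito_contigs),
            "seed_contigs": sorted(seeds),
        }
        if not mito_contigs:
            logger.info("no mitochondrial contigs identified; stopping")
            report["status"] = "no_mito_contigs"
            _write_report(report, out)
            return report

    # ---- annotation ---------------------------------------------------
    annotations: list = []
    fragments: list = []
    repeat_feats: list = []
    frameshift_calls: list = []
    if config.do_annotation:
        for contig in mito_contigs:
            anns = ann_mod.annotate_by_homology(contig, panel, config.search_code,
                                                min_score=config.min_score)
            anns = ann_mod.detect_split_genes(anns)
            annotations.extend(anns)
            fragments.extend(ann_mod.scan_intergenic_fragments(
                contig, anns, panel, config.search_code,
                min_taxa=config.fragment_min_taxa, seed=config.seed))
            if config.detect_repeats:
                for fam_i, fam in enumerate(ann_mod.detect_pseudorepeats(contig.seq)):
                    for occ in fam.occurrences:
                        repeat_feats.append((contig.id, fam_i, occ))
            if config.repair_frameshifts:
                frameshift_calls.extend(_scan_frameshifts(contig, anns, panel,
                                                          config.search_code))
        mio.write_gff3(_gff_features(annotations, fragments, repeat_feats,
                                     frameshift_calls), out / "annotations.gff3")
        matrix = export_presence_matrix(
            {"query": (ann_mod.full_gene_annotations(annotations), fragments)},
            genes=sorted(panel))
        matrix.to_csv(out / "presence_matrix.tsv", sep="\t")
        summary = [ann_mod.coding_summary(c, [a for a in annotations if a.contig_id == c.id])
                   for c in mito_contigs]
        (out / "coding_summary.json").write_text(json.dumps(summary, indent=2, default=str))
        report["stages"]["annotation"] = {
            "n_genes": len({(a.gene) for a in annotations}),
            "n_annotations": len(annotations),
            "n_fragments": len(fragments),
            "n_repeat_occurrences": len(repeat_feats),
            "n_frameshift_calls": len(frameshift_calls),
        }

    # ---- inference ----------------------------------------------------
    if config.do_inference:
        if not annotations:
            raise ValueError("code inference requires gene annotations")
        by_contig = {c.id: c for c in mito_contigs}
        cds_set = [extract_cds(by_contig[a.contig_id], a)
                   for a in ann_mod.full_gene_annotations(annotations)]
        sites, tab, profile, call, inferred, msas = infer_from_cds(
            cds_set, panel, code_for_stops=config.search_code, params=config.inference)
        tab.to_frame().to_csv(out / "stop_tally.tsv", sep="\t", index=False)
        whole_gene_msas = {k: m for k, m in msas.items() if k[1] == 0}
        if whole_gene_msas:  # split genes are excluded from the concatenation
            mio.write_fasta(rec_mod.export_concatenated_alignment(whole_gene_msas),
                            out / "concat_alignment.fasta")
        pd.DataFrame([dataclasses.asdict(s) for s in sites]).to_csv(
            out / "stop_sites.tsv", sep="\t", index=False)
        (out / "code_call.json").write_text(call.to_json())
        (out / "inferred_code.json").write_text(inferred.to_json())
        report["stages"]["inference"] = {
            "n_cds": len(cds_set),
            "verdicts": {c: v.verdict for c, v in call.verdicts.items()},
            "amino_acids": {c: v.amino_acid for c, v in call.verdicts.items()},
            "terminal_usage": profile.usage,
        }

    report["status"] = "ok"
    _write_report(report, out)
    return report


def _scan_frameshifts(contig, annotations, panel, code) -> list:
    """Heuristic frameshift screen: two nearby same-gene annotations in
    different frames trigger an exhaustive single-insertion repair of the
    joint region."""
    calls = []
    by_gene: dict = {}
    for a in annotations:
        by_gene.setdefault(a.gene, []).append(a)
    for gene, anns in by_gene.items():
        if len(anns) < 2:
            continue
        anns = sorted(anns, key=lambda a: a.start)
        for a, b in zip(anns, anns[1:]):
            if a.strand != b.strand or b.start - a.end > 200:
                continue
            if (a.frame, a.strand) == (b.frame, b.strand):
                continue
            lo, hi = a.start, b.end
            region = contig.seq[lo:hi]
            if a.strand == "-":
                from Bio.Seq import reverse_complement
                region = reverse_complement(region)
            ref = ann_mod.panel_consensus(panel[gene])
            for call in ann_mod.repair_single_insertion_frameshift(region, ref, code):
                call.gene = gene
                calls.append((contig.id, call))
    return calls


def _write_report(report: dict, out: Path) -> None:
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
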