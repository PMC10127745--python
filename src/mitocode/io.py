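"""Reading and writing of the standard formats used by the pipeline.

Reading goes through Biopython's SeqIO; writers are deliberately minimal and
byte-stable (fixed wrapping, fixed field order) so that identical runs
produce identical files.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO


def read_fasta(path) -> list:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def read_fastq(path) -> list:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fasta(records: Iterable, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_fastq_pair(pairs: Iterable, path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{'I' * len(p.seq1)}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{'I' * len(p.seq2)}\n")


def read_panel_dir(panel_dir) -> dict:
    """Per-gene orthologue FASTAs (``<gene>.faa`` / ``<gene>.fasta``) ->
    {gene: {taxon: protein}}."""
    panel = {}
    for path in sorted(Path(panel_dir).iterdir()):
        if path.suffix.lower() not in (".fa", ".faa", ".fasta"):
            continue
        gene = path.stem
        panel[gene] = {rid: seq for rid, seq in read_fasta(path)}
    if not panel:
        raise FileNotFoundError(f"no per-gene FASTA files in {panel_dir}")
    return panel


def write_panel_dir(panel_proteins: Mapping, panel_dir) -> None:
    panel_dir = Path(panel_dir)
    panel_dir.mkdir(parents=True, exist_ok=True)
    for gene, by_taxon in sorted(panel_proteins.items()):
        write_fasta(sorted(by_taxon.items()), panel_dir / f"{gene}.faa")


def write_gff3(features: Iterable, path) -> None:
    """Write features as GFF3 (1-based inclusive coordinates).

    Each feature is a dict with keys seqid, source, type, start, end
    (0-based half-open, converted here), score, strand, frame, attributes
    (dict).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.get("attributes", {}).items())
            score = f.get("score")
            fh.write("\t".join([
                f["seqid"], f.get("source", "mitocode"), f["type"],
                str(f["start"] + 1), str(f["end"]),
                f"{score:.1f}" if score is not None else ".",
                f.get("strand", "."), str(f.get("frame", ".")), attrs or ".",
            ]) + "\n")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
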