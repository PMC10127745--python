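"""Genetic-code representation, translation with stop-readthrough policies,
and ORF finding under arbitrary codes.

A :class:`GeneticCode` is a complete 64-codon table mapping DNA triplets to
amino acids or ``*`` (STOP), optionally with *dual-role* codons: triplets that
are read as a sense amino acid inside a coding sequence but act as the
terminator at its end.  Dual-role codons are the signature of ambiguous
stop-codon reassignment (e.g. TAA = Tyr/stop in radiolarian mitochondria,
TAA/TAG = Gln/stop in *Blastocrithidia* nuclei).

Preset codes are built from Biopython's NCBI codon tables rather than
hard-coded; the recoded radiolarian-style mitochondrial code is derived from
translation table 4 by reassigning TGA->W (already W in table 4), TAG->Y and
TAA->Y with TAA kept as a dual-role terminator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio.Data import CodonTable as _NCBICodonTable
from Bio.Seq import reverse_complement

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"
DNA_BASES = "ACGT"
CODONS = tuple(a + b + c for a in DNA_BASES for b in DNA_BASES for c in DNA_BASES)

#: readthrough policies accepted by :func:`translate`
POLICIES = ("none", "dual_role_internal", "all_stops_as_X")


class CodeError(ValueError):
    """Raised for invalid genetic codes or untranslatable sequences."""


@dataclass(frozen=True)
class GeneticCode:
    """A 64-codon genetic code with optional dual-role terminators.

    Parameters
    ----------
    name : str
        Short label, e.g. ``"table4"``.
    table : mapping
        Map from each of the 64 DNA codons to a one-letter amino acid or
        ``"*"`` for STOP.
    dual_role : frozenset of str
        Codons whose table value is a sense amino acid internally but which
        terminate translation when they occur at the end of a CDS.
    source : str
        ``"preset"`` or ``"inferred"``.
    """

    name: str
    table: Mapping[str, str]
    dual_role: frozenset = field(default_factory=frozenset)
    source: str = "preset"

    def __post_init__(self):
        table = dict(self.table)
        if sorted(table) != sorted(CODONS):
            missing = set(CODONS) - set(table)
            extra = set(table) - set(CODONS)
            raise CodeError(
                f"code {self.name!r} must have exactly the 64 DNA codons "
                f"(missing={sorted(missing)!r}, extra={sorted(extra)!r})"
            )
        bad = {c: v for c, v in table.items() if v != STOP and v not in AMINO_ACIDS}
        if bad:
            raise CodeError(f"code {self.name!r} has invalid values: {bad!r}")
        dual = frozenset(self.dual_role)
        object.__setattr__(self, "dual_role", dual)
        not_sense = [c for c in dual if table.get(c) == STOP or c not in table]
        if not_sense:
            raise CodeError(
                f"dual-role codons must map to a sense amino acid: {sorted(not_sense)!r}"
            )
        if not self.stop_codons and not dual:
            raise CodeError(f"code {self.name!r} has no terminator codon")
        object.__setattr__(self, "table", table)

    # -- queries ---------------------------------------------------------
    @property
    def stop_codons(self) -> frozenset:
        """Codons whose table value is STOP (dual-role codons excluded)."""
        return frozenset(c for c, v in self.table.items() if v == STOP)

    @property
    def terminators(self) -> frozenset:
        """All codons that can terminate a CDS: STOP-valued plus dual-role."""
        return self.stop_codons | self.dual_role

    def is_terminator(self, codon: str) -> bool:
        return codon in self.terminators

    def synonymous_codons(self, aa: str) -> list:
        """Sense codons encoding ``aa`` (dual-role codons included)."""
        return [c for c, v in self.table.items() if v == aa]

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "table": {c: self.table[c] for c in CODONS},
                "dual_role": sorted(self.dual_role),
                "source": self.source,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GeneticCode":
        doc = json.loads(text)
        return cls(
            name=doc["name"],
            table=doc["table"],
            dual_role=frozenset(doc.get("dual_role", [])),
            source=doc.get("source", "preset"),
        )

    def with_overrides(
        self,
        name: str,
        overrides: Mapping[str, str],
        dual_role: Iterable[str] = (),
        source: str = "preset",
    ) -> "GeneticCode":
        """Derive a new code from this one by reassigning selected codons."""
        table = dict(self.table)
        table.update(overrides)
        return GeneticCode(name=name, table=table, dual_role=frozenset(dual_role), source=source)


def _from_ncbi(table_id: int, name: str) -> GeneticCode:
    ncbi = _NCBICodonTable.unambiguous_dna_by_id[table_id]
    table = dict(ncbi.forward_table)
    for c in ncbi.stop_codons:
        table[c] = STOP
    return GeneticCode(name=name, table=table)


def standard_code() -> GeneticCode:
    """The standard nuclear genetic code (NCBI table 1)."""
    return _from_ncbi(1, "standard")


def table4() -> GeneticCode:
    """Mold/protozoan mitochondrial code (NCBI table 4): TGA = Trp."""
    return _from_ncbi(4, "table4")


def radiolarian_mito_code() -> GeneticCode:
    """Recoded mitochondrial code with all three standard stops as sense.

    Derived from table 4: TGA = W (as in table 4), TAG = Y, and TAA = Y with
    TAA retained as a dual-role terminator (Y internally, stop at CDS ends).
    """
    return table4().with_overrides(
        "radiolarian_mito",
        {"TAG": "Y", "TAA": "Y"},
        dual_role={"TAA"},
    )


# ---------------------------------------------------------------------------
# CDS records and translation
# ---------------------------------------------------------------------------

@dataclass
class CDSRecord:
    """An in-frame coding sequence located on a contig.

    Coordinates are 0-based half-open on the forward strand of the contig;
    ``seq`` is given 5'->3' on the coding strand (already reverse-complemented
    for ``strand == '-'``).
    """

    gene: str
    seq: str
    contig_id: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    frame_offset: int = 0
    split_part: int = 0  # 0 = not split, 1/2 = segment order on the protein

    def __post_init__(self):
        self.seq = self.seq.upper()
        if set(self.seq) - set("ACGTN"):
            raise CodeError(f"CDS {self.gene!r} contains non-ACGTN characters")
        if self.end == 0 and self.start == 0:
            self.end = len(self.seq)
        if self.end - self.start != len(self.seq):
            raise CodeError(
                f"CDS {self.gene!r}: coordinate span {self.end - self.start} "
                f"!= sequence length {len(self.seq)}"
            )

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3

    def codons(self) -> list:
        return [self.seq[i : i + 3] for i in range(0, 3 * self.n_codons, 3)]


@dataclass
class Translation:
    """Result of translating a CDS: peptide plus in-frame stop bookkeeping."""

    protein: str
    #: codon indices (0-based) of every codon that is STOP-valued or dual-role
    stop_indices: list
    #: codon index at which translation terminated, or None if it ran through
    terminated_at: int | None = None

    @property
    def internal_stop_indices(self) -> list:
        if self.terminated_at is None:
            return list(self.stop_indices)
        return [i for i in self.stop_indices if i != self.terminated_at]


def translate(seq: str, code: GeneticCode, readthrough: str = "none") -> Translation:
    """Translate an in-frame DNA string under ``code``.

    Policies
    --------
    ``none``
        every terminator codon (STOP-valued or dual-role) terminates.
    ``dual_role_internal``
        dual-role codons are read as their sense amino acid internally; a
        dual-role codon in terminal position (or any STOP-valued codon)
        terminates.
    ``all_stops_as_X``
        nothing terminates; STOP-valued codons are rendered as ``X`` so the
        peptide can be aligned with stop positions kept addressable.

    Codons containing N translate to ``X`` and never appear in stop lists.
    The returned peptide excludes the terminator codon itself.
    """
    seq = seq.upper()
    if readthrough not in POLICIES:
        raise CodeError(f"unknown readthrough policy {readthrough!r}")
    if len(seq) < 3:
        raise CodeError("sequence shorter than one codon")
    if len(seq) % 3:
        raise CodeError(f"sequence length {len(seq)} not divisible by 3")

    n = len(seq) // 3
    stop_indices: list = []
    peptide: list = []
    terminated_at: int | None = None
    for i in range(n):
        codon = seq[3 * i : 3 * i + 3]
        if "N" in codon:
            if terminated_at is None:
                peptide.append("X")
            continue
        value = code.table[codon]
        is_dual = codon in code.dual_role
        if value == STOP or is_dual:
            stop_indices.append(i)
        if terminated_at is not None:
            continue
        if value == STOP:
            if readthrough == "all_stops_as_X":
                peptide.append("X")
            else:
                terminated_at = i
        elif is_dual:
            if readthrough == "none":
                terminated_at = i
            elif i == n - 1 and readthrough == "dual_role_internal":
                terminated_at = i
            else:
                peptide.append(value)
        else:
            peptide.append(value)
    return Translation("".join(peptide), stop_indices, terminated_at)


def translate_cds(cds: CDSRecord, code: GeneticCode, readthrough: str = "none") -> Translation:
    """Translate a :class:`CDSRecord`, naming the CDS in any error."""
    try:
        return translate(cds.seq, code, readthrough=readthrough)
    except CodeError as exc:
        raise CodeError(f"CDS {cds.gene!r} ({cds.contig_id}): {exc}") from exc


def back_translate(protein: str, code: GeneticCode) -> str:
    """Deterministic injective back-translation (alphabetically first sense
    codon per amino acid, dual-role codons excluded so the result round-trips
    under every readthrough policy)."""
    out = []
    for aa in protein:
        choices = sorted(c for c in code.synonymous_codons(aa) if c not in code.dual_role)
        if not choices:
            raise CodeError(f"no non-dual codon encodes {aa!r} in code {code.name!r}")
        out.append(choices[0])
    return "".join(out)


# ---------------------------------------------------------------------------
# ORF finding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ORF:
    """A maximal stop-to-stop span, 0-based half-open on the forward strand."""

    start: int
    end: int
    frame: int
    strand: str

    def astuple(self):
        return (self.start, self.end, self.frame, self.strand)


def find_orfs(
    seq: str,
    code: GeneticCode,
    min_aa: int,
    require_start: str | None = "ATG",
) -> list:
    """ORFs of >= ``min_aa`` codons on all six frames.

    Each candidate is a maximal run of non-terminator codons (stop-to-stop
    span); with ``require_start`` set (the default, ATG initiation) the span
    is trimmed to begin at its first start codon, and spans lacking one are
    dropped.  Pass ``require_start=None`` for raw stop-to-stop spans.
    Coordinates are nucleotide positions, 0-based half-open, on the forward
    strand.  Codons containing N count as sense.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = seq.upper()
    if not seq:
        return []
    length = len(seq)
    orfs: list = []
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        for frame in range(3):
            n = (length - frame) // 3
            if n <= 0:
                continue
            run_start = 0
            for ci in range(n + 1):
                codon = s[frame + 3 * ci : frame + 3 * ci + 3] if ci < n else None
                terminates = codon is not None and "N" not in codon and code.is_terminator(codon)
                if ci == n or terminates:
                    first = run_start
                    if require_start is not None:
                        while first < ci and s[frame + 3 * first : frame + 3 * first + 3] != require_start:
                            first += 1
                    if ci - first >= min_aa:
                        nt_start = frame + 3 * first
                        nt_end = frame + 3 * ci
                        if strand == "-":
                            nt_start, nt_end = length - nt_end, length - nt_start
                        orfs.append(ORF(nt_start, nt_end, frame, strand))
                    run_start = ci + 1
    orfs.sort(key=lambda o: (o.start, o.end, o.strand, o.frame))
    return orfs
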