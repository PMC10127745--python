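"""Synthetic data with full ground truth for every downstream stage.

The generator emulates a single-cell mini-metagenome containing one circular,
low-GC, high-coverage mitochondrial contig among higher-GC background
contigs.  The mitochondrial molecule carries a reduced complement of
ETC/ATP-synthase genes encoded under a chosen (possibly recoded) genetic
code, separated by large AT-rich intergenic spacers that contain ~50-bp
pseudorepeat families and pseudogene fragments.  Structural quirks observed
in real retarian mitogenomes are planted with recorded coordinates: one gene
split into two segments and one gene broken by a single-nucleotide deletion
(so that inserting one N restores a continuous reading frame).

Reference orthologue panels are simulated under a star phylogeny: each panel
taxon evolves independently from a common ancestral protein under a
Poisson substitution process with a two-class (conserved/variable) site-rate
mixture.  Conserved columns are what the downstream consensus tally needs;
their per-site class is recorded in the panel so tests can check recovery
against truth.

Recoded codons (TGA at Trp sites, TAG/TAA at Tyr sites) are planted at
*eligible* sites: internal, conserved-class positions where the query retains
the ancestral residue.  The consensus-tally method can only ever see
reassignment at columns with a clear consensus, and in real data dual-role
TAA was recognisable precisely because it sat opposite conserved tyrosines -
so eligibility is part of what the generator emulates, not a convenience.
Planted counts are deterministic: ``round(rate * n_eligible)`` sites drawn
without replacement.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import reverse_complement

from .codes import CDSRecord, CodeError, GeneticCode, radiolarian_mito_code, translate
from .recovery import Contig

logger = logging.getLogger(__name__)

#: amino-acid frequencies typical of mitochondrion-encoded membrane proteins
#: (hydrophobic- and aromatic-rich, Leu/Ile/Phe-heavy)
MITO_AA_FREQS = {
    "L": 0.170, "I": 0.090, "F": 0.085, "S": 0.085, "T": 0.060,
    "A": 0.055, "G": 0.055, "V": 0.055, "N": 0.045, "Y": 0.045,
    "M": 0.040, "K": 0.035, "P": 0.035, "W": 0.030, "R": 0.025,
    "Q": 0.020, "H": 0.020, "E": 0.020, "D": 0.020, "C": 0.010,
}
_AA = "".join(MITO_AA_FREQS)
_FREQS = np.array([MITO_AA_FREQS[a] for a in _AA])

#: the 13 protein-coding genes shared by foram and radiolarian mitogenomes,
#: with protein lengths typical of their orthologues elsewhere
DEFAULT_GENES = (
    ("atp1", 510), ("atp6", 255), ("atp9", 75),
    ("cob", 385),
    ("cox1", 530), ("cox2", 250), ("cox3", 265),
    ("nad1", 330), ("nad3", 120), ("nad4", 490), ("nad4L", 100),
    ("nad5", 600), ("nad7", 400),
)

#: genes present in the reference panel but absent (as full genes) from the
#: simulated mitogenome; pseudogene fragments are planted from these
DEFAULT_PANEL_ONLY_GENES = (("nad9", 190),)


@dataclass
class SimulationConfig:
    """All knobs of the generator; identical config => identical bytes."""

    seed: int = 0
    n_taxa: int = 30
    genes: tuple = DEFAULT_GENES
    panel_only_genes: tuple = DEFAULT_PANEL_ONLY_GENES
    divergence: float = 0.5
    conserved_fraction: float = 0.7
    conserved_rate: float = 0.15
    truth_code: GeneticCode = field(default_factory=radiolarian_mito_code)
    recode_density: float = 0.3
    internal_taa_rate: float = 0.02
    gc_target: float = 0.25
    background_gc: float = 0.45
    repeat_unit_len: int = 50
    repeat_copies: int = 6
    repeat_max_mismatch: int = 2
    fragment_spec: tuple = (("nad9", 0.35),)
    split_gene: str | None = "nad1"
    split_fraction: float = 0.45
    frameshift_gene: str | None = "cox1"
    intergenic_mean: int = 800
    intergenic_min: int = 150
    n_background: int = 8
    background_len_range: tuple = (4000, 8000)
    read_len: int = 150
    insert: int = 350
    coverage_mito: float = 50.0
    coverage_background: float = 5.0
    error_rate: float = 0.002

    def __post_init__(self):
        for name in ("divergence", "conserved_fraction", "conserved_rate",
                     "recode_density", "internal_taa_rate", "gc_target",
                     "background_gc", "error_rate"):
            v = getattr(self, name)
            if name == "divergence":
                if v < 0:
                    raise ValueError("divergence must be >= 0")
            elif not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        for g, L in tuple(self.genes) + tuple(self.panel_only_genes):
            if L <= 0:
                raise ValueError(f"gene {g} has non-positive length")
        if not 0 < self.conserved_fraction < 1:
            raise ValueError("conserved_fraction must be in (0, 1)")
        names = [g for g, _ in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names")
        # planting a codon requires the truth code to read it as the target aa
        checks = []
        if self.recode_density > 0:
            checks += [("TGA", "W"), ("TAG", "Y")]
        if self.internal_taa_rate > 0:
            checks += [("TAA", "Y")]
        for codon, aa in checks:
            if self.truth_code.table[codon] != aa:
                raise CodeError(
                    f"inconsistent truth: planting {codon} as {aa} but "
                    f"truth code reads it as {self.truth_code.table[codon]!r}"
                )

    @property
    def variable_rate(self) -> float:
        """Rate of the variable class so the mixture has mean rate 1."""
        f, r = self.conserved_fraction, self.conserved_rate
        return (1.0 - f * r) / (1.0 - f)

    def gene_length(self, name: str) -> int:
        for g, L in tuple(self.genes) + tuple(self.panel_only_genes):
            if g == name:
                return L
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Panel simulation (star phylogeny, two-class site rates)
# ---------------------------------------------------------------------------

@dataclass
class GenePanel:
    gene: str
    ancestor: str
    conserved: np.ndarray          # bool per site
    taxa: list
    sequences: dict                # taxon -> protein (all equal length)

    @property
    def length(self) -> int:
        return len(self.ancestor)

    def aligned_rows(self) -> dict:
        return dict(self.sequences)


@dataclass
class Panel:
    genes: dict                    # gene name -> GenePanel

    def proteins_by_gene(self) -> dict:
        return {g: dict(gp.sequences) for g, gp in self.genes.items()}


def _draw_protein(rng: np.random.Generator, length: int) -> np.ndarray:
    idx = rng.choice(len(_AA), size=length, p=_FREQS)
    idx[0] = _AA.index("M")
    return idx


def _evolve(rng: np.random.Generator, anc_idx: np.ndarray, site_rates: np.ndarray,
            divergence: float) -> np.ndarray:
    """One tip of the star: Poisson(divergence * rate) substitution events per
    site; after >= 1 event the site state is a fresh draw from the stationary
    amino-acid frequencies."""
    n_events = rng.poisson(divergence * site_rates)
    out = anc_idx.copy()
    hit = np.nonzero(n_events > 0)[0]
    if hit.size:
        out[hit] = rng.choice(len(_AA), size=hit.size, p=_FREQS)
    return out


def _idx_to_str(idx: np.ndarray) -> str:
    return "".join(_AA[i] for i in idx)


def _site_rates(cfg: SimulationConfig, conserved: np.ndarray) -> np.ndarray:
    rates = np.where(conserved, cfg.conserved_rate, cfg.variable_rate)
    rates[0] = 0.0  # initiator Met is invariant
    return rates


def simulate_panel(cfg: SimulationConfig) -> Panel:
    """Per-gene orthologue sets: ``n_taxa`` proteins evolved independently
    from a common ancestor, returned pre-aligned (substitutions only, so the
    gapless rows are themselves the alignment)."""
    rng = np.random.default_rng([cfg.seed, 11])
    taxa = [f"taxon{i + 1:02d}" for i in range(cfg.n_taxa)]
    genes = {}
    for gene, length in tuple(cfg.genes) + tuple(cfg.panel_only_genes):
        anc = _draw_protein(rng, length)
        conserved = rng.random(length) < cfg.conserved_fraction
        conserved[0] = True
        rates = _site_rates(cfg, conserved)
        seqs = {t: _idx_to_str(_evolve(rng, anc, rates, cfg.divergence)) for t in taxa}
        genes[gene] = GenePanel(gene, _idx_to_str(anc), conserved, taxa, seqs)
    return Panel(genes)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """The generator's record of everything it planted."""

    code: GeneticCode
    mito_contig_ids: list
    genes: list          # dicts: gene, contig_id, start, end, strand, split_part,
                         #        cds_seq (intact, coding strand), protein
    planted_stops: dict  # codon -> list of {gene, split_part, codon_index, true_aa}
    fragments: list      # dicts: gene, contig_id, start, end, strand, fraction
    repeats: list        # dicts: start, end, family, mismatches
    repeat_unit: str
    frameshift: dict | None   # gene, contig_id, start, end, strand, cds_pos
    query_proteins: dict      # gene -> full-length protein (pre-split)

    def cds_records(self) -> list:
        """Intact in-frame CDS records (terminator codon included).

        For the frameshifted gene this is the CDS *before* the planted
        deletion; the genome FASTA carries the broken copy.
        """
        out = []
        for g in self.genes:
            # for the frameshifted gene the intact CDS is one base longer
            # than its (deleted) genome copy; span the intact length
            out.append(CDSRecord(
                gene=g["gene"], seq=g["cds_seq"], contig_id=g["contig_id"],
                start=g["start"], end=g["start"] + len(g["cds_seq"]),
                strand=g["strand"], split_part=g["split_part"],
            ))
        return out

    def internal_stop_count(self, codon: str) -> int:
        return len(self.planted_stops.get(codon, []))

    def to_json(self) -> str:
        doc = {
            "code": json.loads(self.code.to_json()),
            "mito_contig_ids": self.mito_contig_ids,
            "genes": self.genes,
            "planted_stops": self.planted_stops,
            "fragments": self.fragments,
            "repeats": self.repeats,
            "repeat_unit": self.repeat_unit,
            "frameshift": self.frameshift,
            "query_proteins": self.query_proteins,
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        doc = json.loads(text)
        return cls(
            code=GeneticCode.from_json(json.dumps(doc["code"])),
            mito_contig_ids=doc["mito_contig_ids"],
            genes=doc["genes"],
            planted_stops=doc["planted_stops"],
            fragments=doc["fragments"],
            repeats=doc["repeats"],
            repeat_unit=doc["repeat_unit"],
            frameshift=doc["frameshift"],
            query_proteins=doc["query_proteins"],
        )


# ---------------------------------------------------------------------------
# Query mitogenome
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _codon_sampler(cfg: SimulationConfig):
    """Synonymous-codon chooser: uniform over sense codons, reweighted toward
    A/T-ending composition to approach the low genomic GC target.  The three
    standard stop triplets are never emitted here - they enter the genome only
    through explicit planting."""
    code = cfg.truth_code
    g = cfg.gc_target
    base_w = {"A": (1 - g) / 2, "T": (1 - g) / 2, "C": g / 2, "G": g / 2}
    table = {}
    for aa in set(code.table.values()) - {"*"}:
        cands = [c for c in code.synonymous_codons(aa) if c not in ("TGA", "TAG", "TAA")]
        if not cands:
            continue
        w = np.array([base_w[c[0]] * base_w[c[1]] * base_w[c[2]] for c in cands])
        table[aa] = (cands, w / w.sum())

    def choose(rng: np.random.Generator, aa: str) -> str:
        cands, w = table[aa]
        return cands[rng.choice(len(cands), p=w)]

    return choose


def _terminator(code: GeneticCode) -> str:
    if "TAA" in code.terminators:
        return "TAA"
    return sorted(code.terminators)[0]


def simulate_query_genome(cfg: SimulationConfig, panel: Panel):
    """Build the query mitogenome plus background contigs.

    Returns ``(contigs, truth)``: a list of :class:`~mitocode.recovery.Contig`
    (the first one the circular mitochondrial contig) and a
    :class:`GroundTruth`.
    """
    rng = np.random.default_rng([cfg.seed, 101])
    choose_codon = _codon_sampler(cfg)
    term = _terminator(cfg.truth_code)
    mito_id = "mito1"

    # -- query proteins (one more independent tip of the star) ----------
    query_proteins = {}
    eligible_w, eligible_y = [], []
    for gene, _length in cfg.genes:
        gp = panel.genes[gene]
        anc_idx = np.array([_AA.index(a) for a in gp.ancestor])
        rates = _site_rates(cfg, gp.conserved)
        q_idx = _evolve(rng, anc_idx, rates, cfg.divergence)
        prot = _idx_to_str(q_idx)
        query_proteins[gene] = prot
        for i in range(1, len(prot)):
            if not gp.conserved[i] or prot[i] != gp.ancestor[i]:
                continue
            if prot[i] == "W":
                eligible_w.append((gene, i))
            elif prot[i] == "Y":
                eligible_y.append((gene, i))

    # -- deterministic planting counts ----------------------------------
    def _pick(pool: list, n: int) -> list:
        if n <= 0 or not pool:
            return []
        n = min(n, len(pool))
        sel = rng.choice(len(pool), size=n, replace=False)
        return [pool[i] for i in sorted(sel)]

    n_taa = round(cfg.internal_taa_rate * len(eligible_y))
    taa_sites = _pick(eligible_y, n_taa)
    remaining_y = [s for s in eligible_y if s not in set(taa_sites)]
    tag_sites = _pick(remaining_y, round(cfg.recode_density * len(remaining_y)))
    tga_sites = _pick(eligible_w, round(cfg.recode_density * len(eligible_w)))
    planted = {"TGA": {}, "TAG": {}, "TAA": {}}
    for codon, sites in (("TGA", tga_sites), ("TAG", tag_sites), ("TAA", taa_sites)):
        for gene, i in sites:
            planted[codon].setdefault(gene, []).append(i)

    # -- back-translate each gene under the truth code ------------------
    gene_codons = {}
    for gene, _length in cfg.genes:
        prot = query_proteins[gene]
        codons = [choose_codon(rng, aa) for aa in prot]
        for codon, by_gene in planted.items():
            for i in by_gene.get(gene, []):
                codons[i] = codon
        gene_codons[gene] = codons

    # -- segments: split gene in two, others whole; terminator appended -
    segments = []  # (gene, split_part, genome_cds, intact_cds, protein_span)
    for gene, _length in cfg.genes:
        codons = gene_codons[gene]
        if gene == cfg.split_gene:
            k = max(1, round(cfg.split_fraction * len(codons)))
            part1 = "".join(codons[:k]) + term
            part2 = "".join(codons[k:]) + term
            segments.append([gene, 1, part1, part1, (0, k)])
            segments.append([gene, 2, part2, part2, (k, len(codons))])
        else:
            cds = "".join(codons) + term
            segments.append([gene, 0, cds, cds, (0, len(codons))])

    # record planted stops with codon indices local to each segment
    planted_stops = {"TGA": [], "TAG": [], "TAA": []}
    for codon, by_gene in planted.items():
        for gene, idxs in by_gene.items():
            for i in sorted(idxs):
                part = 0
                local = i
                if gene == cfg.split_gene:
                    k = round(cfg.split_fraction * len(gene_codons[gene]))
                    k = max(1, k)
                    part, local = (1, i) if i < k else (2, i - k)
                planted_stops[codon].append({
                    "gene": gene, "split_part": part, "codon_index": local,
                    "true_aa": cfg.truth_code.table[codon],
                })

    # -- frameshift: delete one nucleotide from the genome copy ----------
    frameshift = None
    if cfg.frameshift_gene:
        for seg in segments:
            if seg[0] == cfg.frameshift_gene and seg[1] in (0, 1):
                intact = seg[3]
                lo, hi = int(0.1 * len(intact)), int(0.9 * len(intact))
                d = int(rng.integers(lo, hi))
                seg[2] = intact[:d] + intact[d + 1:]
                frameshift = {"gene": seg[0], "cds_pos": d}
                break

    # -- spacers with repeat families and pseudogene fragments -----------
    order = rng.permutation(len(segments))
    segments = [segments[i] for i in order]
    strands = ["+" if rng.random() < 0.5 else "-" for _ in segments]
    n_spacers = len(segments)
    spacer_len = [max(cfg.intergenic_min, int(rng.gamma(2.0, cfg.intergenic_mean / 2.0)))
                  for _ in range(n_spacers)]
    spacers = [list(_random_dna(rng, L, cfg.gc_target)) for L in spacer_len]
    used = [[] for _ in spacers]  # reserved (start, end) intervals per spacer

    def _reserve(length: int):
        for _ in range(200):
            si = int(rng.integers(0, len(spacers)))
            if len(spacers[si]) < length + 2:
                continue
            off = int(rng.integers(0, len(spacers[si]) - length))
            if all(off + length <= s or off >= e for s, e in used[si]):
                used[si].append((off, off + length))
                return si, off
        raise RuntimeError("could not place a planted feature in any spacer")

    unit = _random_dna(rng, cfg.repeat_unit_len, cfg.gc_target)
    repeat_places = []
    for ci in range(cfg.repeat_copies):
        si, off = _reserve(cfg.repeat_unit_len)
        n_mm = int(rng.integers(0, cfg.repeat_max_mismatch + 1)) if ci else 0
        copy = list(unit)
        mm_pos = rng.choice(cfg.repeat_unit_len, size=n_mm, replace=False)
        for p in mm_pos:
            copy[p] = rng.choice([b for b in "ACGT" if b != copy[p]])
        spacers[si][off:off + cfg.repeat_unit_len] = copy
        repeat_places.append((si, off, n_mm))

    fragment_places = []
    for gname, frac in cfg.fragment_spec:
        gp = panel.genes[gname]
        anc_idx = np.array([_AA.index(a) for a in gp.ancestor])
        rates = _site_rates(cfg, gp.conserved)
        prot = _idx_to_str(_evolve(rng, anc_idx, rates, cfg.divergence))
        flen = max(20, round(frac * len(prot)))
        start_aa = int(rng.integers(0, len(prot) - flen + 1))
        frag_nt = "".join(choose_codon(rng, aa) for aa in prot[start_aa:start_aa + flen])
        strand = "+" if rng.random() < 0.5 else "-"
        ins = frag_nt if strand == "+" else reverse_complement(frag_nt)
        si, off = _reserve(len(ins))
        spacers[si][off:off + len(ins)] = list(ins)
        fragment_places.append((gname, frac, si, off, len(ins), strand))

    # -- assemble the circular contig ------------------------------------
    parts = []
    pos = 0
    spacer_start = []
    gene_coords = []
    for i, (seg, strand) in enumerate(zip(segments, strands)):
        spacer_start.append(pos)
        parts.append("".join(spacers[i]))
        pos += len(spacers[i])
        genome_cds = seg[2] if strand == "+" else reverse_complement(seg[2])
        gene_coords.append({
            "gene": seg[0], "contig_id": mito_id, "start": pos,
            "end": pos + len(genome_cds), "strand": strand,
            "split_part": seg[1], "cds_seq": seg[3],
            "protein": query_proteins[seg[0]][seg[4][0]:seg[4][1]],
        })
        parts.append(genome_cds)
        pos += len(genome_cds)
    mito_seq = "".join(parts)

    if frameshift is not None:
        for g in gene_coords:
            if g["gene"] == frameshift["gene"] and g["split_part"] in (0, 1):
                frameshift.update(contig_id=mito_id, start=g["start"],
                                  end=g["end"], strand=g["strand"])

    repeats = []
    for fam_i, (si, off, n_mm) in enumerate(repeat_places):
        start = spacer_start[si] + off
        repeats.append({"start": start, "end": start + cfg.repeat_unit_len,
                        "family": 0, "mismatches": n_mm})
    fragments = []
    for gname, frac, si, off, length, strand in fragment_places:
        start = spacer_start[si] + off
        fragments.append({"gene": gname, "contig_id": mito_id, "start": start,
                          "end": start + length, "strand": strand, "fraction": frac})

    contigs = [Contig(mito_id, mito_seq, coverage=cfg.coverage_mito, circular=True)]
    lo, hi = cfg.background_len_range
    for i in range(cfg.n_background):
        L = int(rng.integers(lo, hi + 1))
        contigs.append(Contig(f"bg{i + 1:02d}", _random_dna(rng, L, cfg.background_gc),
                              coverage=cfg.coverage_background))

    truth = GroundTruth(
        code=cfg.truth_code, mito_contig_ids=[mito_id], genes=gene_coords,
        planted_stops=planted_stops, fragments=fragments, repeats=repeats,
        repeat_unit=unit, frameshift=frameshift, query_proteins=query_proteins,
    )
    return contigs, truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadPair:
    id: str
    seq1: str
    seq2: str


def _add_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def simulate_reads(cfg: SimulationConfig, contigs: Sequence[Contig]) -> list:
    """Uniform-start paired reads at each contig's nominal coverage.

    Circular contigs are sampled with wrap-around, so read pairs spanning the
    origin exist.  Contigs shorter than one read are skipped with a warning.
    """
    rng = np.random.default_rng([cfg.seed, 301])
    pairs = []
    for contig in contigs:
        L = len(contig.seq)
        if L < cfg.read_len:
            warnings.warn(f"contig {contig.id} shorter than read length; skipped")
            logger.warning("contig %s shorter than read length; skipped", contig.id)
            continue
        cov = contig.coverage if contig.coverage is not None else cfg.coverage_background
        insert = min(cfg.insert, L)
        n_pairs = max(1, round(cov * L / (2 * cfg.read_len)))
        doubled = contig.seq + contig.seq
        for i in range(n_pairs):
            if contig.circular:
                start = int(rng.integers(0, L))
            else:
                start = int(rng.integers(0, L - insert + 1))
            frag = doubled[start:start + insert]
            r1 = _add_errors(rng, frag[:cfg.read_len], cfg.error_rate)
            r2 = _add_errors(rng, reverse_complement(frag[-cfg.read_len:]), cfg.error_rate)
            pairs.append(ReadPair(f"{contig.id}:{i}", r1, r2))
    return pairs


def reads_as_sequences(pairs: Iterable[ReadPair]) -> list:
    """Flatten pairs to (read_id, sequence) tuples for mapping stages."""
    out = []
    for p in pairs:
        out.append((p.id + "/1", p.seq1))
        out.append((p.id + "/2", p.seq2))
    return out
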