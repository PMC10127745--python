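# Methods

`mitocode` implements the computational workflow used to pull mitochondrial
genomes out of single-cell (mini-meta)genome assemblies of rhizarian
protists and to decide, from orthologue alignments alone, whether the
standard stop codons TGA/TAG/TAA have been reassigned to amino acids in
those genomes.  This note records the models, the defaults and the design
choices made where the procedure was genuinely open.

## 1. The inference problem

Mitochondrial genomes of Foraminifera and Radiolaria are AT-rich, present in
many copies per cell, and carry a reduced complement of about 14
protein-coding genes (ETC subunits and ATP synthase components) separated by
large noncoding regions.  In radiolarian mitogenomes all three standard stop
codons appear in-frame inside otherwise ordinary coding sequences.  The
question the core module answers is: *what does each stop triplet mean?*

The evidence is positional.  Every in-frame TGA/TAG/TAA of a query CDS is
mapped onto a column of a multiple alignment of that gene's orthologues from
a reference panel of other protists.  If a codon repeatedly lands on columns
where most panel sequences carry one particular residue, the codon most
plausibly encodes that residue; if it almost never occurs internally but
terminates nearly every gene, it is the stop codon; a codon that does both —
recurring at coherent consensus columns *and* terminating most genes — has a
dual role (sense internally, terminator at gene ends).

## 2. Genetic codes and translation

A `GeneticCode` is a complete 64-codon table plus an optional set of
*dual-role* codons (sense internally, terminator at a CDS end).  Three
presets ship: the standard code, translation table 4 (TGA = Trp; the usual
baseline for protist mitochondria), and a radiolarian-style code derived
from table 4 by TAG→Y and TAA→Y with TAA kept as the (dual-role)
terminator.  The derived code is constructed, not hard-coded, so other
reassignment patterns can be expressed the same way.

Translation supports three read-through policies: `none` (every terminator
terminates), `dual_role_internal` (dual codons are sense except in terminal
position) and `all_stops_as_X` (nothing terminates; stops become `X`, used
to keep peptides alignable).  Codons containing N translate to `X` and never
enter stop lists.  ORF finding enumerates maximal stop-free spans on all six
frames and by default trims each span to its first ATG; initiation at
non-ATG codons is untested in this group, so the requirement is a
configurable default rather than an assumption baked in.

## 3. The synthetic study

Because no second ground-truth dataset of this kind exists, every stage is
validated on synthetic studies with full ground truth.  The generator is
first-class, seeded, and byte-reproducible.

**Reference panel.**  For each gene an ancestral protein is drawn from
amino-acid frequencies typical of mitochondrion-encoded membrane proteins
(Leu/Ile/Phe-heavy, ~4.5% Tyr, ~3% Trp).  Thirty panel taxa evolve
independently from the ancestor (a star phylogeny — the tally treats panel
taxa exchangeably, so deeper tree structure would add realism the method
never consumes).  Substitution is a Poisson process per site; after at
least one event the site state is a fresh draw from the stationary
frequencies.  Site rates follow a two-class mixture: 70% conserved sites at
0.15× the mean rate, 30% variable sites at the complementary rate, mean 1.
At the default tip divergence of 0.5 substitutions/site this yields ~90%
column identity at conserved sites and no usable consensus at variable
sites, which is the contrast the tally method requires.  The per-site class
is recorded as ground truth.

**Query genome.**  The query species is one more independent tip.  Its 13
genes (the shared foram/radiolarian complement, 75–600 aa) are
back-translated under the chosen truth code with synonymous-codon weights
biased toward A/T-ending codons (intergenic GC target 0.25).  The three
standard stop triplets are *never* emitted by the codon sampler; they enter
CDSs only through explicit planting, so the planting densities are the sole
source of in-frame stop triplets and a zero-recoding run is a true negative
control.

Recoded codons are planted at *eligible* sites: internal positions of the
conserved class where the query retains the ancestral residue.  A planted
codon at a variable column would be invisible to the consensus tally by
construction, and in real data the recognisable dual-role TAAs sat opposite
conserved tyrosines, so eligibility is part of what is being emulated rather
than a convenience.  Planted counts are deterministic —
`round(rate × n_eligible)` sites drawn without replacement — at the default
densities 0.30 (TGA at Trp sites, TAG at Tyr sites) and 0.02 (TAA at Tyr
sites).  Every gene ends with the truth terminator (TAA).

Structural quirks, all with recorded coordinates: one gene (`nad1`) split
into two separately terminated segments; one gene (`cox1`) with a single
planted nucleotide deletion (the genome carries the broken copy, ground
truth keeps the intact CDS); one ~50-bp pseudorepeat family planted six
times across spacers with up to two mismatches per copy; one `nad9`
pseudogene fragment (35% of the protein) in intergenic space.  Intergenic
spacers are gamma-length (mean 800 bp) random DNA at GC 0.25; eight
background contigs at GC 0.45 emulate co-assembled contamination.  The
default mitochondrial contig is ~24 kb with a coding fraction near 0.55.

**Reads.**  Uniform-start 2×150 bp pairs, fixed insert 350 bp, per-base
error 0.002, nominal coverage 50× (mitochondrial) vs 5× (background);
circular contigs are sampled with wrap-around so origin-spanning pairs
exist.

What the generator does *not* emulate: MDA amplification bias and chimeras,
indel evolution in the panel (panel rows are gapless, so the "alignment" is
exact), rRNA genes, compositional heterogeneity among lineages, and real
contaminant genomes with genes of their own.  Passing tests therefore show
that the algorithms do what they claim under controlled conditions, not
that any particular real SAG will assemble cleanly.

## 4. Mitochondrial contig recovery

Per-contig blob statistics (mean mapped-read coverage, GC) are computed with
an exact k-mer-anchored ungapped mapper; a read mapping equally well to n
contigs contributes 1/n of its bases to each, so shared repeats do not
inflate depth.  Candidate mitochondrial contigs are *seeded* by translated
homology: any six-frame local alignment against any panel protein above a
score threshold (default 80, BLOSUM62).  Remaining contigs are labelled
mitochondrial when their coverage lies within a 2× band of the median seed
coverage and their GC within ±0.08 of the median seed GC — a native
implementation of the coverage/GC blob-plot argument.  Cross-species
*nucleotide* mapping thresholds are exposed in configuration but protein
space is the default signal; at these divergences nucleotide identity is
unreliable.

**Bait-and-extend.**  From a seed sequence, each round recruits every
unrecruited read (either orientation) whose best ungapped placement on the
round-start consensus overlaps by ≥100 bp with ≤1% mismatches and no gaps;
placements are anchored by exact 21-mers sampled along the read.  Recruits
are applied after the scan, which makes the result independent of read input
order.  The consensus is re-called per column by majority vote over all
recruited reads (the seed votes once; ties keep the previous base, new
columns break ties alphabetically) and extends across overhanging bases.
Iteration stops at a fixpoint.  Circularity is declared when a suffix of the
consensus exactly equals a prefix (≥50 bp — at convergence the two ends of
a finished circle overlap by at least `2·min_overlap − read_len`); one copy of the duplicated
terminus is trimmed and the sequence is reported at its lexicographically
smallest rotation over both strands, so repeated runs emit identical bytes.

## 5. Annotation and intergenic features

**Composition is the enemy.**  AT-rich DNA translates into Leu/Ile/Phe-heavy
peptides that score positively against hydrophobic membrane proteins under
BLOSUM62 despite being unrelated.  Raw Smith–Waterman hits therefore
overshoot gene boundaries and produce spurious intergenic hits.  Two
countermeasures are applied to every translated search: a co-diagonal
k-mer-seed prefilter (scattered random seeds do not cluster on one
diagonal), and trimming of each alignment to its maximum-identity core
(columns re-scored as `match − 0.45`, maximum-sum stretch kept — a Kadane
pass), with hits also required to reach 40% identity over ≥20 columns.
These thresholds cleanly separate genuine orthologue hits (≥60% identity in
the synthetic study) from compositional artefacts (≤~35%).

Genes are annotated per panel-consensus reference across the six frames;
after a hit the matched stretch is masked and the frame searched once more,
so both halves of split or frameshifted genes are found.  Because local
alignment clips divergent first/last residues, boundaries are projected
outward to the full reference extent when the missing margin is ≤15 codons;
boundary error on synthetic genomes is ≤6 nt.  Two same-gene annotations
with complementary reference coverage (combined ≥0.8, reference overlap
≤0.1 after clipping modest boundary fuzz) are flagged split parts 1/2;
full-length duplicates fail the overlap rule and stay unflagged.

**Fragment rule.**  Intergenic regions (the exact complement of
full-gene/split annotations) are searched in six frames against *every*
panel taxon; a region is annotated as a pseudogene fragment of gene *g* only
when at least four *distinct panel taxa* (source labels, not alignments) hit
it for *g* above a threshold calibrated per contig from shuffled-sequence
null alignments (99th percentile × 1.1, floor 60) — shuffling preserves the
composition that drives the null scores.

**Pseudorepeats.**  Candidate pairs of ~50-bp units are seeded by shared
exact 14-mers (two mismatches in 50 bp leave a ≥16-bp exact stretch, so no
qualifying pair is missed), extended by exact diagonal window search under a
2×2-mismatch pairwise budget, clustered into families, and placed on
diagonal-consistent coordinates; the unit window maximizing cross-member
agreement is validated by requiring each member within 2 mismatches of the
family consensus, placed greedily without overlap.

**Frameshift repair.**  For a region whose reading frame cannot cover the
reference, every insertion offset p is tried exhaustively: insert one N,
find the longest run without a hard stop (dual-role codons are sense
internally and do not break runs), and accept p when the run's translation
aligns to ≥90% of the reference protein.  Contiguous accepted offsets are
grouped into a single call (within a homopolymer the exact position is
unknowable); disjoint windows are all reported, best first, flagged
ambiguous.  The scan is equivalent to brute force on regions ≤2 kb.

## 6. Recoding inference

The query peptide of each CDS, with all standard stop triplets rendered as
`X` (placeholders avoid biasing the aligner toward any candidate residue),
is threaded into the pre-aligned panel by semi-global alignment against the
panel consensus; the codon→column mapping is exact and invertible.

Per internal stop site, the panel column is classified: `excluded_sparse`
when fewer than 50% of panel rows span the column (alignment
beginnings/ends), `excluded_gap` when most spanning rows carry a gap,
`excluded_no_consensus` when no residue is a strict majority, else `counted`
with the consensus residue.  Consensus is *strictly greater than* 50% of
non-gap rows with a unique mode — ties are genuinely ambiguous.  Counted
sites aggregate per codon by residue and by biochemical class (aromatic
F/W/Y/H, charged D/E/K/R, polar S/T/N/Q/C, nonpolar G/A/V/L/I/P/M; His is
grouped aromatic; all memberships are configuration since any grouping is a
convention).  Bookkeeping is exact: counted + excluded = total internal
occurrences, enforced by tests against an independent recount.

A gene's *terminator* is its final codon when that codon is a stop triplet
at a reference-relative position within the last 10% of the predicted
protein length.  An internal stop triplet inside that window terminates
nothing and is never attributed — otherwise recoded sense codons near the
3′ end would masquerade as terminators.  Genes whose frame runs through are
reported separately.

The call, per codon: **sense(aa)** when counted ≥ 5 sites with a top-residue
fraction ≥ 0.5 and terminal usage < 0.2; **dual_role(aa)** when terminal
usage ≥ 0.2 *and* ≥ 2 counted internal sites agree on a unique top residue;
**stop** when terminal usage ≥ 0.2 with (almost) no counted internal sites;
anything contradictory is flagged `insufficient_data` rather than silently
called.  The emitted code overlays the verdicts on table 4; an
insufficient-data codon keeps its baseline meaning.  All four thresholds are
free parameters with these defaults; verdicts of this kind are ultimately
judgment calls, so the defaults are deliberately conservative and every one
is exposed in `InferenceParams`.

A pairwise profile (internal stops of one protein against the aligned
residues of another, counting Y/F/W and hydrophobic partners, gap-aligned
stops excluded and reported) reproduces the two-genome comparison that
supports the dual-role reading when no panel is available.  The hydrophobic
set is A/V/L/I/M/F/W/Y/C, again configuration.

## 7. Numerical and reproducibility choices

* All randomness flows from `numpy.random.default_rng` seeded per stage from
  the single study seed; identical configuration gives byte-identical FASTA,
  FASTQ, TSV and JSON outputs.
* Alignment engine: Biopython `PairwiseAligner` (BLOSUM62, gap open −11,
  extend −1), behind a thin pluggable layer; every threshold that touches it
  (score 80/identity 0.4 for genes, calibrated-null floor 60/identity 0.5
  for fragments, trim level 0.45) is a keyword argument.
* Consensus ties in assembly keep the existing base (interior) or take the
  alphabetically first base (new columns); split-part numbering follows
  reference order; circular output is canonically rotated.
* Degenerate inputs fail loudly: codes without a terminator, CDS lengths not
  divisible by 3 (the error names the CDS), ragged "aligned" panels, empty
  contig sets, classification without coverage.

## 8. Problem sizes used by the test suite

Replicate counts and sizes are chosen to make the statistical claims they
support: code recovery and its negative control run 50 seeded studies each
at the full default conditions; assembly fidelity runs 20 studies of a
~20-kb circular genome at 40× error-free coverage from a 2-kb seed;
frameshift repair runs 20 studies (the repair scan is the most expensive
single operation, since under a dual-role code no hard stop prunes the
candidate list); the fragment-rule boundary is exercised on 3 studies plus
reduced panels of exactly 3 and 4 supporting taxa.  The acceptance script
reports the same quantities at slightly smaller replicate counts (8 assembly
and 10 repair studies) so a full rerun stays inside a few minutes.

## 9. Known limitations

* Panels must be pre-aligned (or alignable with an external aligner at the
  pipeline boundary); the internal consensus-threading step does not build a
  de novo MSA from ragged orthologue sets.
* Gapped read recruitment is not implemented (`allow_gaps=True` raises);
  the recruitment rule here is deliberately ungapped.
* The frameshift repair considers exactly one inserted base; multi-base or
  multi-site disruptions return empty results by design.
* rRNA fragment annotation and phylogenetic placement are out of scope; the
  pipeline exports alignments others can feed into tree software.
* Under a code whose only terminator is dual-role, "stop-free" pruning in
  the repair scan is vacuous and the scan cost is dominated by per-candidate
  alignment.
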