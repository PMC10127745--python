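# mitocode

Recovery of mitochondrial genomes from single-cell read sets and inference
of noncanonical mitochondrial genetic codes.

Single isolated cells of uncultured protists (Foraminifera, Radiolaria and
their relatives) yield mini-metagenomes: a mixture of host nuclear
fragments, symbiont organelles and bacteria.  The host mitochondrial genome
is recoverable from that mixture because it is present in many copies
(orders-of-magnitude-higher read coverage) and is AT-rich (much lower GC)
than most co-assembled DNA.  Once recovered, these genomes can hide a
deeper surprise: stop codons that no longer mean *stop*.

`mitocode` implements that entire workflow as a tested library and CLI:

* **Recovery** — coverage/GC blob statistics, translated-homology seeding of
  mitochondrial contigs against a reference orthologue panel, and genome
  finishing by iterative bait-and-extend read mapping (reads recruited at
  ≥100 bp overlap, ≤1% mismatches, no gaps, to a fixpoint) with circularity
  detection.
* **Annotation** — protein-coding genes by translated local alignment
  (stops rendered as X so recoded genes stay contiguous), split-gene
  detection, intergenic pseudogene fragments under a ≥4-distinct-taxa rule,
  ~50-bp pseudorepeat families (≤2 mismatches from a family consensus), and
  exhaustive single-nucleotide-insertion frameshift repair.
* **Genetic-code inference** (the core) — every in-frame TGA/TAG/TAA of the
  query CDSs is mapped to a column of its gene's orthologue alignment; the
  >50%-consensus residues at those columns are tallied per codon and per
  biochemical property class, columns that are mostly gap or sparsely
  occupied are excluded but accounted for, terminal codon usage is profiled,
  and each codon is called sense(aa) / stop / dual-role(aa):

  * **sense(aa)**: ≥ 5 counted internal sites, top residue ≥ 50% of counted,
    rarely terminal;
  * **dual-role(aa)**: terminates ≥ 20% of genes *and* recurs internally at
    ≥ 2 counted sites with a coherent residue;
  * **stop**: terminal with (almost) no counted internal sites;
  * anything contradictory is flagged `insufficient_data`, never silently
    called.

  The emitted `GeneticCode` overlays the verdicts on translation table 4.

A first-class synthetic-study generator (`mitocode.simulate`) produces
reference panels, recoded query mitogenomes with the relevant structural
quirks (split gene, planted frameshift, pseudorepeats, pseudogene fragment,
low-GC spacers, high-GC background contigs) and paired reads — all with
machine-readable ground truth, so every stage is testable without any
download.

## Worked example

Generate a synthetic study and infer its genetic code:

```bash
mitocode simulate --seed 3 --out-dir fixture --no-reads
mitocode infer-code --contigs fixture/contigs.fasta --panel fixture/panel \
                    --out-dir results --seed 3
```

which prints (abridged):

```json
{
  "n_cds": 15,
  "verdicts":    { "TGA": "sense", "TAG": "sense", "TAA": "dual_role" },
  "amino_acids": { "TGA": "W",     "TAG": "Y",     "TAA": "Y" },
  "terminal_usage": { "TGA": 0.0, "TAG": 0.067, "TAA": 0.933 }
}
```

Reading: across the 15 annotated coding sequences, internal TGA and TAG
codons sit at alignment columns whose consensus residues are tryptophan and
tyrosine respectively, and essentially never terminate a gene — they are
sense codons.  TAA terminates 93% of genes *and* recurs at a few coherent
tyrosine columns, so it is called dual-role: tyrosine internally, the
(only) stop codon at gene ends.  The generating code for this fixture was
exactly that (TGA=W, TAG=Y, TAA=Y/stop); `results/` also contains the
stop-site table, the per-codon/per-class tally TSV, the annotations GFF3,
the gene presence/fragment/absence matrix, a gap-free concatenated protein
alignment for external phylogenetics, and the inferred code as JSON.

The same stages are available as library calls (`simulate_panel`,
`simulate_query_genome`, `bait_extend_iterate`, `annotate_by_homology`,
`scan_intergenic_fragments`, `repair_single_insertion_frameshift`,
`infer_from_cds`, ...) for use on real contigs and panels.

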