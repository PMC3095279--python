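# famevol

A toolkit for gene-family molecular-evolution analysis: family membership by
catalytic-motif scanning, neighbor-joining phylogenies, duplication-mechanism
classification, Ka/Ks estimation, molecular-clock dating, and protein motif
architecture — plus a synthetic-genome generator that plants ground truth for
every pipeline stage.

## What it does

| Module | Purpose |
|---|---|
| `famevol.family` | Membership by two separated HxKxxxxD (HKD) motifs; subfamily (C2 / PXPH / SP) from a domain table; pseudogene flag from premature in-frame stops |
| `famevol.phylogeny` | NJ trees from protein alignments (p-distance, complete deletion), column-resampling bootstrap, anchor-based subgroup labels |
| `famevol.duplication` | Same-species cherries as paralog pairs; tandem (adjacency) vs segmental (conserved flanking genes, 10 per side, one-to-one matching) |
| `famevol.kaks` | Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction, pathway-averaged multi-substitution codons, 300/50-nt sliding windows, mean Ks with a 2.0 saturation cutoff |
| `famevol.dating` | Duplication ages T = Ks/(2λ) with built-in per-species synonymous rates (Arabidopsis 1.5e-8, rice/grape 6.5e-9, poplar 9.1e-9 per site per year) |
| `famevol.motifs` | Regex motif scanning, partition into N-terminal / middle / C-terminal regions relative to the HKD spans, shared/specific motif reports |
| `famevol.simulate` | Synthetic chromosomes with planted family members, decoys, a pseudogene, tandem and segmental pairs, and CDS pairs evolved to a chosen Ks |

## CLI

Every stage is a `famevol` subcommand; a full round trip on synthetic data:

```bash
famevol simulate --seed 42 --out bundle/
famevol identify --proteins bundle/proteins.faa --cds bundle/cds.fna \
                 --domains bundle/domains.tsv --out assignments.tsv
famevol tree     --aln bundle/alignment.faa --bootstrap 1000 --seed 42 --out tree.nwk
famevol dups     --tree tree.nwk --genes bundle/genes.gff3 \
                 --homology bundle/homology.tsv --out dups.tsv
famevol kaks     --aln bundle/alignment.faa --cds bundle/cds.fna \
                 --pairs pairs.tsv --window 300 --step 50 --out kaks.tsv
famevol date     --kaks meanks.tsv --out dates.tsv
famevol motifs   --proteins bundle/proteins.faa --motifs bundle/motifs.tsv \
                 --families assignments.tsv --out arch.tsv
```

Inputs are plain text: FASTA (proteins, CDS, alignment), GFF3 or TSV gene
order, and TSV for homology pairs, domain annotations, and motif regexes.

## Notes

- Ka/Ks is standardized on Nei–Gojobori (1986): fractional site counts per
  codon, equal-weight averaging over stop-free mutational pathways, and
  Jukes–Cantor correction. ω is `inf` when Ka > 0 with Ks = 0, and undefined
  (NaN) when both are 0 or a proportion saturates (≥ 3/4).
- Sliding windows are defined on nucleotide coordinates as printed (300 bp
  window, 50 bp step); partial codons at window edges are not scored.
- Known source inconsistency: the narrative text swaps the species of two
  dates (25.09 Ma vs 88.39 Ma); this package follows the tabulated values and
  the T = Ks/(2λ) arithmetic, under which Ks 0.7527 with the Arabidopsis rate
  gives 25.09 Ma and Ks 1.1491 with the grape rate gives 88.39 Ma.
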