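# ringcensus

Genome-wide census of RING zinc-finger domains from a proteome + annotation,
built around a variable-gap consensus grammar instead of external HMM/BLAST
pipelines.

A RING domain is modelled as an octet of metal-ligand residues (ml1..ml8)
with constrained spacing between consecutive ligands. Seven built-in domain
types (RING-H2, RING-HCa, RING-HCb, RING-v, RING-C2, RING-S/T, RING-G) are
encoded as data and are provably pairwise exclusive, so every octet has at
most one type. The package provides:

- `ring_model` — the grammar: type specs, octet matching, classification,
  plain-text profile (de)serialisation for custom grammars.
- `scanner` — exhaustive octet enumeration, deterministic overlap
  resolution, and detection of *incomplete* domains (single metal-ligand
  violations).
- `domain_stats` — spacing histograms/modes/fractions and metal-ligand
  anchored conservation profiles (+ information content for logo rendering).
- `census` — per-type/per-chromosome tallies, multi-domain proteins,
  intronless gene counts, protein length/MW/pI, pairwise identity, and
  tandem duplicate cluster detection.
- `evolution` — Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction.
- `synthetic` — proteome/gene-model/CDS generators with planted ground
  truth, so every stage is testable offline.
- `seqio` — FASTA/GFF3 readers and writers, deterministic TSV reports.

## CLI

```sh
# generate a synthetic proteome with planted domains + decoys + truth table
ringcensus simulate -o sim --seed 7 --n-proteins 50 --n-domains 40 --n-decoys 5 --tandem 3

# scan a protein FASTA for complete + incomplete RING domains
ringcensus scan sim/proteome.fasta -o matches.tsv

# full census (scan + tallies + spacing + conservation + tandem clusters)
ringcensus census sim/proteome.fasta sim/genes.gff3 -o census_out

# NG86 Ka/Ks for consecutive pairs in a nucleotide FASTA
ringcensus kaks pairs.fasta -o kaks.tsv
```

All commands are deterministic for fixed inputs/seed; reports use 1-based
inclusive coordinates.

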