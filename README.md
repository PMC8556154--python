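# cladeprimers

Clade-specific degenerate qPCR primer design from single-copy core genes.

Quantifying one microbial clade (a genus, a species complex) in complex
communities by qPCR requires primers that amplify **every member** of the
clade and **nothing else**. `cladeprimers` automates that design: given the
annotated gene catalogs of a set of target-clade genomes and a set of
non-target sequences, it

1. filters genomes on assembly QC metadata (completeness ≥ 90 %,
   contamination ≤ 5 % by default),
2. clusters protein sequences across genomes (greedy centroid clustering,
   ≥ 80 % identity / ≥ 90 % mutual coverage) and keeps **single-copy core
   clusters** — exactly one member in every target genome,
3. aligns each core cluster's proteins (center-star, BLOSUM62),
   back-translates the alignment codon-by-codon, and builds a per-column
   majority **consensus** with recorded variant sets,
4. enumerates candidate primer pairs on the consensus under length, Tm,
   GC, homopolymer, self-complementarity, pair-ΔTm and product-size
   constraints, then widens each primer position to the IUPAC union of the
   bases observed in its alignment column — degenerate primers that cover
   exactly the observed variation,
5. filters pairs on degeneracy budgets (total degeneracy ≤ 32 per primer;
   **no** degenerate code in the 3'-terminal five nucleotides by default),
   and
6. removes pairs with off-target amplification potential by IUPAC-aware
   **in-silico PCR**, in two stages: first against all other genes of the
   target genomes, then against the non-target set. A hit is viable when
   it covers > 80 % of the primer (3'-anchored) with at most 3 mismatches;
   a pair is rejected when a predicted off-target product falls inside
   30–2,000 bp.

Melting temperatures use the SantaLucia (1998) unified nearest-neighbor
model: Tm = ΔH° / (ΔS° + 0.368 (N−1) ln[Mon⁺] + R ln(Cₜ/4)) − 273.15, with
[Mon⁺] = [Na⁺] + 120·√[Mg²⁺] (mM) and defaults of 50 nM oligo, 50 mM
monovalent, 1.5 mM Mg²⁺. The Tm of a degenerate primer is the arithmetic
mean over all of its concrete expansions.

A seeded synthetic pan-genome generator (`cladeprimers simulate`) produces
complete test fixtures — a clade of diverged genomes sharing planted
single-copy core genes, with mutation-protected primer sites and
off-target "decoys" that near-match them — so the whole pipeline is
testable without downloading any data.

## Worked example

The degeneracy-aware Tm calculator on a published *Methanothermobacter*-
targeting forward primer:

```
$ cladeprimers tm TMARRACMCACTGCAGGGAC
primer  TMARRACMCACTGCAGGGAC
degeneracy      16
degenerate_positions    4
three_prime_degeneracy  0
mean_tm_C       60.68
```

The primer pool contains 16 concrete sequences (four 2-fold codes:
M, R, R, M), none of them within the extension-critical last five
nucleotides, and the pool's mean nearest-neighbor Tm is 60.68 °C.

A full design run on a synthetic five-genome clade:

```
$ cladeprimers simulate --seed 1 -o demo/fixture
$ cat > demo/config.yaml <<EOF
cds_nt: demo/fixture/target_cds.fna
cds_aa: demo/fixture/target_proteins.faa
non_target: demo/fixture/non_target.fasta
qc_table: demo/fixture/genome_qc.tsv
EOF
$ cladeprimers design demo/config.yaml -o demo/run
loaded 40 genes from 5 genomes
QC filter: 5 genomes retained
8 clusters, 8 single-copy core
16000 candidate pairs after degeneracy filtering
screen: 15976 retained, 24 rejected
report: demo/run/primer_report.tsv
```

All 8 planted gene families are recovered as single-copy core clusters;
24 candidate pairs predicted an off-target product and were rejected with
the stage, subject and product length recorded:

```
$ head -3 demo/run/rejections.tsv
cluster_id  forward             reverse             stage       subject_id  product_length
CL0000      GCGATGGCACACTTTCCC  GTATGGCGCGAGTTGTGG  non_target  ot00        954
CL0004      CCTTTAGCCGGCAACAACTT CAAGGTGAGTGCTCGTGTTC non_target ot00       505
```

The report table (`primer_report.tsv`) lists, per pair, the degenerate
sequences, per-primer length, mean Tm, total and 3'-window degeneracy,
1-based consensus coordinates, product length and screening status.

## Command-line interface

| command | purpose |
| --- | --- |
| `cladeprimers design CONFIG -o DIR` | full pipeline → report TSV (exit 3 when nothing is retained) |
| `cladeprimers simulate --seed N -o DIR` | synthetic fixture with ground truth |
| `cladeprimers insilico-pcr FASTA -f FWD -r REV` | stand-alone amplicon prediction |
| `cladeprimers tm PRIMER` | degeneracy-aware mean Tm |

The library surface (`cladeprimers.*`) exposes every stage individually;
see `docs/methods.md` for the model details, parameter defaults and known
limitations.
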