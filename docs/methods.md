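# Methods

This note documents the models and procedures implemented in
`cladeprimers`, the defaults that matter, and what the synthetic fixtures
do and do not establish about behavior on real genome sets.

## Problem setting

A clade-specific qPCR assay needs a locus that is (i) present in exactly
one copy in every genome of the target clade, (ii) conserved enough that
one (possibly degenerate) primer pair amplifies all members, and (iii)
absent or divergent everywhere else. The pipeline operationalizes this as
single-copy core gene clustering, consensus-based degenerate primer
design, and in-silico PCR specificity screening.

## Gene clustering and core selection

Input genes are paired nucleotide CDS / protein sequences per genome
(`genomeID|geneID` FASTA ids). Protein pairing is validated against the
bacterial/archaeal genetic code (NCBI table 11); a translation mismatch
warns rather than errors, to tolerate annotation quirks.

Clustering is greedy centroid clustering on protein sequences: genes are
visited longest-first (ties lexicographic by id, for determinism); a gene
joins the first cluster whose centroid it matches at ≥ `min_identity`
(default 0.80) and ≥ `min_coverage` (default 0.90), else founds a new
cluster. Identity and coverage come from a "glocal" pairwise alignment
(BLOSUM62, gap open −11 / extend −1; the shorter sequence aligned
end-to-end with free end gaps on the longer side): identity is matches
over aligned non-gap columns; coverage is **bidirectional** — the minimum
over both sequences of aligned span / length, the cov-mode-0 convention
of common clustering tools — so a half-length fragment never absorbs into
a full-length cluster. A cluster is *single-copy core* when it has
exactly one member in every retained target genome.

This replaces cascaded k-mer clustering tools with an exact, dependency-
free method of the same contract; at desk scale (tens of genomes ×
thousands of genes) the quadratic centroid comparisons are negligible.

## Alignment, back-translation, consensus

Each core cluster's proteins are aligned by center-star construction: the
longest member is the center, every other member is aligned to it
globally (BLOSUM62, −11/−1), and pairwise alignments are merged by gap
propagation ("once a gap, always a gap"). For within-clade clusters at
≥ 80 % amino-acid identity this is near-optimal; an externally computed
alignment can be imported from gapped FASTA instead.

The protein alignment is back-translated by substituting each residue
with its source codon and each gap with `---`, so degapping any row
reproduces the member CDS exactly (a tested invariant). The majority
consensus is computed per nucleotide column (ties broken A < C < G < T <
gap), with the full set of observed symbols recorded per column.
Consensus is taken at the nucleotide level because primers are nucleotide
sequences; columns whose majority is a gap, and columns whose variant set
contains a gap, are masked — a primer cannot reliably span an indel
polymorphism.

## Thermodynamics

Duplex melting temperatures use the SantaLucia (1998) unified
nearest-neighbor parameters with terminal initiation terms:

    Tm(K) = ΔH° · 1000 / (ΔS° + 0.368·(N−1)·ln[Mon⁺] + R·ln(Cₜ/4))

with R = 1.987 cal mol⁻¹ K⁻¹, Cₜ the oligo concentration (default
50 nM), and the entropic salt correction evaluated at the
monovalent-equivalent cation concentration [Mon⁺] = [monovalent] +
120·√[Mg²⁺] (mM → M). The divalent term uses the **total** magnesium
concentration; dNTP chelation of Mg²⁺ is deliberately not subtracted —
with the default 1.5 mM Mg²⁺ / 0.6 mM dNTP mix, this dialect reproduces
published degenerate-primer mean Tms to within 0.3 °C, where the
free-magnesium variant is ~0.65 °C low. The dNTP concentration remains a
reaction parameter for reporting and future corrections. No symmetry
correction is applied (primers are treated as non-self-complementary;
the association constant is Cₜ/4 throughout).

The Tm of a degenerate primer is the arithmetic mean of the Tm over all
concrete expansions (pool capped at 512; larger pools are refused, and
are far beyond any sensible degeneracy budget anyway). Tests cross-check
the implementation against an independent nearest-neighbor implementation
at identical conditions to within 0.2 °C.

## Primer design

Defaults (all configurable): length 18/20/25 (min/opt/max), Tm 57/60/63
°C, pair ΔTm ≤ 3 °C, GC 0.30–0.70, homopolymer ≤ 4, product 70–1000 bp,
self-complementary run ≤ 8 nt (a longest-common-compatible-substring
heuristic against the primer's own reverse complement, not a folding
model).

Candidate enumeration considers every consensus window passing the
single-primer filters, in both primer roles (the filters are
strand-symmetric), and every forward/reverse combination with the
forward window upstream, non-overlapping, product size in range and
consensus-Tm difference within the ΔTm bound. Each retained window is
then mapped back to the alignment and every position widened to the
IUPAC union of its column's variant set — the degenerate pool covers
exactly the observed variation, no more (no frequency floor: every
observed base counts, though a floor is configurable). Degeneracy budgets
are applied per primer: total degeneracy ≤ 32 and **zero** degenerate
codes within the 3'-terminal 5 nt by default, where ambiguity most
impairs polymerase extension. The budgets are deliberately generous
relative to a published pair with pools of 16 and 8.

Pairs are ranked by (combined total degeneracy, combined |Tm − Tm_opt|,
coordinates) — lowest degeneracy first, then best Tm fit, matching how a
final qPCR pair is chosen in practice — and the top
`max_pairs_per_cluster` (default 2000) proceed to screening and the
report. At desk scale this budget is effectively exhaustive; on large,
highly conserved consensus tracks it bounds memory and report size. The
pipeline uses a fused implementation (window-level widening and budget
filtering before pair assembly) that is verified in tests to equal the
composed elementary operations.

Optional internal hydrolysis probes are designed on the plus strand
strictly between the primer binding sites, under the same machinery with
the Tm band shifted up by 8 °C (probes are designed hotter than primers);
the window with mean Tm closest to Tm_opt + 8 wins.

## In-silico PCR and two-stage screening

A primer binding site is an ungapped placement of the primer on either
strand with at most `max_mismatches` (default 3) IUPAC-incompatible
positions. Placements may be 5'-truncated — the 3' end must stay anchored
for extension — down to a coverage floor: placements covering ≤ 80 % of
the primer are not viable (strictly greater than 80 % is required, so
16/20 fails and 17/20 passes). Overlapping placements sharing a 3' anchor
are reported once at the longest viable length. The scan is exhaustive
(bitmask-encoded compatibility over sliding windows), verified against a
position-by-position reference scanner; no heuristic seeding is used, and
the mismatch cap is this package's stand-in for a short-word local
aligner's sensitivity, since word size/E-value equivalents are not
meaningful here.

An amplicon is predicted when a forward hit on the plus strand lies
upstream of a reverse hit on the minus strand, without overlap, with an
outer-edge-to-outer-edge product length inside the size window.
Screening is two-staged: a pair is rejected if it predicts an off-target
product of 30–2,000 bp (default) first on any target-clade gene outside
its own cluster, then on any non-target sequence. Amplicons on the pair's
own cluster are the intended signal and never reject, at any length.
Every rejection records stage, subject and product length; retained and
rejected partition the input.

## Genome QC

Completeness/contamination are consumed as metadata (e.g., from an
assembly-QC tool), never computed. Genomes pass at completeness ≥ 90 %
and contamination ≤ 5 %; boundary values are retained, since the
filtered side is specified strictly (< 90 %, > 5 %). Genomes without a
QC record are retained with a warning (configurable input expectation:
the genome list should already be dereplicated; ANI dereplication is out
of scope).

## Synthetic pan-genome fixtures

The generator emulates the pipeline's input at desk scale: a star
phylogeny of `n_target_genomes` (default 5) sharing `n_core_genes`
(default 8) ancestral CDSs of 150–300 codons, mutated i.i.d. per site
with a 3:1 bias toward third codon positions (`substitution_prob`,
default 0.02, is the third-position rate; first/second positions mutate
at one third of it) — keeping amino-acid identity high while exercising
nucleotide degeneracy, the regime real clades present. Substitutions that
would create an in-frame stop revert their codon (a ≲ 5 % deflation of
the realized rate, accounted for in the statistical tests). Genes are
concatenated with uniform-random spacers (50–500 nt) into genome
sequences; off-target genomes are unrelated random gene arrays.

Planted primer sites are codon-aligned 21-mers sampled to satisfy the
default design constraints with Tm within 0.4 °C of the optimum (a
well-chosen qPCR site), written into chosen core genes and protected from
mutation. Decoy specs embed copies of one planted pair's sites, each with
an exact number of substitutions, into a non-target sequence at an
amplifiable spacing — ground truth for the stage-2 screen. Identical
config + seed yields byte-identical output.

What the fixtures do **not** model: tree-structured evolution (star
phylogeny only), indels inside genes, paralog families beyond explicit
duplication cases, compositional bias, or annotation errors. Passing
end-to-end tests therefore demonstrates correctness of the machinery
under controlled variation, not robustness to every artifact of real
assemblies.

## Determinism and numerical choices

The pipeline itself uses no randomness; all iteration orders are fixed
(sorted genome ids, input order, explicit tie-breaks), so identical
inputs give byte-identical reports — a tested contract. Internal
coordinates are 0-based half-open; report files are 1-based inclusive
(stated in the report header docs). Consensus ties break A < C < G < T <
gap; cluster centroids tie-break lexicographically; pair ranking
tie-breaks by coordinates. Tm comparisons in ranking round to 6 decimals
to keep float noise out of orderings.

## Known limitations

- Greedy centroid clustering is order-dependent by design (longest
  first); it matches the contract of standard tools but is not a graph-
  based orthology inference, and fragmented assemblies can split
  clusters.
- The self-complementarity heuristic does not compute folding ΔG; strong
  hairpins with loops are only caught through the complementary-run
  proxy.
- The specificity screen treats every template as amplifiable naked DNA;
  3'-mismatch extension efficiency is not modeled, so the mismatch cap is
  conservative.
- No resume-from-intermediate orchestration: stage artifacts (per-cluster
  alignments, tables) are re-loadable through the library, but the CLI
  always runs the full pipeline.
- Annotation of clusters against external protein databases (for naming
  the targeted gene) is out of scope; the report's annotation column is a
  pass-through.
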