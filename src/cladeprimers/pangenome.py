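"""Pan-genome gene clustering and single-copy core gene selection.

Input is the annotated gene catalog of a target clade: for every genome,
each protein-coding gene as a nucleotide CDS plus its amino-acid
translation.  Genes are grouped across genomes by greedy centroid
clustering on the protein sequences at an identity/coverage cut-off
(defaults 80% / 90%), and clusters present in exactly one copy in every
target genome are flagged as single-copy core — the gene families from
which clade-specific primers are designed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

_STOP_CODONS = {"TAA", "TAG", "TGA"}  # genetic code table 11


@dataclass(frozen=True)
class GeneRecord:
    """One CDS of one genome: paired nucleotide and amino-acid sequences.

    ``nt_seq`` excludes the terminal stop codon, so ``len(nt_seq) ==
    3 * len(aa_seq)`` always holds.  Use :meth:`from_cds` to build records
    from raw annotation output (strips the stop codon, checks the
    translation under the bacterial/archaeal code and warns on mismatch).
    """

    genome_id: str
    gene_id: str
    nt_seq: str
    aa_seq: str

    def __post_init__(self) -> None:
        if not self.nt_seq or not self.aa_seq:
            raise ValueError(f"{self.gene_id}: empty sequence")
        if len(self.nt_seq) != 3 * len(self.aa_seq):
            raise ValueError(
                f"{self.gene_id}: CDS length {len(self.nt_seq)} is not 3x the "
                f"protein length {len(self.aa_seq)}"
            )

    @classmethod
    def from_cds(cls, genome_id: str, gene_id: str, nt_seq: str, aa_seq: str) -> "GeneRecord":
        nt_seq = nt_seq.upper().replace("U", "T")
        aa_seq = aa_seq.upper().rstrip("*")
        if len(nt_seq) == 3 * len(aa_seq) + 3 and nt_seq[-3:] in _STOP_CODONS:
            nt_seq = nt_seq[:-3]
        rec = cls(genome_id, gene_id, nt_seq, aa_seq)
        translated = str(Seq(nt_seq).translate(table=11))
        # annotation pipelines disagree on start-codon translation; compare
        # past position 0 and warn rather than refuse
        if translated[1:] != aa_seq[1:]:
            warnings.warn(
                f"{gene_id}: CDS translation (table 11) disagrees with the "
                "supplied protein sequence",
                stacklevel=2,
            )
        return rec


@dataclass
class GeneCluster:
    """A set of genes grouped by protein similarity to a centroid."""

    cluster_id: str
    members: list[GeneRecord]
    centroid: str  # gene_id of the founding (longest) member
    is_single_copy_core: bool = False

    @property
    def genome_ids(self) -> list[str]:
        return [m.genome_id for m in self.members]

    def member(self, gene_id: str) -> GeneRecord:
        for m in self.members:
            if m.gene_id == gene_id:
                return m
        raise KeyError(gene_id)


def _make_aligner(mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


# glocal: full-length alignment with free end gaps on the target (longer)
# side, so a short sequence aligns contiguously inside a long one
_GLOCAL = _make_aligner("global")
try:
    _GLOCAL.end_insertion_score = 0.0
except AttributeError:  # older PairwiseAligner attribute name
    _GLOCAL.target_end_gap_score = 0.0


def pairwise_identity_coverage(a: str, b: str) -> tuple[float, float]:
    """Percent-identity and mutual coverage of two protein sequences.

    The shorter sequence is aligned end-to-end against the longer with free
    end gaps on the longer side (a "glocal" alignment, BLOSUM62, gap open
    -11 / extend -1).  Identity is matches over aligned (non-gap) columns.
    Coverage is bidirectional: min over both sequences of aligned span /
    sequence length, the convention of cov-mode 0 in common clustering
    tools — so a half-length fragment of a gene has coverage 0.5, not 1.0.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    aln = _GLOCAL.align(target, query)[0]
    t_blocks, q_blocks = aln.aligned
    matches = 0
    aligned_cols = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        aligned_cols += te - ts
        matches += sum(1 for i, j in zip(range(ts, te), range(qs, qe)) if target[i] == query[j])
    if aligned_cols == 0:
        return 0.0, 0.0
    identity = matches / aligned_cols
    t_span = (t_blocks[-1][1] - t_blocks[0][0]) / len(target)
    q_span = (q_blocks[-1][1] - q_blocks[0][0]) / len(query)
    return identity, min(t_span, q_span)


def cluster_genes(
    genes: Sequence[GeneRecord],
    min_identity: float = 0.80,
    min_coverage: float = 0.90,
) -> list[GeneCluster]:
    """Greedy centroid clustering of genes by protein similarity.

    Genes are visited in order of decreasing protein length (ties broken
    lexicographically by gene_id).  Each gene joins the first existing
    cluster whose centroid it matches at ≥ *min_identity* and
    ≥ *min_coverage*, else founds a new cluster with itself as centroid.
    The result partitions the input: every gene is in exactly one cluster.
    """
    if not genes:
        raise ValueError("no genes to cluster")
    order = sorted(genes, key=lambda g: (-len(g.aa_seq), g.gene_id))
    clusters: list[GeneCluster] = []
    centroids: list[GeneRecord] = []
    for gene in order:
        placed = False
        for cluster, centroid in zip(clusters, centroids):
            ident, cov = pairwise_identity_coverage(gene.aa_seq, centroid.aa_seq)
            if ident >= min_identity and cov >= min_coverage:
                cluster.members.append(gene)
                placed = True
                break
        if not placed:
            clusters.append(
                GeneCluster(
                    cluster_id=f"CL{len(clusters):04d}",
                    members=[gene],
                    centroid=gene.gene_id,
                )
            )
            centroids.append(gene)
    return clusters


def select_core_clusters(
    clusters: Iterable[GeneCluster], genome_ids: Iterable[str]
) -> list[GeneCluster]:
    """Single-copy core clusters: exactly one member in every target genome."""
    wanted = set(genome_ids)
    if not wanted:
        raise ValueError("empty target genome set")
    core: list[GeneCluster] = []
    for cluster in clusters:
        seen = cluster.genome_ids
        if set(seen) == wanted and len(seen) == len(wanted):
            cluster.is_single_copy_core = True
            core.append(cluster)
    return core


def parse_header(header: str, delimiter: str = "|") -> tuple[str, str]:
    """Split a FASTA id of the form ``genomeID|geneID``."""
    if delimiter not in header:
        raise ValueError(
            f"FASTA id {header!r} lacks the {delimiter!r} genome/gene delimiter"
        )
    genome_id, gene_id = header.split(delimiter, 1)
    return genome_id, gene_id


def read_gene_records(
    nt_fasta: str | Path,
    aa_fasta: str | Path,
    delimiter: str = "|",
) -> list[GeneRecord]:
    """Load paired nucleotide/protein CDS FASTA files into GeneRecords.

    Both files must use ``genomeID|geneID`` ids; every nucleotide record
    needs a protein partner and vice versa.
    """
    nt = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(nt_fasta), "fasta")}
    aa = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(aa_fasta), "fasta")}
    if nt.keys() != aa.keys():
        missing = sorted(nt.keys() ^ aa.keys())
        raise ValueError(f"unpaired ids between CDS and protein FASTA: {missing[:5]}")
    records = []
    for rec_id in nt:
        genome_id, gene_id = parse_header(rec_id, delimiter)
        records.append(GeneRecord.from_cds(genome_id, rec_id, nt[rec_id], aa[rec_id]))
    return records


def genes_by_genome(genes: Iterable[GeneRecord]) -> dict[str, list[GeneRecord]]:
    out: dict[str, list[GeneRecord]] = {}
    for g in genes:
        out.setdefault(g.genome_id, []).append(g)
    return out
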