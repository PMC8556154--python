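"""Protein alignment, codon-aware back-translation, and majority consensus.

Primers are nucleotide sequences, but homology within a core gene cluster
is best captured at the protein level.  Each cluster is therefore aligned
as proteins, the alignment is back-translated codon-by-codon into a
nucleotide (codon) alignment — each residue replaced by its source codon,
each gap by ``---`` — and a per-column majority consensus with recorded
variant sets drives primer design: the consensus supplies candidate
windows, the variant sets supply the degeneracies.

The built-in aligner is a center-star construction over pairwise global
BLOSUM62 alignments: exact pairwise alignments merged by gap propagation
around the longest member.  For the within-clade, high-identity clusters
this pipeline consumes, that is accurate and dependency-free; a
pre-computed alignment can also be imported from gapped FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .pangenome import GeneRecord, _make_aligner
from .seqcore import GAP

_GLOBAL = _make_aligner("global")


@dataclass
class ProteinAlignment:
    """Gapped amino-acid rows, keyed by gene_id, all the same length."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


@dataclass
class CodonAlignment:
    """Gapped nucleotide rows; column count is 3x the protein alignment."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


@dataclass
class ConsensusTrack:
    """Majority consensus plus the per-column sets of observed symbols.

    ``consensus[i]`` is the most frequent symbol of column i (ties broken
    A < C < G < T < '-'); ``variants[i]`` is every symbol observed there.
    Columns whose consensus is a gap are masked for primer design, as is
    any column whose variant set contains a gap — a primer cannot reliably
    span an indel polymorphism.
    """

    consensus: str
    variants: list[frozenset[str]]

    def __post_init__(self) -> None:
        if len(self.consensus) != len(self.variants):
            raise ValueError("consensus/variants length mismatch")

    @property
    def length(self) -> int:
        return len(self.consensus)

    def usable(self) -> list[bool]:
        """Per column: consensus is a concrete base and no gap variant."""
        return [
            c != GAP and GAP not in v
            for c, v in zip(self.consensus, self.variants)
        ]


def _merge_into_master(
    master: str, rows: dict[str, str], c_aln: str, o_aln: str, other_id: str
) -> tuple[str, dict[str, str]]:
    """Merge one pairwise (center, other) alignment into the master MSA.

    *master* is the center row as gapped so far; *c_aln*/*o_aln* are the
    center/other rows of the new pairwise alignment.  Gaps are propagated
    both ways (master gaps into the new row, new center gaps into all
    existing rows); center residues are never reordered, so "once a gap,
    always a gap" holds and every row degaps to its input exactly.
    """
    merged_master: list[str] = []
    new_rows: dict[str, list[str]] = {rid: [] for rid in rows}
    new_other: list[str] = []
    i = j = 0
    # both strings degap to the same center sequence, so whenever one side
    # shows a residue the other side eventually shows the same residue;
    # master gaps are consumed before new gaps for determinism
    while i < len(master) or j < len(c_aln):
        if i < len(master) and master[i] == GAP:
            # column exists only in the old master: keep old rows, pad new row
            merged_master.append(GAP)
            for rid in rows:
                new_rows[rid].append(rows[rid][i])
            new_other.append(GAP)
            i += 1
        elif j < len(c_aln) and c_aln[j] == GAP:
            # column exists only in the new pairwise alignment: pad old rows
            merged_master.append(GAP)
            for rid in rows:
                new_rows[rid].append(GAP)
            new_other.append(o_aln[j])
            j += 1
        else:
            # both advance on the same center residue
            merged_master.append(master[i])
            for rid in rows:
                new_rows[rid].append(rows[rid][i])
            new_other.append(o_aln[j])
            i += 1
            j += 1
    out_rows = {rid: "".join(chars) for rid, chars in new_rows.items()}
    out_rows[other_id] = "".join(new_other)
    return "".join(merged_master), out_rows


def align_protein_cluster(members: Mapping[str, str]) -> ProteinAlignment:
    """Center-star multiple alignment of a cluster's protein sequences.

    The center is the longest member (ties: lexicographically smallest
    gene_id); every other member is aligned to it globally (BLOSUM62,
    gap open -11 / extend -1) and the pairwise alignments are merged by
    gap propagation.  Row order follows the input mapping order.
    """
    if len(members) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    for gid, seq in members.items():
        if not seq:
            raise ValueError(f"{gid}: empty sequence")
    center_id = min(members, key=lambda g: (-len(members[g]), g))
    center_seq = members[center_id]
    master = center_seq
    rows: dict[str, str] = {}
    for gid, seq in members.items():
        if gid == center_id:
            continue
        aln = _GLOBAL.align(center_seq, seq)[0]
        c_aln, o_aln = str(aln[0]), str(aln[1])
        master, rows = _merge_into_master(master, rows, c_aln, o_aln, gid)
    rows[center_id] = master
    return ProteinAlignment(rows={gid: rows[gid] for gid in members})


def back_translate_alignment(
    aln: ProteinAlignment, members: Sequence[GeneRecord] | Mapping[str, str]
) -> CodonAlignment:
    """Replace each aligned residue by its source codon, each gap by ``---``.

    *members* supplies the CDS for every row, either as GeneRecords or as a
    gene_id → nucleotide-sequence mapping.  Degapping any output row
    returns the member's CDS exactly.
    """
    if isinstance(members, Mapping):
        nt_by_id = dict(members)
    else:
        nt_by_id = {m.gene_id: m.nt_seq for m in members}
    out: dict[str, str] = {}
    for gid, row in aln.rows.items():
        if gid not in nt_by_id:
            raise ValueError(f"no CDS supplied for aligned gene {gid}")
        nt = nt_by_id[gid]
        n_res = sum(1 for sym in row if sym != GAP)
        if len(nt) != 3 * n_res:
            raise ValueError(
                f"{gid}: CDS length {len(nt)} does not match {n_res} aligned residues"
            )
        codons: list[str] = []
        k = 0
        for sym in row:
            if sym == GAP:
                codons.append(GAP * 3)
            else:
                codons.append(nt[3 * k : 3 * k + 3])
                k += 1
        out[gid] = "".join(codons)
    return CodonAlignment(rows=out)


_TIE_ORDER = "ACGT" + GAP


def majority_consensus(aln: CodonAlignment) -> ConsensusTrack:
    """Per-column majority symbol with ties broken A < C < G < T < '-'.

    Row order never affects the result; the variant set of a column always
    contains its consensus symbol.
    """
    if len(aln.rows) < 2:
        raise ValueError("consensus needs at least 2 rows")
    rows = list(aln.rows.values())
    consensus: list[str] = []
    variants: list[frozenset[str]] = []
    for col in zip(*rows):
        counts: dict[str, int] = {}
        for sym in col:
            if sym not in _TIE_ORDER:
                raise ValueError(f"unexpected alignment symbol {sym!r}")
            counts[sym] = counts.get(sym, 0) + 1
        winner = max(counts, key=lambda s: (counts[s], -_TIE_ORDER.index(s)))
        consensus.append(winner)
        variants.append(frozenset(counts))
    return ConsensusTrack(consensus="".join(consensus), variants=variants)


def write_alignment_fasta(aln: ProteinAlignment | CodonAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid, row in aln.rows.items():
            fh.write(f">{gid}\n{row}\n")


def read_codon_alignment_fasta(path: str | Path) -> CodonAlignment:
    rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return CodonAlignment(rows=rows)
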