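"""In-silico PCR: degenerate primer binding sites and off-target screening.

A primer pair amplifies a subject when the forward primer binds the plus
strand upstream of a reverse-primer binding site on the minus strand,
within a product-size window.  Binding is modeled as an ungapped placement
of the primer (full-length, or 5'-truncated down to a coverage floor — the
3' end must stay anchored for extension) with at most a configured number
of IUPAC-compatibility mismatches.  Placements covering ≤ 80% of the
primer are not considered viable hits.

Screening is two-staged: a pair is first rejected if it amplifies any
*other* gene of the target clade's own catalog (within-clade off-target),
then if it amplifies anything in the non-target set, in both cases for
predicted products inside the off-target size window (default 30–2000 bp).
Amplicons on the pair's own cluster are the intended signal and never
cause rejection.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .pangenome import GeneRecord
from .primer_design import DegeneratePrimerPair
from .seqcore import IUPAC_TO_BASES, normalize, reverse_complement

#: bitmask encoding: A=1, C=2, G=4, T=8; degenerate codes OR their bases
_CODE_MASK = {
    code: np.uint8(sum(1 << "ACGT".index(b) for b in bases))
    for code, bases in IUPAC_TO_BASES.items()
}


def encode(seq: str) -> np.ndarray:
    """Encode an IUPAC sequence as a base-set bitmask array."""
    seq = normalize(seq)
    return np.frombuffer(
        bytes(int(_CODE_MASK[sym]) for sym in seq), dtype=np.uint8
    ).copy()


@functools.lru_cache(maxsize=4096)
def _encode_cached(seq: str) -> np.ndarray:
    out = encode(seq)
    out.setflags(write=False)
    return out


@dataclass(frozen=True)
class PrimerHit:
    """One viable primer placement on a subject sequence.

    ``start``/``end`` are 0-based half-open plus-strand coordinates of the
    placed (possibly truncated) primer; ``coverage`` is the placed length
    over the full primer length; mismatches are IUPAC-incompatible
    positions.  On the minus strand the primer's 3' end maps to ``start``.
    """

    subject_id: str
    strand: str  # '+' or '-'
    start: int
    end: int
    coverage: float
    mismatches: int
    role: str = ""  # 'forward' or 'reverse' when part of a pair screen


@dataclass(frozen=True)
class AmpliconHit:
    """A predicted PCR product: forward hit upstream of a reverse hit."""

    subject_id: str
    forward: PrimerHit
    reverse: PrimerHit
    product_length: int  # outer edge to outer edge, both primers included
    classification: str = ""


@dataclass(frozen=True)
class Rejection:
    """Why a primer pair was screened out, with the triggering amplicon."""

    pair: DegeneratePrimerPair
    stage: str  # 'target_gene' or 'non_target'
    subject_id: str
    product_length: int


@dataclass
class ScreenResult:
    retained: list[DegeneratePrimerPair]
    rejected: list[Rejection]


def _min_placement_length(primer_len: int, min_coverage: float) -> int:
    """Shortest placed length with coverage strictly above the floor."""
    length = int(np.floor(primer_len * min_coverage)) + 1
    # coverage must be strictly greater than the floor; nudge across any
    # floating-point edge in either direction
    while length <= primer_len and length / primer_len <= min_coverage:
        length += 1
    while length > 1 and (length - 1) / primer_len > min_coverage:
        length -= 1
    return min(length, primer_len + 1)


def find_primer_hits(
    primer: str,
    subject: str,
    subject_id: str = "",
    max_mismatches: int = 3,
    min_coverage: float = 0.8,
    role: str = "",
) -> list[PrimerHit]:
    """All viable placements of a degenerate primer on both subject strands.

    For each strand, the primer is slid along the subject at full length
    and at every 5'-truncated length whose coverage stays strictly above
    *min_coverage* (3'-anchored truncation only: a shortened 5' end still
    extends, a lost 3' end does not).  A placement is viable with at most
    *max_mismatches* IUPAC-incompatible positions.  Overlapping placements
    sharing a strand and 3'-end position are reported once, at the longest
    viable length.  Hits are ordered by (start, end, strand).
    """
    primer = normalize(primer)
    plen = len(primer)
    if plen == 0:
        raise ValueError("empty primer")
    sub = _encode_cached(subject)
    if min(len(sub), plen) == 0 or len(sub) < _min_placement_length(plen, min_coverage):
        return []
    pat_plus = _encode_cached(primer)
    pat_minus = _encode_cached(reverse_complement(primer))
    floor_len = _min_placement_length(plen, min_coverage)
    best: dict[tuple[str, int], tuple[int, int, int]] = {}  # (strand, 3'pos) -> (len, start, mm)
    for length in range(floor_len, plen + 1):
        if length > len(sub):
            continue
        for strand, pattern in (("+", pat_plus[plen - length :]), ("-", pat_minus[:length])):
            windows = np.lib.stride_tricks.sliding_window_view(sub, length)
            mismatches = ((windows & pattern) == 0).sum(axis=1)
            for start in np.nonzero(mismatches <= max_mismatches)[0]:
                start = int(start)
                mm = int(mismatches[start])
                # 3' end: rightmost base on '+', leftmost on '-'
                anchor = start + length - 1 if strand == "+" else start
                key = (strand, anchor)
                prev = best.get(key)
                if prev is None or length > prev[0]:
                    best[key] = (length, start, mm)
    hits = [
        PrimerHit(
            subject_id=subject_id,
            strand=strand,
            start=start,
            end=start + length,
            coverage=length / plen,
            mismatches=mm,
            role=role,
        )
        for (strand, _anchor), (length, start, mm) in best.items()
    ]
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def predict_amplicons(
    fwd_hits: Iterable[PrimerHit],
    rev_hits: Iterable[PrimerHit],
    size_min: int,
    size_max: int,
) -> list[AmpliconHit]:
    """All plus-strand-forward / minus-strand-reverse product predictions.

    Product length runs from the forward hit's outer (5') edge to the
    reverse hit's outer (5') edge, both primers included; hit pairs must
    not overlap and must fall inside [size_min, size_max].
    """
    amps: list[AmpliconHit] = []
    for f in fwd_hits:
        if f.strand != "+":
            continue
        for r in rev_hits:
            if r.strand != "-":
                continue
            if f.subject_id != r.subject_id:
                continue
            if r.start < f.end:
                continue
            product = r.end - f.start
            if size_min <= product <= size_max:
                amps.append(
                    AmpliconHit(
                        subject_id=f.subject_id,
                        forward=f,
                        reverse=r,
                        product_length=product,
                    )
                )
    amps.sort(key=lambda a: (a.forward.start, a.product_length, a.reverse.start))
    return amps


def _first_amplicon(
    pair: DegeneratePrimerPair,
    subject_id: str,
    subject_seq: str,
    size_min: int,
    size_max: int,
    max_mismatches: int,
    min_coverage: float,
    hit_cache: Optional[dict] = None,
) -> Optional[AmpliconHit]:
    def hits(primer: str, role: str) -> list[PrimerHit]:
        # many pairs share primer windows; cache scans per (primer, subject)
        if hit_cache is None:
            return find_primer_hits(
                primer, subject_seq, subject_id, max_mismatches, min_coverage, role
            )
        key = (primer, subject_id, role)
        if key not in hit_cache:
            hit_cache[key] = find_primer_hits(
                primer, subject_seq, subject_id, max_mismatches, min_coverage, role
            )
        return hit_cache[key]

    fwd_hits = hits(pair.forward, "forward")
    if not fwd_hits:
        return None
    rev_hits = hits(pair.reverse, "reverse")
    amps = predict_amplicons(fwd_hits, rev_hits, size_min, size_max)
    return amps[0] if amps else None


def screen_primer_pairs(
    pairs: Sequence[DegeneratePrimerPair],
    target_genes_by_genome: Mapping[str, Sequence[GeneRecord]],
    gene_to_cluster: Mapping[str, str],
    non_target_seqs: Sequence[tuple[str, str]],
    off_target_window: tuple[int, int] = (30, 2000),
    max_mismatches: int = 3,
    min_coverage: float = 0.8,
) -> ScreenResult:
    """Two-stage off-target screen over a set of candidate pairs.

    Stage 1 rejects a pair that predicts an amplicon inside
    *off_target_window* on any target-clade gene outside its own cluster;
    stage 2 rejects on any non-target sequence.  Every rejection records
    the stage, the offending subject and the product length.  The
    retained and rejected lists partition the input, in input order;
    subjects are visited in sorted-genome then catalog order, so the
    result is independent of mapping iteration order.
    """
    size_min, size_max = off_target_window
    retained: list[DegeneratePrimerPair] = []
    rejected: list[Rejection] = []
    genome_order = sorted(target_genes_by_genome)
    hit_cache: dict = {}
    for pair in pairs:
        verdict: Optional[Rejection] = None
        for genome_id in genome_order:
            for gene in target_genes_by_genome[genome_id]:
                if gene_to_cluster.get(gene.gene_id) == pair.cluster_id:
                    continue  # the pair's own target: never a rejection
                amp = _first_amplicon(
                    pair, gene.gene_id, gene.nt_seq, size_min, size_max,
                    max_mismatches, min_coverage, hit_cache,
                )
                if amp is not None:
                    verdict = Rejection(pair, "target_gene", gene.gene_id, amp.product_length)
                    break
            if verdict:
                break
        if verdict is None:
            for subject_id, seq in non_target_seqs:
                amp = _first_amplicon(
                    pair, subject_id, seq, size_min, size_max,
                    max_mismatches, min_coverage, hit_cache,
                )
                if amp is not None:
                    verdict = Rejection(pair, "non_target", subject_id, amp.product_length)
                    break
        if verdict is None:
            retained.append(pair)
        else:
            rejected.append(verdict)
    return ScreenResult(retained=retained, rejected=rejected)


def hits_table_rows(hits: Iterable[PrimerHit]) -> list[dict]:
    """Flatten hits for TSV export (documented column order)."""
    return [
        {
            "subject_id": h.subject_id,
            "role": h.role,
            "strand": h.strand,
            "start": h.start + 1,  # 1-based inclusive in reports
            "end": h.end,
            "coverage": round(h.coverage, 4),
            "mismatches": h.mismatches,
        }
        for h in hits
    ]
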