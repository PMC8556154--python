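"""IUPAC nucleotide ambiguity-code algebra.

A degenerate oligonucleotide is written over the 15-letter IUPAC alphabet,
where each letter stands for a non-empty set of concrete bases (M = {A,C},
N = {A,C,G,T}, ...).  The oligo denotes the pool of all concrete sequences
obtained by choosing one base per position; the pool size is the *total
degeneracy*, the product over positions of each code's cardinality.

Everything downstream — consensus-based primer design, degeneracy budgets,
IUPAC-aware in-silico PCR — reduces to the handful of set operations
defined here.  Sequences are plain ``str`` objects, 5'→3', uppercase
canonical; lowercase and RNA ``U`` are accepted on input.  The gap symbol
``-`` belongs to alignments, never to primers: operations in this module
reject it unless explicitly told otherwise.
"""

from __future__ import annotations

import itertools
from typing import Iterable, NamedTuple

#: concrete-base set denoted by each IUPAC code
IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_BASES.items()}

IUPAC_CODES: frozenset[str] = frozenset(IUPAC_TO_BASES)
CONCRETE_BASES = "ACGT"
GAP = "-"

_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: IUPAC-aware complement table (M↔K, R↔Y, B↔V, D↔H, N↔N, ...)
IUPAC_COMPLEMENT: dict[str, str] = {
    code: BASES_TO_IUPAC[frozenset(_COMPLEMENT_BASE[b] for b in bases)]
    for code, bases in IUPAC_TO_BASES.items()
}
IUPAC_COMPLEMENT[GAP] = GAP


class DegeneracyStats(NamedTuple):
    """Degeneracy summary of one primer.

    total
        product of per-position code cardinalities (= expansion-pool size).
    n_degenerate
        number of positions carrying a non-concrete code.
    n_three_prime
        number of degenerate positions within the 3'-terminal window.
    """

    total: int
    n_degenerate: int
    n_three_prime: int


def normalize(seq: str, allow_gaps: bool = False) -> str:
    """Return the canonical form of *seq*: uppercase, U→T, validated.

    Raises ``ValueError`` on any symbol outside the IUPAC alphabet, or on a
    gap unless *allow_gaps* is set.
    """
    out = seq.upper().replace("U", "T")
    for sym in out:
        if sym in IUPAC_CODES:
            continue
        if sym == GAP and allow_gaps:
            continue
        if sym == GAP:
            raise ValueError("gap symbol '-' is not permitted outside alignments")
        raise ValueError(f"invalid IUPAC nucleotide code: {sym!r}")
    return out


def iupac_union(bases: Iterable[str]) -> str:
    """Minimal single IUPAC code covering the union of the inputs' base sets.

    ``{A, C} → M``; ``{A, C, G, T} → N``; idempotent and order-independent.
    """
    union: set[str] = set()
    n = 0
    for code in bases:
        code = normalize(code)
        if len(code) != 1:
            raise ValueError(f"expected single codes, got {code!r}")
        union.update(IUPAC_TO_BASES[code])
        n += 1
    if n == 0:
        raise ValueError("iupac_union of an empty set is undefined")
    return BASES_TO_IUPAC[frozenset(union)]


def iupac_expansions(seq: str, max_expansions: int | None = None) -> set[str]:
    """All concrete (A/C/G/T-only) sequences compatible with *seq*.

    The result size equals the total degeneracy.  *max_expansions*, if
    given, bounds the pool size; exceeding it raises ``ValueError`` before
    any enumeration work is done.
    """
    seq = normalize(seq)
    if not seq:
        raise ValueError("cannot expand an empty sequence")
    total = degeneracy_total(seq)
    if max_expansions is not None and total > max_expansions:
        raise ValueError(
            f"total degeneracy {total} exceeds the expansion cap {max_expansions}"
        )
    pools = [sorted(IUPAC_TO_BASES[sym]) for sym in seq]
    return {"".join(combo) for combo in itertools.product(*pools)}


def degeneracy_total(seq: str) -> int:
    """Total degeneracy: product of per-position code cardinalities."""
    seq = normalize(seq)
    total = 1
    for sym in seq:
        total *= len(IUPAC_TO_BASES[sym])
    return total


def degeneracy_of(seq: str, three_prime_window: int = 5) -> DegeneracyStats:
    """Degeneracy statistics of a primer, including the 3'-window count.

    The 3' window is the final *three_prime_window* symbols of the 5'→3'
    sequence — the extension-critical end where ambiguity is least
    tolerated by the polymerase.
    """
    seq = normalize(seq)
    if three_prime_window > len(seq):
        raise ValueError(
            f"3' window ({three_prime_window}) longer than sequence ({len(seq)})"
        )
    total = 1
    n_degen = 0
    for sym in seq:
        card = len(IUPAC_TO_BASES[sym])
        total *= card
        if card > 1:
            n_degen += 1
    tail = seq[len(seq) - three_prime_window :] if three_prime_window else ""
    n_three = sum(1 for sym in tail if len(IUPAC_TO_BASES[sym]) > 1)
    return DegeneracyStats(total, n_degen, n_three)


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement; an involution that preserves degeneracy."""
    seq = normalize(seq, allow_gaps=True)
    return "".join(IUPAC_COMPLEMENT[sym] for sym in reversed(seq))


def is_compatible(code_a: str, code_b: str) -> bool:
    """True iff the two codes' concrete-base sets intersect.

    This is the per-position match predicate of the in-silico PCR screen:
    a degenerate primer position can pair with a subject base whenever at
    least one concrete expansion matches it.
    """
    a = normalize(code_a)
    b = normalize(code_b)
    if len(a) != 1 or len(b) != 1:
        raise ValueError("is_compatible expects single IUPAC codes")
    return not IUPAC_TO_BASES[a].isdisjoint(IUPAC_TO_BASES[b])


def gc_fraction(seq: str) -> float:
    """Fraction of positions whose code is a subset of {G, C}.

    Degenerate codes count as G/C only when every concrete base they denote
    is G or C (S counts; R, N do not) — a conservative GC measure for
    degenerate primers.
    """
    seq = normalize(seq)
    if not seq:
        raise ValueError("gc_fraction of an empty sequence")
    gc = sum(1 for sym in seq if IUPAC_TO_BASES[sym] <= frozenset("GC"))
    return gc / len(seq)


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest run of one identical symbol."""
    seq = normalize(seq)
    best = run = 0
    prev = ""
    for sym in seq:
        run = run + 1 if sym == prev else 1
        prev = sym
        best = max(best, run)
    return best
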