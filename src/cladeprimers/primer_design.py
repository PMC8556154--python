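"""Degenerate primer-pair design on a cluster consensus.

The design problem: a reference primer designer works on one concrete
sequence, but a core gene cluster is an alignment.  The pipeline therefore
(1) enumerates candidate forward/reverse windows on the cluster's majority
consensus under length, melting-temperature, GC, homopolymer,
self-complementarity, pair-ΔTm and product-size constraints, (2) maps each
retained window back onto the alignment and widens every position to the
IUPAC union of the bases observed in that column — so the degenerate
primer covers all recorded variation, never more — and (3) filters pairs
on degeneracy budgets: total degeneracy per primer and, separately, the
number of degenerate codes in the extension-critical 3' window (default:
none allowed in the final five nucleotides).

Melting temperatures use the SantaLucia (1998) unified nearest-neighbor
parameters with the entropic salt correction 0.368·(N−1)·ln[Mon+], where
the monovalent-equivalent cation concentration is Na+ + 120·√[Mg2+]
(total divalent; mM), and the duplex association constant CT/4 at the
oligo concentration.  The Tm of a degenerate primer is the arithmetic
mean over all of its concrete expansions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from . import seqcore
from .msa import ConsensusTrack
from .seqcore import DegeneracyStats, degeneracy_of, iupac_expansions, iupac_union, reverse_complement

# SantaLucia 1998 unified NN parameters: ΔH kcal/mol, ΔS cal/(mol·K)
_NN: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# duplex initiation terms per terminal base pair
_INIT: dict[str, tuple[float, float]] = {
    "A": (2.3, 4.1), "T": (2.3, 4.1),
    "G": (0.1, -2.8), "C": (0.1, -2.8),
}
_R = 1.987  # gas constant, cal/(mol·K)


@dataclass(frozen=True)
class ReactionConditions:
    """PCR mix composition entering the Tm model.

    oligo_nM
        primer concentration (nM); the association term uses CT/4.
    monovalent_mM, divalent_mM
        Na+/K+ and Mg2+ concentrations (mM); the divalent contribution is
        folded into a monovalent equivalent as 120·√[Mg2+].
    dntp_mM
        dNTP concentration (mM); carried for reporting and future
        corrections, not part of the default salt equivalence.
    """

    oligo_nM: float = 50.0
    monovalent_mM: float = 50.0
    divalent_mM: float = 1.5
    dntp_mM: float = 0.6

    def __post_init__(self) -> None:
        for name in ("oligo_nM", "monovalent_mM", "divalent_mM", "dntp_mM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.oligo_nM == 0 or (self.monovalent_mM == 0 and self.divalent_mM == 0):
            raise ValueError("oligo and cation concentrations must be positive")

    @property
    def monovalent_equivalent_M(self) -> float:
        return (self.monovalent_mM + 120.0 * math.sqrt(self.divalent_mM)) / 1000.0


@dataclass(frozen=True)
class DesignConstraints:
    """Primer/probe design constraints (lengths nt, temperatures °C)."""

    primer_len_min: int = 18
    primer_len_opt: int = 20
    primer_len_max: int = 25
    tm_min: float = 57.0
    tm_opt: float = 60.0
    tm_max: float = 63.0
    max_pair_tm_diff: float = 3.0
    gc_min: float = 0.30
    gc_max: float = 0.70
    max_homopolymer: int = 4
    product_min: int = 70
    product_max: int = 1000
    max_total_degeneracy: int = 32
    max_three_prime_degeneracy: int = 0
    three_prime_window: int = 5
    max_self_comp_run: int = 8
    probe_tm_offset: float = 8.0
    # screening budget: how many ranked pairs per cluster proceed to the
    # specificity screen and the report; effectively exhaustive at desk
    # scale, a tractability bound on genome-scale consensus tracks
    max_pairs_per_cluster: int = 2000

    def __post_init__(self) -> None:
        for lo, opt, hi in (
            (self.primer_len_min, self.primer_len_opt, self.primer_len_max),
            (self.tm_min, self.tm_opt, self.tm_max),
        ):
            if not (0 < lo <= opt <= hi):
                raise ValueError("constraint triples must satisfy 0 < min <= opt <= max")
        if not (0 < self.product_min <= self.product_max):
            raise ValueError("product size bounds must satisfy 0 < min <= max")
        if not (0.0 <= self.gc_min <= self.gc_max <= 1.0):
            raise ValueError("GC bounds must lie in [0, 1] with min <= max")
        if self.three_prime_window > self.primer_len_min:
            raise ValueError("3' window cannot exceed the minimum primer length")


@dataclass(frozen=True)
class Probe(object):
    """Internal hydrolysis probe between the two primers (plus strand)."""

    seq: str
    start: int
    end: int
    mean_tm: float
    degeneracy: DegeneracyStats


@dataclass(frozen=True, slots=True)
class DegeneratePrimerPair:
    """A forward/reverse primer pair anchored on a cluster consensus.

    Both primers are written 5'→3'; the reverse primer is the reverse
    complement of its consensus window.  Coordinates are 0-based
    half-open on the consensus; ``product_length = rev_end - fwd_start``.
    Tm fields are means over all concrete expansions.
    """

    cluster_id: str
    forward: str
    reverse: str
    fwd_start: int
    fwd_end: int
    rev_start: int
    rev_end: int
    fwd_tm: float
    rev_tm: float
    fwd_degeneracy: DegeneracyStats
    rev_degeneracy: DegeneracyStats
    probe: Optional[Probe] = None

    @property
    def product_length(self) -> int:
        return self.rev_end - self.fwd_start


def melting_temperature(seq: str, cond: ReactionConditions = ReactionConditions()) -> float:
    """Nearest-neighbor duplex Tm (°C) of a concrete primer sequence.

    SantaLucia 1998 unified parameters with terminal initiation terms,
    entropy salt correction at the monovalent-equivalent concentration,
    and ΔG association at CT/4.  Degenerate input is refused — average
    over expansions with :func:`mean_primer_tm` instead.
    """
    seq = seqcore.normalize(seq)
    if any(sym not in "ACGT" for sym in seq):
        raise ValueError("melting_temperature requires a concrete A/C/G/T sequence")
    if len(seq) < 8:
        raise ValueError("sequence too short for the nearest-neighbor model (< 8 nt)")
    dh, ds = 0.0, 0.0
    for terminal in (seq[0], seq[-1]):
        h, s = _INIT[terminal]
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(cond.monovalent_equivalent_M)
    ct = cond.oligo_nM * 1e-9
    return dh * 1000.0 / (ds + _R * math.log(ct / 4.0)) - 273.15


def mean_primer_tm(
    primer: str,
    cond: ReactionConditions = ReactionConditions(),
    max_expansions: int = 512,
) -> float:
    """Mean nearest-neighbor Tm over every concrete expansion of *primer*."""
    expansions = sorted(iupac_expansions(primer, max_expansions=max_expansions))
    return sum(melting_temperature(e, cond) for e in expansions) / len(expansions)


def max_self_complementary_run(seq: str) -> int:
    """Longest k such that some k-mer's reverse complement is also in *seq*.

    A cheap self-annealing screen: long self-complementary stretches allow
    the primer (or primer pool) to fold or dimerize.  IUPAC-aware via the
    compatibility predicate.
    """
    seq = seqcore.normalize(seq)
    n = len(seq)
    rc = reverse_complement(seq)
    best = 0
    # longest common compatible substring of seq and its reverse complement
    prev = [0] * (n + 1)
    for i in range(1, n + 1):
        cur = [0] * (n + 1)
        for j in range(1, n + 1):
            if seqcore.is_compatible(seq[i - 1], rc[j - 1]):
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def _window_ok(
    seq: str, constraints: DesignConstraints, cond: ReactionConditions
) -> Optional[float]:
    """Tm if the concrete window passes all single-primer filters, else None."""
    gc = seqcore.gc_fraction(seq)
    if not (constraints.gc_min <= gc <= constraints.gc_max):
        return None
    if seqcore.max_homopolymer_run(seq) > constraints.max_homopolymer:
        return None
    tm = melting_temperature(seq, cond)
    if not (constraints.tm_min <= tm <= constraints.tm_max):
        return None
    if max_self_complementary_run(seq) > constraints.max_self_comp_run:
        return None
    return tm


def _valid_windows(
    track: ConsensusTrack, constraints: DesignConstraints, cond: ReactionConditions
) -> list[tuple[int, int, float]]:
    """All (start, end, consensus Tm) windows passing single-primer filters.

    Windows must avoid masked columns and columns with gap variants;
    validity is orientation-independent (Tm, GC, homopolymer and
    self-complementarity are strand-symmetric), so one scan serves both
    the forward and the reverse role.
    """
    usable = track.usable()
    # prefix sums for O(1) "window fully usable" queries
    pref = [0]
    for u in usable:
        pref.append(pref[-1] + (1 if u else 0))
    windows: list[tuple[int, int, float]] = []
    for length in range(constraints.primer_len_min, constraints.primer_len_max + 1):
        for start in range(0, track.length - length + 1):
            end = start + length
            if pref[end] - pref[start] != length:
                continue
            tm = _window_ok(track.consensus[start:end], constraints, cond)
            if tm is not None:
                windows.append((start, end, tm))
    return windows


def enumerate_candidates(
    track: ConsensusTrack,
    constraints: DesignConstraints = DesignConstraints(),
    cond: ReactionConditions = ReactionConditions(),
    cluster_id: str = "",
) -> list[DegeneratePrimerPair]:
    """All concrete consensus primer pairs satisfying the constraints.

    Pairs are built from every valid forward window and every valid,
    non-overlapping reverse window downstream of it whose product length
    (reverse window end − forward window start) lies in the configured
    range and whose Tm difference is within ``max_pair_tm_diff``.  The
    output order is deterministic: forward start, then product length,
    then forward length.  An empty list is a valid outcome.
    """
    if track.length < constraints.product_min:
        return []
    windows = _valid_windows(track, constraints, cond)
    by_end: list[tuple[int, int, float]] = sorted(windows, key=lambda w: w[1])
    pairs: list[DegeneratePrimerPair] = []
    for fs, fe, ftm in windows:
        for rs, re, rtm in by_end:
            product = re - fs
            if product < constraints.product_min:
                continue
            if product > constraints.product_max:
                break
            if rs < fe:
                continue
            if abs(ftm - rtm) > constraints.max_pair_tm_diff:
                continue
            fwd = track.consensus[fs:fe]
            rev = reverse_complement(track.consensus[rs:re])
            # consensus windows are concrete by construction (masked and
            # gap-variant columns were excluded), so stats are trivial
            concrete = DegeneracyStats(1, 0, 0)
            pairs.append(
                DegeneratePrimerPair(
                    cluster_id=cluster_id,
                    forward=fwd,
                    reverse=rev,
                    fwd_start=fs,
                    fwd_end=fe,
                    rev_start=rs,
                    rev_end=re,
                    fwd_tm=ftm,
                    rev_tm=rtm,
                    fwd_degeneracy=concrete,
                    rev_degeneracy=concrete,
                )
            )
    pairs.sort(key=lambda p: (p.fwd_start, p.product_length, p.fwd_end - p.fwd_start, p.rev_start))
    return pairs


def _degenerate_window(
    track: ConsensusTrack,
    start: int,
    end: int,
    cond: ReactionConditions,
    constraints: DesignConstraints,
    cache: Optional[dict] = None,
    tm_cap: int = 512,
) -> Optional[tuple[str, DegeneracyStats, Optional[float]]]:
    """IUPAC-widened plus-strand window, its stats, and its mean Tm.

    Returns None when any column's variant set contains a gap.  The mean
    Tm is None when the expansion pool exceeds *tm_cap* (such primers are
    over budget anyway).  *cache* memoizes by (start, end) so that pairs
    sharing a window do not recompute expansions.
    """
    key = (start, end)
    if cache is not None and key in cache:
        return cache[key]
    symbols: list[str] = []
    result: Optional[tuple[str, DegeneracyStats, Optional[float]]]
    for i in range(start, end):
        variants = track.variants[i]
        if seqcore.GAP in variants:
            symbols = []
            break
        symbols.append(iupac_union(variants))
    if not symbols:
        result = None
    else:
        seq = "".join(symbols)
        stats = degeneracy_of(seq, constraints.three_prime_window)
        tm = mean_primer_tm(seq, cond, tm_cap) if stats.total <= tm_cap else None
        result = (seq, stats, tm)
    if cache is not None:
        cache[key] = result
    return result


def add_degeneracies(
    pair: DegeneratePrimerPair,
    track: ConsensusTrack,
    cond: ReactionConditions = ReactionConditions(),
    constraints: DesignConstraints = DesignConstraints(),
    cache: Optional[dict] = None,
) -> Optional[DegeneratePrimerPair]:
    """Widen both primers to the IUPAC union of their columns' variants.

    Each primer position becomes the union code of every base observed in
    its alignment column, so the primer pool covers exactly the recorded
    variation.  The reverse primer is complemented after widening.  Mean
    Tms are recomputed over the expansion pools.  Returns None (rejected,
    not raised) when a window overlaps a column with a gap variant.
    """
    if pair.fwd_start < 0 or pair.rev_end > track.length:
        raise ValueError("primer pair lies outside the consensus track")
    fwd = _degenerate_window(track, pair.fwd_start, pair.fwd_end, cond, constraints, cache)
    rev = _degenerate_window(track, pair.rev_start, pair.rev_end, cond, constraints, cache)
    if fwd is None or rev is None:
        return None
    fwd_seq, fwd_stats, fwd_tm = fwd
    rev_plus, _, rev_tm = rev
    rev_seq = reverse_complement(rev_plus)
    rev_stats = degeneracy_of(rev_seq, constraints.three_prime_window)
    return replace(
        pair,
        forward=fwd_seq,
        reverse=rev_seq,
        fwd_tm=fwd_tm if fwd_tm is not None else float("nan"),
        rev_tm=rev_tm if rev_tm is not None else float("nan"),
        fwd_degeneracy=fwd_stats,
        rev_degeneracy=rev_stats,
    )


def filter_degeneracy(
    pairs: Iterable[DegeneratePrimerPair],
    constraints: DesignConstraints = DesignConstraints(),
) -> list[DegeneratePrimerPair]:
    """Keep pairs whose primers respect both degeneracy budgets.

    Both primers must have total degeneracy ≤ ``max_total_degeneracy`` and
    at most ``max_three_prime_degeneracy`` degenerate codes in their
    3'-terminal window (default: zero in the final five nucleotides).
    Monotone: relaxing either budget never drops a retained pair.
    """
    kept = []
    for pair in pairs:
        if pair.fwd_degeneracy.total > constraints.max_total_degeneracy:
            continue
        if pair.rev_degeneracy.total > constraints.max_total_degeneracy:
            continue
        if pair.fwd_degeneracy.n_three_prime > constraints.max_three_prime_degeneracy:
            continue
        if pair.rev_degeneracy.n_three_prime > constraints.max_three_prime_degeneracy:
            continue
        kept.append(pair)
    return kept


def rank_pairs(
    pairs: Iterable[DegeneratePrimerPair],
    constraints: DesignConstraints = DesignConstraints(),
) -> list[DegeneratePrimerPair]:
    """Order pairs best-first: lowest combined degeneracy, then Tm fit.

    Mirrors the selection rationale for a final qPCR pair — low overall
    degeneracy and melting temperatures close to the optimum — with
    coordinates as the final deterministic tie-break.
    """

    def key(p: DegeneratePrimerPair):
        tm_dev = abs(p.fwd_tm - constraints.tm_opt) + abs(p.rev_tm - constraints.tm_opt)
        return (
            p.fwd_degeneracy.total + p.rev_degeneracy.total,
            round(tm_dev, 6),
            p.fwd_start,
            p.product_length,
            p.rev_start,
        )

    return sorted(pairs, key=key)


def design_cluster_pairs(
    track: ConsensusTrack,
    constraints: DesignConstraints = DesignConstraints(),
    cond: ReactionConditions = ReactionConditions(),
    cluster_id: str = "",
) -> list[DegeneratePrimerPair]:
    """Enumerate → widen → budget-filter → rank → cap, fused per cluster.

    Produces the same retained set as running :func:`enumerate_candidates`,
    :func:`add_degeneracies`, :func:`filter_degeneracy` and
    :func:`rank_pairs` in sequence and keeping the top
    ``max_pairs_per_cluster`` unique pairs — but filters at the *window*
    level first (degeneracy budgets are per primer) and only materializes
    the capped winners, so a conserved consensus with hundreds of valid
    windows does not allocate hundreds of thousands of pair objects.
    """
    if track.length < constraints.product_min:
        return []
    windows = _valid_windows(track, constraints, cond)
    cache: dict = {}
    tm_cap = 512
    # widen each window once; a window can serve as a forward site, a
    # reverse site (3' budget checked on the complemented end), or both
    fwd_ok: list[tuple] = []  # (start, end, seq, stats, mean_tm, consensus_tm)
    rev_ok: list[tuple] = []
    for start, end, cons_tm in windows:
        widened = _degenerate_window(track, start, end, cond, constraints, cache, tm_cap)
        if widened is None:
            continue
        seq, stats, mean_tm = widened
        if mean_tm is None or stats.total > constraints.max_total_degeneracy:
            continue
        if stats.n_three_prime <= constraints.max_three_prime_degeneracy:
            fwd_ok.append((start, end, seq, stats, mean_tm, cons_tm))
        rev_seq = reverse_complement(seq)
        rev_stats = degeneracy_of(rev_seq, constraints.three_prime_window)
        if rev_stats.n_three_prime <= constraints.max_three_prime_degeneracy:
            rev_ok.append((start, end, rev_seq, rev_stats, mean_tm, cons_tm))
    rev_by_end = sorted(rev_ok, key=lambda w: w[1])
    opt = constraints.tm_opt
    scored: list[tuple[tuple, tuple, tuple]] = []
    for fwd in fwd_ok:
        fs, fe, _fseq, fstats, ftm, fcons_tm = fwd
        for rev in rev_by_end:
            rs, re, _rseq, rstats, rtm, rcons_tm = rev
            product = re - fs
            if product < constraints.product_min:
                continue
            if product > constraints.product_max:
                break
            if rs < fe:
                continue
            if abs(fcons_tm - rcons_tm) > constraints.max_pair_tm_diff:
                continue
            rank_key = (
                fstats.total + rstats.total,
                round(abs(ftm - opt) + abs(rtm - opt), 6),
                fs,
                product,
                rs,
            )
            scored.append((rank_key, fwd, rev))
    scored.sort(key=lambda t: t[0])
    out: list[DegeneratePrimerPair] = []
    seen: set[tuple[str, str]] = set()
    for _key, fwd, rev in scored:
        fs, fe, fseq, fstats, ftm, _ = fwd
        rs, re, rseq, rstats, rtm, _ = rev
        if (fseq, rseq) in seen:
            continue
        seen.add((fseq, rseq))
        out.append(
            DegeneratePrimerPair(
                cluster_id=cluster_id,
                forward=fseq,
                reverse=rseq,
                fwd_start=fs,
                fwd_end=fe,
                rev_start=rs,
                rev_end=re,
                fwd_tm=ftm,
                rev_tm=rtm,
                fwd_degeneracy=fstats,
                rev_degeneracy=rstats,
            )
        )
        if len(out) >= constraints.max_pairs_per_cluster:
            break
    return out


def design_internal_probe(
    pair: DegeneratePrimerPair,
    track: ConsensusTrack,
    constraints: DesignConstraints = DesignConstraints(),
    cond: ReactionConditions = ReactionConditions(),
) -> Optional[Probe]:
    """Best internal probe strictly between the primer binding sites.

    Candidate windows (plus strand, primer length bounds) must satisfy the
    single-primer filters at a Tm band shifted up by ``probe_tm_offset``
    (hydrolysis probes are designed hotter than primers), pass degeneracy
    budgets after widening, and must not overlap either primer.  The
    window whose mean Tm is closest to ``tm_opt + probe_tm_offset`` wins;
    ties break by start then length.  Returns None when no window fits.
    """
    lo, hi = pair.fwd_end, pair.rev_start
    if hi - lo < constraints.primer_len_min:
        return None
    shifted = replace(
        constraints,
        tm_min=constraints.tm_min + constraints.probe_tm_offset,
        tm_opt=constraints.tm_opt + constraints.probe_tm_offset,
        tm_max=constraints.tm_max + constraints.probe_tm_offset,
    )
    usable = track.usable()
    target = shifted.tm_opt
    best: Optional[Probe] = None
    best_key: Optional[tuple] = None
    cache: dict = {}
    for length in range(constraints.primer_len_min, constraints.primer_len_max + 1):
        for start in range(lo, hi - length + 1):
            end = start + length
            if not all(usable[start:end]):
                continue
            if _window_ok(track.consensus[start:end], shifted, cond) is None:
                continue
            widened = _degenerate_window(track, start, end, cond, shifted, cache)
            if widened is None:
                continue
            seq, stats, tm = widened
            if tm is None or stats.total > constraints.max_total_degeneracy:
                continue
            if stats.n_three_prime > constraints.max_three_prime_degeneracy:
                continue
            key = (round(abs(tm - target), 6), start, length)
            if best_key is None or key < best_key:
                best_key = key
                best = Probe(seq=seq, start=start, end=end, mean_tm=tm, degeneracy=stats)
    return best
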