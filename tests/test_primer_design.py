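"""Thermodynamics, candidate enumeration, degeneracy injection and budgets."""

import dataclasses

import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as mt

from cladeprimers.msa import ConsensusTrack
from cladeprimers.primer_design import (
    DegeneratePrimerPair,
    DesignConstraints,
    ReactionConditions,
    add_degeneracies,
    design_cluster_pairs,
    design_internal_probe,
    enumerate_candidates,
    filter_degeneracy,
    max_self_complementary_run,
    mean_primer_tm,
    melting_temperature,
    rank_pairs,
)
from cladeprimers.seqcore import degeneracy_of, reverse_complement
from cladeprimers.synthetic_pangenome import sample_primer_site

COND = ReactionConditions()


def concrete_track(seq: str) -> ConsensusTrack:
    return ConsensusTrack(consensus=seq, variants=[frozenset(c) for c in seq])


def _pair_from_track(track, fs, fe, rs, re, cluster="CL"):
    fwd = track.consensus[fs:fe]
    rev = reverse_complement(track.consensus[rs:re])
    return DegeneratePrimerPair(
        cluster_id=cluster,
        forward=fwd,
        reverse=rev,
        fwd_start=fs,
        fwd_end=fe,
        rev_start=rs,
        rev_end=re,
        fwd_tm=melting_temperature(fwd, COND),
        rev_tm=melting_temperature(rev, COND),
        fwd_degeneracy=degeneracy_of(fwd),
        rev_degeneracy=degeneracy_of(rev),
    )


class TestMeltingTemperature:
    @pytest.mark.parametrize(
        "seq",
        [
            "ACGTACGTACGTACGTACGT",
            "TAAAAACACACTGCAGGGAC",
            "GGGCGCGCCTTAATTAAGGC",
            "ATATATATATATATATAT",
            "TCCGTGTTCAACTTTTTTCCT",
        ],
    )
    def test_matches_independent_nearest_neighbor_oracle(self, seq):
        # identical model/conditions expressed through an independent
        # implementation: SantaLucia unified table, entropic salt
        # correction, CT/4, monovalent-equivalent salt
        expected = mt.Tm_NN(
            seq,
            nn_table=mt.DNA_NN3,
            dnac1=COND.oligo_nM / 4.0,
            dnac2=0,
            Na=COND.monovalent_mM,
            Mg=COND.divalent_mM,
            dNTPs=0,
            saltcorr=5,
        )
        assert melting_temperature(seq, COND) == pytest.approx(expected, abs=0.2)

    def test_equal_for_reverse_complement(self, rng):
        for _ in range(20):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=20))
            assert melting_temperature(seq, COND) == pytest.approx(
                melting_temperature(reverse_complement(seq), COND), abs=1e-9
            )

    def test_gc_substitution_strictly_raises_tm(self):
        template = "ATGATCGTTAGCATTGACCA"
        base_tm = melting_temperature(template, COND)
        for i, sym in enumerate(template):
            if sym in "AT":
                for repl in "GC":
                    hotter = template[:i] + repl + template[i + 1 :]
                    assert melting_temperature(hotter, COND) > base_tm

    def test_degenerate_and_short_input_rejected(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTACGTACGTACGTACGM", COND)
        with pytest.raises(ValueError):
            melting_temperature("ACGTACG", COND)


class TestMeanPrimerTm:
    def test_concrete_primer_equals_single_tm(self):
        seq = "ACGTACGTACGTACGTACGT"
        assert mean_primer_tm(seq, COND) == melting_temperature(seq, COND)

    def test_degenerate_primer_averages_over_pool(self):
        # mean over {TA, TC} prefixed pool, checked by direct enumeration
        seq = "MACGTACGTACGTACGTACG"
        expected = np.mean(
            [melting_temperature(s + "ACGTACGTACGTACGTACG", COND) for s in "AC"]
        )
        assert mean_primer_tm(seq, COND) == pytest.approx(expected, abs=1e-9)

    def test_expansion_cap_refused_with_value(self):
        with pytest.raises(ValueError, match="1024"):
            mean_primer_tm("NNNNN" + "ACGTACGTACGT", COND)


class TestEnumerate:
    def _planted_track(self, seed=11, product=300):
        rng = np.random.default_rng(seed)
        sites = [sample_primer_site(rng), sample_primer_site(rng)]
        n = 400
        background = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
        fs = 30
        rs = fs + product - len(sites[1])
        seq = background[:fs] + sites[0] + background[fs + len(sites[0]) : rs] + sites[1] + background[rs + len(sites[1]) :]
        return concrete_track(seq), fs, len(sites[0]), rs, len(sites[1])

    def test_planted_pair_is_enumerated(self):
        track, fs, flen, rs, rlen = self._planted_track()
        pairs = enumerate_candidates(track, cluster_id="CL")
        found = [
            p
            for p in pairs
            if (p.fwd_start, p.fwd_end, p.rev_start, p.rev_end)
            == (fs, fs + flen, rs, rs + rlen)
        ]
        assert len(found) == 1
        pair = found[0]
        assert pair.product_length == 300
        assert pair.reverse == reverse_complement(track.consensus[rs : rs + rlen])

    def test_consensus_shorter_than_product_min_yields_nothing(self):
        track = concrete_track("ACGT" * 10)
        assert enumerate_candidates(track) == []

    def test_impossible_tm_band_yields_nothing(self):
        track, *_ = self._planted_track()
        constraints = DesignConstraints(tm_min=95.0, tm_opt=96.0, tm_max=97.0)
        assert enumerate_candidates(track, constraints) == []

    def test_emitted_pairs_satisfy_constraints_and_order(self):
        track, *_ = self._planted_track()
        constraints = DesignConstraints()
        pairs = enumerate_candidates(track, constraints)
        assert pairs, "expected at least the planted pair"
        keys = [(p.fwd_start, p.product_length) for p in pairs]
        assert keys == sorted(keys)
        for p in pairs[:50]:
            assert constraints.product_min <= p.product_length <= constraints.product_max
            assert constraints.tm_min <= p.fwd_tm <= constraints.tm_max
            assert abs(p.fwd_tm - p.rev_tm) <= constraints.max_pair_tm_diff


class TestAddDegeneracies:
    def _track(self, consensus, variant_overrides):
        variants = [frozenset(c) for c in consensus]
        for i, vs in variant_overrides.items():
            variants[i] = frozenset(vs)
        return ConsensusTrack(consensus=consensus, variants=variants)

    def test_conserved_windows_stay_concrete(self):
        seq = "ATGATCGTTAGCATTGACCA" + "GCTA" * 70 + "TGGTCAATGCTAACGATCAT"
        track = concrete_track(seq)
        pair = _pair_from_track(track, 0, 20, len(seq) - 20, len(seq))
        out = add_degeneracies(pair, track)
        assert out.forward == pair.forward
        assert out.reverse == pair.reverse
        assert out.fwd_degeneracy.total == 1

    def test_variant_column_becomes_union_code(self):
        seq = "ATGATCGTTAGCATTGACCA" + "GCTA" * 70 + "TGGTCAATGCTAACGATCAT"
        track = self._track(seq, {2: "GC", 4: "AT"})
        pair = _pair_from_track(track, 0, 20, len(seq) - 20, len(seq))
        out = add_degeneracies(pair, track)
        assert out.forward[2] == "S"
        assert out.forward[4] == "W"
        assert out.fwd_degeneracy.total == 4

    def test_reverse_primer_degeneracy_is_complemented(self):
        from cladeprimers.seqcore import IUPAC_COMPLEMENT, iupac_union

        seq = "ATGATCGTTAGCATTGACCA" + "GCTA" * 70 + "TGGTCAATGCTAACGATCAT"
        i = len(seq) - 3  # third-last column -> position 2 of the reverse primer
        track = self._track(seq, {i: {seq[i], "A" if seq[i] != "A" else "G"}})
        pair = _pair_from_track(track, 0, 20, len(seq) - 20, len(seq))
        out = add_degeneracies(pair, track)
        assert out.reverse[2] == IUPAC_COMPLEMENT[iupac_union(track.variants[i])]
        assert out.rev_degeneracy.total == 2

    def test_gap_variant_rejects_candidate(self):
        seq = "ATGATCGTTAGCATTGACCA" + "GCTA" * 70 + "TGGTCAATGCTAACGATCAT"
        track = self._track(seq, {5: {"A", "-"}})
        pair = _pair_from_track(track, 0, 20, len(seq) - 20, len(seq))
        assert add_degeneracies(pair, track) is None


class TestDegeneracyFilter:
    def _pair_with(self, fwd, rev):
        return DegeneratePrimerPair(
            cluster_id="CL",
            forward=fwd,
            reverse=rev,
            fwd_start=0,
            fwd_end=len(fwd),
            rev_start=300,
            rev_end=300 + len(rev),
            fwd_tm=60.0,
            rev_tm=60.0,
            fwd_degeneracy=degeneracy_of(fwd),
            rev_degeneracy=degeneracy_of(rev),
        )

    def test_printed_worked_example_pair_passes_defaults(self):
        pair = self._pair_with("TMARRACMCACTGCAGGGAC", "TCCGTGYTCAACYTTYTTCCT")
        assert filter_degeneracy([pair]) == [pair]

    def test_three_prime_degeneracy_rejected_at_default_budget(self):
        pair = self._pair_with("TMARRACMCACTGCAGGGAM", "TCCGTGYTCAACYTTYTTCCT")
        assert filter_degeneracy([pair]) == []

    def test_total_degeneracy_budget(self):
        pair = self._pair_with("NNNACGTACGTACGTACGT", "ACGTACGTACGTACGTACGT")
        assert filter_degeneracy([pair]) == []  # 64 > 32
        relaxed = DesignConstraints(max_total_degeneracy=64)
        assert filter_degeneracy([pair], relaxed) == [pair]

    def test_zero_degeneracy_always_kept(self):
        pair = self._pair_with("ACGTACGTACGTACGTACGT", "TGCATGCATGCATGCATGCA")
        assert filter_degeneracy([pair]) == [pair]

    def test_filter_monotone_under_relaxation(self):
        pairs = [
            self._pair_with("TMARRACMCACTGCAGGGAC", "TCCGTGYTCAACYTTYTTCCT"),
            self._pair_with("NNNACGTACGTACGTACGT", "ACGTACGTACGTACGTACGT"),
            self._pair_with("ACGTACGTACGTACGTACGM", "ACGTACGTACGTACGTACGT"),
        ]
        strict = filter_degeneracy(pairs, DesignConstraints())
        relaxed = filter_degeneracy(
            pairs,
            DesignConstraints(max_total_degeneracy=1024, max_three_prime_degeneracy=5),
        )
        assert set(id(p) for p in strict) <= set(id(p) for p in relaxed)


def test_fused_design_path_equals_composed_operations(small_sim):
    """design_cluster_pairs == enumerate → widen → filter → rank → cap."""
    from cladeprimers.msa import align_protein_cluster, back_translate_alignment, majority_consensus
    from cladeprimers.pangenome import cluster_genes

    cluster = cluster_genes(small_sim.gene_records)[0]
    aln = back_translate_alignment(
        align_protein_cluster({m.gene_id: m.aa_seq for m in cluster.members}),
        cluster.members,
    )
    full = majority_consensus(aln)
    track = ConsensusTrack(consensus=full.consensus[:250], variants=full.variants[:250])
    constraints = dataclasses.replace(DesignConstraints(), max_pairs_per_cluster=10)

    slow = []
    cache = {}
    for pair in enumerate_candidates(track, constraints, COND, "CL"):
        widened = add_degeneracies(pair, track, COND, constraints, cache)
        if widened is not None:
            slow.append(widened)
    slow = filter_degeneracy(slow, constraints)
    seen, unique = set(), []
    for p in rank_pairs(slow, constraints):
        if (p.forward, p.reverse) not in seen:
            seen.add((p.forward, p.reverse))
            unique.append(p)
    slow_top = unique[:10]

    fast = design_cluster_pairs(track, constraints, COND, "CL")
    assert [(p.forward, p.reverse, p.fwd_start, p.rev_end) for p in fast] == [
        (p.forward, p.reverse, p.fwd_start, p.rev_end) for p in slow_top
    ]


class TestProbe:
    def _at_rich(self, rng, n):
        # AT-rich background: no window reaches the probe Tm band
        return "".join(rng.choice(list("ATATACGT"), size=n))

    def test_short_interprimer_region_gives_no_probe(self, rng):
        seq = "ATGATCGTTAGCATTGACCA" + self._at_rich(rng, 10) + "TGGTCAATGCTAACGATCAT"
        track = concrete_track(seq)
        pair = _pair_from_track(track, 0, 20, len(seq) - 20, len(seq))
        assert design_internal_probe(pair, track) is None

    def test_planted_probe_window_recovered(self, rng):
        # sample a probe-band site (Tm ~ 65-71) and bury it in AT-rich sequence
        probe_site = None
        while probe_site is None:
            cand = "".join(rng.choice(list("ACGT"), size=22, p=[0.2, 0.3, 0.3, 0.2]))
            from cladeprimers.seqcore import gc_fraction, max_homopolymer_run

            if (
                0.3 <= gc_fraction(cand) <= 0.7
                and max_homopolymer_run(cand) <= 4
                and max_self_complementary_run(cand) <= 8
                and 65.0 <= melting_temperature(cand, COND) <= 71.0
            ):
                probe_site = cand
        left = "ATGATCGTTAGCATTGACCA"
        right = "TGGTCAATGCTAACGATCAT"
        mid = self._at_rich(rng, 40) + probe_site + self._at_rich(rng, 40)
        seq = left + mid + right
        track = concrete_track(seq)
        pair = _pair_from_track(track, 0, len(left), len(seq) - len(right), len(seq))
        probe = design_internal_probe(pair, track)
        assert probe is not None
        planted_start = len(left) + 40
        # the probe must sit on the planted hot window (flanks cannot reach
        # the probe Tm band) and strictly between the primers
        assert probe.end > planted_start and probe.start < planted_start + len(probe_site)
        assert probe.start >= pair.fwd_end and probe.end <= pair.rev_start
        assert 65.0 <= probe.mean_tm <= 71.0

    def test_probe_never_overlaps_primers(self, small_sim):
        from cladeprimers.msa import align_protein_cluster, back_translate_alignment, majority_consensus
        from cladeprimers.pangenome import cluster_genes

        cluster = cluster_genes(small_sim.gene_records)[0]
        aln = back_translate_alignment(
            align_protein_cluster({m.gene_id: m.aa_seq for m in cluster.members}),
            cluster.members,
        )
        track = majority_consensus(aln)
        constraints = dataclasses.replace(DesignConstraints(), max_pairs_per_cluster=5)
        for pair in design_cluster_pairs(track, constraints, COND, "CL"):
            probe = design_internal_probe(pair, track, constraints, COND)
            if probe is not None:
                assert probe.start >= pair.fwd_end
                assert probe.end <= pair.rev_start
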