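"""Synthetic pan-genome fixtures with known ground truth.

Emulates the input of a clade-targeted primer design run without any
download: a small clade of genomes diverged from a common set of ancestral
single-copy core genes (star phylogeny, i.i.d. per-site substitutions with
a 3:1 bias toward third codon positions, so amino-acid identity stays high
while nucleotide variation exercises the degeneracy machinery), plus
unrelated off-target genomes.  Optionally the generator plants
constraint-satisfying, mutation-protected primer windows inside chosen
core genes — sites a designer should recover exactly — and "decoy"
off-target sequences carrying near-matches (k mismatches per primer) to a
planted site, which the specificity screen must catch.

Identical config + seed reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .pangenome import GeneRecord
from .primer_design import DesignConstraints, ReactionConditions, melting_temperature, max_self_complementary_run
from .seqcore import gc_fraction, max_homopolymer_run, reverse_complement

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES if a + b + c not in _STOPS]


@dataclass(frozen=True)
class PlantedPairSpec:
    """A conserved forward/reverse primer-site pair inside one core gene.

    Coordinates are nucleotide offsets within the gene; windows are
    codon-aligned (start and length multiples of 3) so planting preserves
    the reading frame structure of protection.  The reverse *window* is on
    the plus strand; the reverse primer is its reverse complement.
    """

    gene_index: int = 0
    fwd_start: int = 90
    primer_len: int = 21
    product_len: int = 300

    def __post_init__(self) -> None:
        if self.fwd_start % 3 or self.primer_len % 3 or self.product_len % 3:
            raise ValueError("planted windows must be codon-aligned (multiples of 3)")
        if self.product_len < 2 * self.primer_len:
            raise ValueError("product shorter than the two primers")

    @property
    def rev_start(self) -> int:
        return self.fwd_start + self.product_len - self.primer_len

    @property
    def rev_end(self) -> int:
        return self.fwd_start + self.product_len


@dataclass(frozen=True)
class DecoySpec:
    """An off-target sequence mimicking one planted site at k mismatches."""

    planted_index: int = 1
    mismatches: int = 2
    product_len: int = 500


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic clade.

    ``substitution_prob`` is the per-site substitution probability at
    third codon positions; first/second positions mutate at one third of
    it, giving the synonymous bias.  Planted windows never mutate.
    """

    n_target_genomes: int = 5
    n_core_genes: int = 8
    gene_len_codons: tuple[int, int] = (150, 300)
    substitution_prob: float = 0.02
    n_offtarget_genomes: int = 2
    planted: tuple[PlantedPairSpec, ...] = (
        PlantedPairSpec(gene_index=0),
        PlantedPairSpec(gene_index=1),
    )
    decoy: Optional[DecoySpec] = DecoySpec()
    paralog_in: Optional[tuple[int, int]] = None  # (genome index, gene index)
    missing_in: Optional[tuple[int, int]] = None
    spacer_len: tuple[int, int] = (50, 500)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.substitution_prob <= 1.0):
            raise ValueError("substitution_prob must lie in [0, 1]")
        for name in ("n_target_genomes", "n_core_genes", "n_offtarget_genomes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for spec in self.planted:
            if spec.gene_index >= self.n_core_genes:
                raise ValueError("planted gene_index out of range")
        if self.decoy is not None and self.decoy.planted_index >= len(self.planted):
            raise ValueError("decoy references a planted pair that does not exist")


@dataclass(frozen=True)
class PlantedPair:
    """A resolved planted site: where it is and what the primers are."""

    spec: PlantedPairSpec
    family_id: int
    fwd_seq: str
    rev_window_seq: str  # plus strand

    @property
    def rev_primer(self) -> str:
        return reverse_complement(self.rev_window_seq)


@dataclass
class SimulatedPangenome:
    """Generator output: sequences plus the ground-truth bookkeeping."""

    config: SimulationConfig
    ancestors: dict[int, str]
    gene_records: list[GeneRecord]
    target_genomes: dict[str, str]
    non_target: list[tuple[str, str]]
    planted: list[PlantedPair]
    truth: pd.DataFrame


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    return "".join(_CODONS[i] for i in rng.integers(0, len(_CODONS), size=n_codons))


def _site_acceptable(
    seq: str, constraints: DesignConstraints, cond: ReactionConditions
) -> bool:
    # planted sites sit comfortably inside the default design bands, with
    # Tm close to the optimum — emulating a well-chosen qPCR site
    if not (0.35 <= gc_fraction(seq) <= 0.65):
        return False
    if max_homopolymer_run(seq) > constraints.max_homopolymer:
        return False
    if max_self_complementary_run(seq) > constraints.max_self_comp_run:
        return False
    tm = melting_temperature(seq, cond)
    return constraints.tm_opt - 0.4 <= tm <= constraints.tm_opt + 0.4


def sample_primer_site(
    rng: np.random.Generator,
    n_codons: int = 7,
    constraints: DesignConstraints = DesignConstraints(),
    cond: ReactionConditions = ReactionConditions(),
    max_attempts: int = 20000,
) -> str:
    """Rejection-sample a codon-aligned, constraint-satisfying primer site."""
    for _ in range(max_attempts):
        seq = _random_cds(rng, n_codons)
        if _site_acceptable(seq, constraints, cond):
            return seq
    raise RuntimeError("could not sample a constraint-satisfying primer site")


def plant_primer_site(
    gene: str,
    start: int,
    site_seq: str,
    occupied: Sequence[tuple[int, int]] = (),
) -> str:
    """Overwrite ``gene[start : start+len(site_seq)]`` with *site_seq*.

    Raises on windows extending past the gene or colliding with an
    interval already planted (``occupied`` is a list of (start, end)).
    """
    end = start + len(site_seq)
    if start < 0 or end > len(gene):
        raise ValueError("planted window does not fit inside the gene")
    for o_start, o_end in occupied:
        if start < o_end and o_start < end:
            raise ValueError(
                f"planted window [{start},{end}) collides with [{o_start},{o_end})"
            )
    return gene[:start] + site_seq + gene[end:]


def _mutate_cds(
    rng: np.random.Generator,
    cds: str,
    p_third: float,
    protected: Sequence[tuple[int, int]],
) -> str:
    """Mutate a CDS codon-wise; stop-creating codons revert to the ancestor."""
    if p_third == 0.0:
        return cds
    p = np.full(len(cds), p_third / 3.0)
    p[2::3] = p_third
    hit = rng.random(len(cds)) < p
    # pre-draw one candidate base per site so the random stream does not
    # depend on which sites were hit
    picks = rng.integers(0, 3, size=len(cds))
    for s, e in protected:
        hit[s:e] = False
    seq = list(cds)
    for i in np.nonzero(hit)[0]:
        alternatives = [b for b in _BASES if b != cds[i]]
        seq[i] = alternatives[picks[i]]
    # revert any codon that became a stop
    for c in range(0, len(seq), 3):
        if "".join(seq[c : c + 3]) in _STOPS:
            seq[c : c + 3] = cds[c : c + 3]
    return "".join(seq)


def _mismatched_copy(rng: np.random.Generator, site: str, k: int) -> str:
    """*site* with exactly k substitutions to definitely-incompatible bases."""
    if k > len(site):
        raise ValueError("more mismatches than positions")
    positions = sorted(rng.choice(len(site), size=k, replace=False).tolist())
    out = list(site)
    for i in positions:
        alternatives = [b for b in _BASES if b != site[i]]
        out[i] = alternatives[int(rng.integers(0, 3))]
    return "".join(out)


def _spacer(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def simulate_pangenome(config: SimulationConfig = SimulationConfig()) -> SimulatedPangenome:
    """Generate a seeded synthetic clade with planted ground truth.

    Per core gene family, an ancestral CDS is drawn codon-wise (no stop
    codons), planted sites are written in, and each target genome receives
    an independently mutated copy.  Off-target genomes are unrelated
    random gene arrays; the decoy, when configured, embeds mismatched
    copies of one planted pair's sites at an amplifiable spacing.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gene_len_codons
    if lo > hi or lo < 1:
        raise ValueError("invalid gene length range")

    # 1. ancestors
    ancestors: dict[int, str] = {}
    lengths = rng.integers(lo, hi + 1, size=config.n_core_genes)
    for j in range(config.n_core_genes):
        ancestors[j] = _random_cds(rng, int(lengths[j]))

    # 2. planted sites (mutation-protected intervals per family)
    protected: dict[int, list[tuple[int, int]]] = {j: [] for j in ancestors}
    planted: list[PlantedPair] = []
    for spec in config.planted:
        gene = ancestors[spec.gene_index]
        if spec.rev_end > len(gene):
            raise ValueError(
                f"planted pair (product {spec.product_len}) does not fit in "
                f"gene {spec.gene_index} of length {len(gene)}"
            )
        fwd_site = sample_primer_site(rng, spec.primer_len // 3)
        rev_site = sample_primer_site(rng, spec.primer_len // 3)
        gene = plant_primer_site(gene, spec.fwd_start, fwd_site, protected[spec.gene_index])
        protected[spec.gene_index].append((spec.fwd_start, spec.fwd_start + spec.primer_len))
        gene = plant_primer_site(gene, spec.rev_start, rev_site, protected[spec.gene_index])
        protected[spec.gene_index].append((spec.rev_start, spec.rev_end))
        ancestors[spec.gene_index] = gene
        planted.append(
            PlantedPair(
                spec=spec,
                family_id=spec.gene_index,
                fwd_seq=fwd_site,
                rev_window_seq=rev_site,
            )
        )

    # 3. target genomes: mutated copies of every family, concatenated
    gene_records: list[GeneRecord] = []
    target_genomes: dict[str, str] = {}
    truth_rows: list[dict] = []
    for i in range(config.n_target_genomes):
        genome_id = f"tg{i:02d}"
        parts: list[str] = []
        for j in range(config.n_core_genes):
            if config.missing_in == (i, j):
                continue
            copies = [""]
            if config.paralog_in == (i, j):
                copies = ["", "b"]
            for copy_tag in copies:
                mutated = _mutate_cds(
                    rng, ancestors[j], config.substitution_prob, protected[j]
                )
                gene_id = f"{genome_id}|g{j:02d}{copy_tag}"
                aa = str(Seq(mutated).translate(table=11))
                rec = GeneRecord(genome_id=genome_id, gene_id=gene_id, nt_seq=mutated, aa_seq=aa)
                gene_records.append(rec)
                parts.append(_spacer(rng, *config.spacer_len))
                parts.append(mutated)
                truth_rows.append(
                    {
                        "kind": "gene",
                        "subject_id": gene_id,
                        "genome_id": genome_id,
                        "family_id": j,
                        "start": -1,
                        "end": -1,
                        "info": "paralog" if copy_tag else "",
                    }
                )
        parts.append(_spacer(rng, *config.spacer_len))
        target_genomes[genome_id] = "".join(parts)

    for idx, pp in enumerate(planted):
        truth_rows.append(
            {
                "kind": "planted_fwd",
                "subject_id": f"family{pp.family_id}",
                "genome_id": "",
                "family_id": pp.family_id,
                "start": pp.spec.fwd_start,
                "end": pp.spec.fwd_start + pp.spec.primer_len,
                "info": pp.fwd_seq,
            }
        )
        truth_rows.append(
            {
                "kind": "planted_rev",
                "subject_id": f"family{pp.family_id}",
                "genome_id": "",
                "family_id": pp.family_id,
                "start": pp.spec.rev_start,
                "end": pp.spec.rev_end,
                "info": pp.rev_primer,
            }
        )

    # 4. off-target genomes (unrelated), plus the decoy construct
    non_target: list[tuple[str, str]] = []
    for i in range(config.n_offtarget_genomes):
        ot_id = f"ot{i:02d}"
        parts = []
        for _ in range(3):
            parts.append(_spacer(rng, *config.spacer_len))
            parts.append(_random_cds(rng, int(rng.integers(lo, hi + 1))))
        if i == 0 and config.decoy is not None:
            decoy = config.decoy
            pp = planted[decoy.planted_index]
            fwd_near = _mismatched_copy(rng, pp.fwd_seq, decoy.mismatches)
            rev_near = _mismatched_copy(rng, pp.rev_window_seq, decoy.mismatches)
            filler_len = decoy.product_len - 2 * pp.spec.primer_len
            block = fwd_near + _exact_spacer(rng, filler_len) + rev_near
            offset = sum(len(p) for p in parts)
            parts.append(block)
            truth_rows.append(
                {
                    "kind": "decoy",
                    "subject_id": ot_id,
                    "genome_id": ot_id,
                    "family_id": pp.family_id,
                    "start": offset,
                    "end": offset + len(block),
                    "info": f"planted_index={decoy.planted_index};mismatches={decoy.mismatches}",
                }
            )
        parts.append(_spacer(rng, *config.spacer_len))
        non_target.append((ot_id, "".join(parts)))

    truth = pd.DataFrame(
        truth_rows, columns=["kind", "subject_id", "genome_id", "family_id", "start", "end", "info"]
    )
    return SimulatedPangenome(
        config=config,
        ancestors=ancestors,
        gene_records=gene_records,
        target_genomes=target_genomes,
        non_target=non_target,
        planted=planted,
        truth=truth,
    )


def _exact_spacer(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def write_fixture(sim: SimulatedPangenome, outdir: str | Path) -> dict[str, Path]:
    """Write the fixture as plain-text FASTA/TSV files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cds_nt": outdir / "target_cds.fna",
        "cds_aa": outdir / "target_proteins.faa",
        "genomes": outdir / "target_genomes.fasta",
        "non_target": outdir / "non_target.fasta",
        "qc": outdir / "genome_qc.tsv",
        "truth": outdir / "truth.tsv",
    }
    with open(paths["cds_nt"], "w") as nt_fh, open(paths["cds_aa"], "w") as aa_fh:
        for rec in sim.gene_records:
            nt_fh.write(f">{rec.gene_id}\n{rec.nt_seq}\n")
            aa_fh.write(f">{rec.gene_id}\n{rec.aa_seq}\n")
    with open(paths["genomes"], "w") as fh:
        for genome_id, seq in sim.target_genomes.items():
            fh.write(f">{genome_id}\n{seq}\n")
    with open(paths["non_target"], "w") as fh:
        for subject_id, seq in sim.non_target:
            fh.write(f">{subject_id}\n{seq}\n")
    with open(paths["qc"], "w") as fh:
        fh.write("genome_id\tcompleteness\tcontamination\n")
        for genome_id in sim.target_genomes:
            fh.write(f"{genome_id}\t99.0\t0.5\n")
    sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
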