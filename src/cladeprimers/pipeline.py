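"""End-to-end orchestration: genome QC → clustering → core selection →
alignment → consensus → primer design → degeneracy filtering → two-stage
specificity screen → final report table.

The pipeline is deliberately deterministic: given the same inputs and
configuration it writes byte-identical outputs, and every parameter that
affects the result is echoed into the run log.
"""

from __future__ import annotations

import dataclasses
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from . import msa, pangenome, primer_design, specificity
from .pangenome import GeneCluster, GeneRecord
from .primer_design import DegeneratePrimerPair, DesignConstraints, ReactionConditions
from .specificity import Rejection, ScreenResult

EXIT_OK = 0
EXIT_NO_CANDIDATES = 3


@dataclass(frozen=True)
class GenomeQCRecord:
    """Assembly QC metadata for one genome (consumed, never computed)."""

    genome_id: str
    completeness: float  # percent
    contamination: float  # percent

    def __post_init__(self) -> None:
        if not (0.0 <= self.completeness <= 100.0):
            raise ValueError(f"{self.genome_id}: completeness outside [0, 100]")
        if self.contamination < 0.0:
            raise ValueError(f"{self.genome_id}: negative contamination")


def filter_genomes_by_qc(
    records: Sequence[GenomeQCRecord],
    min_completeness: float = 90.0,
    max_contamination: float = 5.0,
) -> list[str]:
    """Genome ids passing completeness/contamination thresholds.

    Boundary values are retained: a genome at exactly 90% completeness or
    exactly 5% contamination passes (the filtered side is strict).
    """
    seen = set()
    for rec in records:
        if rec.genome_id in seen:
            raise ValueError(f"duplicate QC record for {rec.genome_id}")
        seen.add(rec.genome_id)
    return [
        rec.genome_id
        for rec in records
        if rec.completeness >= min_completeness and rec.contamination <= max_contamination
    ]


def read_qc_table(path: str | Path) -> list[GenomeQCRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"genome_id", "completeness", "contamination"}
    if not required <= set(df.columns):
        raise ValueError(f"QC table must have columns {sorted(required)}")
    return [
        GenomeQCRecord(str(r.genome_id), float(r.completeness), float(r.contamination))
        for r in df.itertuples()
    ]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a design run needs; loadable from a YAML mapping."""

    cds_nt: str
    cds_aa: str
    non_target: Optional[str] = None
    qc_table: Optional[str] = None
    header_delimiter: str = "|"
    min_identity: float = 0.80
    min_coverage: float = 0.90
    min_completeness: float = 90.0
    max_contamination: float = 5.0
    constraints: DesignConstraints = DesignConstraints()
    conditions: ReactionConditions = ReactionConditions()
    screen_max_mismatches: int = 3
    screen_min_coverage: float = 0.8
    off_target_min: int = 30
    off_target_max: int = 2000
    design_probes: bool = False
    keep_rejected: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "constraints" in raw:
            raw["constraints"] = DesignConstraints(**raw["constraints"])
        if "conditions" in raw:
            raw["conditions"] = ReactionConditions(**raw["conditions"])
        return cls(**raw)

    def echo(self) -> str:
        """YAML dump of every effective parameter, for the run log."""
        data = dataclasses.asdict(self)
        return yaml.safe_dump(data, sort_keys=True)


@dataclass
class PipelineResult:
    report: pd.DataFrame
    retained: list[DegeneratePrimerPair]
    rejected: list[Rejection]
    core_clusters: list[GeneCluster]
    n_genomes: int
    n_genes: int


_REPORT_COLUMNS = [
    "cluster_id",
    "annotation",
    "forward",
    "reverse",
    "probe",
    "fwd_len",
    "rev_len",
    "fwd_mean_tm",
    "rev_mean_tm",
    "fwd_degeneracy",
    "rev_degeneracy",
    "fwd_3p_degeneracy",
    "rev_3p_degeneracy",
    "fwd_start",
    "fwd_end",
    "rev_start",
    "rev_end",
    "product_length",
    "status",
    "rejection_stage",
    "rejection_subject",
    "rejection_product_length",
]


def _report_row(
    pair: DegeneratePrimerPair,
    status: str,
    annotation: str = "",
    rejection: Optional[Rejection] = None,
) -> dict:
    return {
        "cluster_id": pair.cluster_id,
        "annotation": annotation,
        "forward": pair.forward,
        "reverse": pair.reverse,
        "probe": pair.probe.seq if pair.probe else "",
        "fwd_len": len(pair.forward),
        "rev_len": len(pair.reverse),
        "fwd_mean_tm": round(pair.fwd_tm, 2),
        "rev_mean_tm": round(pair.rev_tm, 2),
        "fwd_degeneracy": pair.fwd_degeneracy.total,
        "rev_degeneracy": pair.rev_degeneracy.total,
        "fwd_3p_degeneracy": pair.fwd_degeneracy.n_three_prime,
        "rev_3p_degeneracy": pair.rev_degeneracy.n_three_prime,
        # report coordinates are 1-based inclusive on the consensus
        "fwd_start": pair.fwd_start + 1,
        "fwd_end": pair.fwd_end,
        "rev_start": pair.rev_start + 1,
        "rev_end": pair.rev_end,
        "product_length": pair.product_length,
        "status": status,
        "rejection_stage": rejection.stage if rejection else "",
        "rejection_subject": rejection.subject_id if rejection else "",
        "rejection_product_length": rejection.product_length if rejection else -1,
    }


def design_for_clusters(
    core_clusters: Sequence[GeneCluster],
    constraints: DesignConstraints,
    conditions: ReactionConditions,
    design_probes: bool = False,
    outdir: Optional[Path] = None,
) -> tuple[list[DegeneratePrimerPair], dict[str, msa.ConsensusTrack]]:
    """Per-cluster alignment, consensus and capped candidate design."""
    candidates: list[DegeneratePrimerPair] = []
    tracks: dict[str, msa.ConsensusTrack] = {}
    for cluster in core_clusters:
        members = {m.gene_id: m.aa_seq for m in cluster.members}
        protein_aln = msa.align_protein_cluster(members)
        codon_aln = msa.back_translate_alignment(protein_aln, cluster.members)
        if outdir is not None:
            msa.write_alignment_fasta(codon_aln, outdir / f"{cluster.cluster_id}.codon.aln.fasta")
        track = msa.majority_consensus(codon_aln)
        tracks[cluster.cluster_id] = track
        top = primer_design.design_cluster_pairs(
            track, constraints, conditions, cluster_id=cluster.cluster_id
        )
        if design_probes:
            top = [
                dataclasses.replace(
                    p,
                    probe=primer_design.design_internal_probe(p, track, constraints, conditions),
                )
                for p in top
            ]
        candidates.extend(top)
    return candidates, tracks


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    annotations: Optional[dict[str, str]] = None,
    log=None,
) -> PipelineResult:
    """Execute the full design pipeline and write all artifacts to *outdir*.

    Artifacts: ``primer_report.tsv`` (the final table), per-cluster codon
    alignment FASTA, ``rejections.tsv``, and ``run_log.yaml`` echoing the
    complete effective configuration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = log or (lambda msg: print(msg, file=sys.stderr))

    (outdir / "run_log.yaml").write_text(config.echo())

    genes = pangenome.read_gene_records(config.cds_nt, config.cds_aa, config.header_delimiter)
    genome_ids = sorted({g.genome_id for g in genes})
    log(f"loaded {len(genes)} genes from {len(genome_ids)} genomes")

    if config.qc_table:
        qc = read_qc_table(config.qc_table)
        passing = set(
            filter_genomes_by_qc(qc, config.min_completeness, config.max_contamination)
        )
        recorded = {r.genome_id for r in qc}
        for gid in genome_ids:
            if gid not in recorded:
                log(f"warning: no QC record for genome {gid}; retained")
                passing.add(gid)
        genes = [g for g in genes if g.genome_id in passing]
        genome_ids = sorted({g.genome_id for g in genes})
        log(f"QC filter: {len(genome_ids)} genomes retained")

    clusters = pangenome.cluster_genes(genes, config.min_identity, config.min_coverage)
    core = pangenome.select_core_clusters(clusters, genome_ids)
    log(f"{len(clusters)} clusters, {len(core)} single-copy core")

    candidates, _tracks = design_for_clusters(
        core, config.constraints, config.conditions, config.design_probes, outdir
    )
    log(f"{len(candidates)} candidate pairs after degeneracy filtering")

    gene_to_cluster = {m.gene_id: c.cluster_id for c in clusters for m in c.members}
    by_genome = pangenome.genes_by_genome(genes)
    non_target: list[tuple[str, str]] = []
    if config.non_target:
        non_target = [
            (rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(config.non_target), "fasta")
        ]
    screen = specificity.screen_primer_pairs(
        candidates,
        by_genome,
        gene_to_cluster,
        non_target,
        (config.off_target_min, config.off_target_max),
        config.screen_max_mismatches,
        config.screen_min_coverage,
    )
    log(f"screen: {len(screen.retained)} retained, {len(screen.rejected)} rejected")

    annotations = annotations or {}
    rows = [
        _report_row(p, "retained", annotations.get(p.cluster_id, "")) for p in screen.retained
    ]
    if config.keep_rejected:
        rows += [
            _report_row(r.pair, "rejected", annotations.get(r.pair.cluster_id, ""), r)
            for r in screen.rejected
        ]
    report = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    report.to_csv(outdir / "primer_report.tsv", sep="\t", index=False)

    rej = pd.DataFrame(
        [
            {
                "cluster_id": r.pair.cluster_id,
                "forward": r.pair.forward,
                "reverse": r.pair.reverse,
                "stage": r.stage,
                "subject_id": r.subject_id,
                "product_length": r.product_length,
            }
            for r in screen.rejected
        ],
        columns=["cluster_id", "forward", "reverse", "stage", "subject_id", "product_length"],
    )
    rej.to_csv(outdir / "rejections.tsv", sep="\t", index=False)

    return PipelineResult(
        report=report,
        retained=screen.retained,
        rejected=screen.rejected,
        core_clusters=core,
        n_genomes=len(genome_ids),
        n_genes=len(genes),
    )
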