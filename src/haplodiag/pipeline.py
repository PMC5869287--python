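"""End-to-end orchestration: seeded synthetic runs and consolidated reports.

A run is described by one config mapping (YAML-friendly): a master seed,
stage toggles, and per-stage parameter blocks. Every stochastic stage draws
its own child seed deterministically from the master seed and a fixed stage
index, so disabling one stage never perturbs another's numbers and a rerun
with the same config reproduces the same report (timestamps are kept out of
the report for that reason; the manifest holds provenance instead).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .coverage import (
    CoverageClasses,
    assembly_stats,
    classify_contigs,
    coverage_profiles,
    depth_arrays,
    estimate_genome_size,
    mode_coverage,
)
from .cq import CQConfig, cq_scan, tile_spans
from .expression import ExpressionConfig, quantify
from .mapping import KmerIndex, MapperConfig, best_one_of, ingest_alignments, map_pairs, map_single
from .orthologs import association_test, ingest_gene_hits, instance_crosstab
from .paired import PCConfig, annotate_alignments, build_walks, detect_pcs, doubly_mapped, pc_span_fraction
from .seqs import ContigSet, ReadSet
from .simulate import (
    ExpressionSimSpec,
    GenomeSimSpec,
    ReadSimSpec,
    simulate_assembly,
    simulate_diploid_genome,
    simulate_expression_counts,
    simulate_reads,
)
from .subtraction import cascade_filter

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = ("coverage", "pc", "busco", "cq", "rpkm", "subtract")


def _child_seed(master: int, index: int) -> int:
    ss = np.random.SeedSequence([int(master), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Validated run description.

    Exactly one data source: either ``synthetic`` generator parameters or
    user ``inputs`` (contigs plus alignments). The seed is mandatory —
    every stochastic stage depends on it.
    """

    seed: int
    outdir: str | None = None
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    synthetic: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    mapper: dict = field(default_factory=dict)
    classes: dict = field(default_factory=dict)
    pc: dict = field(default_factory=dict)
    cq: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.inputs and self.synthetic:
            raise ValueError("exactly one of synthetic/inputs may be configured")
        for s in self.stages:
            if s not in _STAGES:
                raise ValueError(f"unknown stage {s!r}")
        full = {s: True for s in _STAGES}
        full.update(self.stages)
        self.stages = full

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, False))


def run_pipeline(config: RunConfig) -> dict:
    """Execute enabled stages in dependency order; return the report dict.

    With an ``outdir``, per-stage tables, the report (``report.json``) and a
    manifest are written there. Missing upstream products raise an error
    naming the stage that needs them.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {"package_version": __version__, "seed": config.seed}

    if config.inputs:
        contigs, best4, truth = _load_inputs(config)
        genome = None
        assembly = None
    else:
        genome, assembly, contigs, best4 = _synthetic_substrate(config, outdir)
        truth = None

    lengths = contigs.lengths
    stats = assembly_stats(lengths.values())
    report["assembly"] = {
        "n_contigs": stats.n_contigs,
        "total_span": stats.total_span,
        "n50": stats.n50,
    }

    class_df = None
    classes = None
    if config.enabled("coverage"):
        if best4 is None:
            raise RuntimeError("coverage stage requires mapped reads (stage: map)")
        b1 = best_one_of(best4, seed=_child_seed(config.seed, 3))
        profiles = coverage_profiles(b1, contigs)
        classes_cfg = CoverageClasses(**config.classes) if config.classes else CoverageClasses()
        class_df, h, classes = classify_contigs(profiles, classes_cfg)
        est = estimate_genome_size(stats.total_span, h)
        ng = assembly_stats(lengths.values(), G=int(est.genome_size))
        report["coverage"] = {
            "separated_fraction": h,
            "haploid_fraction": est.haploid_fraction,
            "genome_size": est.genome_size,
            "ng50": ng.ng50,
            "class_counts": class_df["class"].value_counts().to_dict(),
            "class_center": classes.center,
            "class_halfwidth": classes.halfwidth,
        }
        if outdir:
            class_df.to_csv(outdir / "coverage_classes.tsv", sep="\t", index=False)

    if config.enabled("pc"):
        if best4 is None:
            raise RuntimeError("pc stage requires mapped reads (stage: map)")
        dm = doubly_mapped(best4)
        pc_cfg = PCConfig(**config.pc) if config.pc else PCConfig()
        pcs = detect_pcs(dm, pc_cfg, lengths)
        annotate_alignments(pcs, contigs, pc_cfg)
        pcg = build_walks(pcs, lengths, pc_cfg)
        report["pc"] = {
            "n_pcs": len(pcs),
            "fraction_exactly_twice": dm.fraction_exactly_twice,
            "pc_span_fraction": pc_span_fraction(pcs, lengths),
            "mean_identity": (
                float(np.mean([p.alignment.identity for p in pcs])) if pcs else None
            ),
            "n_walks": len(pcg.walks),
            "longest_walk_contigs": max((len(w) for w in pcg.walks), default=0),
        }
        if outdir:
            import pandas as pd

            pd.DataFrame(
                [
                    {
                        "contig_a": p.contig_a,
                        "contig_b": p.contig_b,
                        "shared_pairs": p.shared_pairs,
                        "aligned_bases": p.alignment.aligned_bases,
                        "identity": p.alignment.identity,
                    }
                    for p in pcs
                ]
            ).to_csv(outdir / "paired_contigs.tsv", sep="\t", index=False)
            pcg.walk_stats.to_csv(outdir / "walks.tsv", sep="\t", index=False)
    else:
        pcs = None

    if config.enabled("busco"):
        if class_df is None:
            raise RuntimeError("busco stage requires the coverage stage")
        if genome is not None:
            hits = assembly.gene_hits(genome)
        elif "gene_hits" in config.inputs:
            import pandas as pd

            hits = pd.read_csv(
                config.inputs["gene_hits"],
                sep="\t",
                names=["gene_id", "contig", "start", "end", "score"],
                comment="#",
            )
        else:
            raise RuntimeError("busco stage requires gene hits (inputs.gene_hits)")
        table = ingest_gene_hits(hits, dict(zip(class_df["contig"], class_df["class"])))
        xtab, summary = instance_crosstab(table)
        assoc = association_test(table)
        report["busco"] = {
            "n_genes": table.n_genes,
            **summary,
            "fisher_p": assoc.p_value,
            "odds_ratio": assoc.odds_ratio,
        }
        if outdir:
            xtab.to_csv(outdir / "ortholog_crosstab.tsv", sep="\t")

    if config.enabled("cq"):
        if genome is None:
            raise RuntimeError("cq stage requires the synthetic data source")
        report["cq"] = _cq_stage(config, genome, assembly, contigs, outdir)

    if config.enabled("rpkm"):
        if genome is None:
            raise RuntimeError("rpkm stage requires the synthetic data source")
        report["rpkm"] = _rpkm_stage(config, genome, outdir)

    if config.enabled("subtract"):
        if genome is None:
            raise RuntimeError("subtract stage requires the synthetic data source")
        report["subtract"] = _subtract_stage(config, genome, contigs)

    if outdir:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        manifest = {
            "config": {
                "seed": config.seed,
                "stages": config.stages,
                "synthetic": config.synthetic,
                "inputs": {k: str(v) for k, v in config.inputs.items()},
            },
            "package_version": __version__,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return report


# ---------------------------------------------------------------------------


def _mapper_kw(config: RunConfig) -> dict:
    return {k: v for k, v in config.mapper.items() if k in ("max_mismatches", "k", "fragment_bounds")}


def _synthetic_substrate(config: RunConfig, outdir: Path | None):
    params = dict(config.synthetic)
    read_params = params.pop("reads", {})
    gspec = GenomeSimSpec(seed=_child_seed(config.seed, 0), **params)
    genome = simulate_diploid_genome(gspec)
    assembly = simulate_assembly(genome)
    rspec = ReadSimSpec(seed=_child_seed(config.seed, 1), **read_params)
    reads = simulate_reads(genome, rspec)
    logger.info("simulated %d contigs, %d read pairs", len(assembly.contigs), reads.n)
    index = KmerIndex(assembly.contigs, MapperConfig().k)
    best4 = map_pairs(
        reads, index, MapperConfig.best4(seed=_child_seed(config.seed, 2), **_mapper_kw(config))
    )
    if outdir:
        assembly.contigs.to_fasta(outdir / "contigs.fasta")
        assembly.truth_table().to_csv(outdir / "contig_truth.tsv", sep="\t", index=False)
    return genome, assembly, assembly.contigs, best4


def _load_inputs(config: RunConfig):
    inputs = config.inputs
    if "contigs" not in inputs:
        raise RuntimeError("inputs require a contigs FASTA")
    contigs = ContigSet.from_fasta(inputs["contigs"])
    best4 = None
    if "alignments" in inputs:
        best4 = ingest_alignments(inputs["alignments"], inputs.get("dialect", "SAM"))
    elif "reads_1" in inputs:
        reads = ReadSet.from_fastq(inputs["reads_1"], inputs.get("reads_2"))
        index = KmerIndex(contigs, MapperConfig().k)
        best4 = map_pairs(
            reads, index, MapperConfig.best4(seed=_child_seed(config.seed, 2), **_mapper_kw(config))
        )
    return contigs, best4, None


def _cq_stage(config: RunConfig, genome, assembly, contigs, outdir):
    cq_params = dict(config.cq)
    depth = cq_params.pop("depth_total", 24.0)
    cfg = CQConfig(**cq_params) if cq_params else CQConfig()
    base = ReadSimSpec(
        seed=0, layout="SINGLE", depth_total=depth, error_rate=0.0
    )
    female = simulate_reads(
        genome, replace(base, sex="FEMALE", seed=_child_seed(config.seed, 4))
    )
    male = simulate_reads(
        genome, replace(base, sex="MALE", seed=_child_seed(config.seed, 5))
    )
    index = KmerIndex(contigs, MapperConfig().k)
    exact = MapperConfig.all_exact()
    f_table = map_single(female, index, exact)
    m_table = map_single(male, index, exact)
    spans = tile_spans(contigs.lengths, None, cfg)
    span_df, per_contig = cq_scan(spans, f_table, m_table, cfg)
    reporting = int(span_df["cq"].notna().sum())
    n_ms = int(span_df["male_specific"].sum())
    out = {
        "n_spans": len(span_df),
        "reporting_spans": reporting,
        "male_specific_spans": n_ms,
        "male_specific_fraction": n_ms / reporting if reporting else None,
        "has_m_locus": genome.m_locus is not None,
    }
    if genome.m_locus is not None:
        name, s, e = assembly.m_locus_contig_interval(genome)
        sub = per_contig[per_contig["contig"] == name]
        out["m_locus_contig"] = name
        out["m_locus_contig_male_specific_fraction"] = (
            float(sub["male_specific_fraction"].iloc[0]) if len(sub) else None
        )
    if outdir:
        span_df.to_csv(outdir / "cq_spans.tsv", sep="\t", index=False)
    return out


def _rpkm_stage(config: RunConfig, genome, outdir):
    expr_params = dict(config.expression)
    total_reads = expr_params.pop("total_reads", 500_000)
    target = expr_params.pop("mean_expressed_rpkm_target", 32.0)
    cfg = ExpressionConfig(**expr_params) if expr_params else ExpressionConfig()
    lengths = {
        row.gene_id: int(row.end - row.start) for row in genome.gene_truth.itertuples()
    }
    if not lengths:
        raise RuntimeError("rpkm stage requires simulated genes (gene_count > 0)")
    counts = simulate_expression_counts(
        lengths,
        ExpressionSimSpec(
            seed=_child_seed(config.seed, 6),
            total_reads=total_reads,
            mean_expressed_rpkm_target=target,
        ),
    )
    result = quantify(counts, cfg)
    if outdir:
        result.table.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    return {
        "n_transcripts": len(result.table),
        "n_expressed": int(result.table["expressed"].sum()),
        "n_het": int(result.table["het"].sum()),
        "mean_expressed_rpkm": result.mean_expressed_rpkm,
        "het_threshold": result.het_threshold,
    }


def _subtract_stage(config: RunConfig, genome, contigs):
    rng = np.random.default_rng(_child_seed(config.seed, 7))
    rspec = ReadSimSpec(
        seed=_child_seed(config.seed, 8), layout="SINGLE", depth_total=2.0, error_rate=0.0
    )
    host = simulate_reads(genome, rspec)
    n_foreign = max(1, int(host.n * 0.15 / 0.85))
    foreign = ReadSet(
        [f"foreign{i}" for i in range(n_foreign)],
        rng.integers(0, 4, (n_foreign, host.read_length), dtype=np.uint8),
    )
    mix = ReadSet(
        host.names + foreign.names, np.vstack([host.r1, foreign.r1])
    )
    # transcript stand-ins: the gene sequences on haplotype A
    t_items = []
    for row in genome.gene_truth.itertuples():
        if row.hap_a_present:
            t_items.append(
                (row.gene_id, genome.haplotypes[row.chrom][0][row.start : row.end])
            )
    if not t_items:
        raise RuntimeError("subtract stage requires simulated genes (gene_count > 0)")
    transcripts = ContigSet(t_items)
    retained, rep = cascade_filter(
        mix, transcripts, contigs, MapperConfig.best_one(seed=_child_seed(config.seed, 9), max_mismatches=2)
    )
    return {
        "total_reads": rep.total_reads,
        "removed_stage1_fraction": rep.removed_stage1_fraction,
        "removed_stage2_fraction": rep.removed_stage2_fraction,
        "remaining_fraction": rep.remaining_fraction,
        "true_foreign_fraction": n_foreign / mix.n,
    }
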