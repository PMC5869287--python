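"""Cascade host-read subtraction with stagewise accounting.

Reads are filtered in two stages — first against the host transcript set,
then survivors against the host genome — and the retained remainder is what
downstream taxonomic characterisation has to handle. Removal requires at
least one end-to-end placement within the configured mismatch tolerance
(default 2). Per-taxon assignment of the survivors ingests a BLAST tabular
hit table (the search itself is external); best hit per query is by bitscore,
ties broken by lower e-value, then lexicographic subject.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mapping import KmerIndex, MapperConfig, map_single
from .seqs import ContigSet, ReadSet

__all__ = [
    "SubtractionReport",
    "TaxonAssignment",
    "cascade_filter",
    "ingest_taxon_hits",
]


@dataclass
class SubtractionReport:
    """Exact read accounting across the two filter stages."""

    total_reads: int
    removed_stage1: int  # transcript mapping
    removed_stage2: int  # genome mapping
    remaining: int

    def __post_init__(self) -> None:
        if self.removed_stage1 + self.removed_stage2 + self.remaining != self.total_reads:
            raise ValueError("stage counts must conserve reads exactly")

    @property
    def removed_stage1_fraction(self) -> float:
        return self.removed_stage1 / self.total_reads if self.total_reads else 0.0

    @property
    def removed_stage2_fraction(self) -> float:
        return self.removed_stage2 / self.total_reads if self.total_reads else 0.0

    @property
    def remaining_fraction(self) -> float:
        return self.remaining / self.total_reads if self.total_reads else 0.0

    @property
    def estimated_downstream_workload(self) -> float:
        """Share of the original data left for taxonomic characterisation."""
        return self.remaining_fraction


def _default_config(seed: int) -> MapperConfig:
    return MapperConfig.best_one(seed=seed, max_mismatches=2)


def cascade_filter(
    reads: ReadSet,
    transcripts: ContigSet,
    genome: ContigSet,
    config: MapperConfig | None = None,
) -> tuple[ReadSet, SubtractionReport]:
    """Two-stage host filter; returns (retained reads, report).

    Single-end reads (paired input is flattened). Stage 1 removes reads with
    any placement on the transcript set; stage 2 maps survivors to the genome
    and removes placed reads. Counts are exact integers.
    """
    if len(transcripts) == 0 or len(genome) == 0:
        raise ValueError("both references must be non-empty")
    if reads.is_paired:
        reads = reads.to_single()
    config = config or _default_config(0)

    t_index = KmerIndex(transcripts, config.k)
    table1 = map_single(reads, t_index, config)
    hit1 = {n for n, pls in table1.placements.items() if pls}
    survivors_idx = [i for i, n in enumerate(reads.names) if n not in hit1]
    survivors = reads.subset(survivors_idx) if survivors_idx else None

    removed2 = 0
    if survivors is not None:
        g_index = KmerIndex(genome, config.k)
        table2 = map_single(survivors, g_index, config)
        hit2 = {n for n, pls in table2.placements.items() if pls}
        retained_idx = [i for i, n in enumerate(survivors.names) if n not in hit2]
        removed2 = survivors.n - len(retained_idx)
        retained = survivors.subset(retained_idx) if retained_idx else None
    else:
        retained = None

    report = SubtractionReport(
        total_reads=reads.n,
        removed_stage1=len(hit1),
        removed_stage2=removed2,
        remaining=retained.n if retained is not None else 0,
    )
    if retained is None:
        retained = ReadSet([], np.empty((0, reads.read_length), dtype=np.uint8))
    return retained, report


@dataclass
class TaxonAssignment:
    counts: pd.DataFrame  # taxon, n_reads
    n_assigned: int
    n_unassigned: int

    @property
    def unassigned_fraction(self) -> float:
        total = self.n_assigned + self.n_unassigned
        return self.n_unassigned / total if total else 0.0


def ingest_taxon_hits(
    hits: pd.DataFrame | str | Path,
    retained_names: list[str],
) -> TaxonAssignment:
    """Best-hit taxon counts over the retained reads.

    Accepts a DataFrame with columns (query, taxon, bitscore, evalue) or a
    BLAST tabular file in standard 12-column order (subject id serving as
    the taxon label). Retained reads with no row are unassigned.
    """
    if not isinstance(hits, pd.DataFrame):
        hits = _read_blast_tab(Path(hits))
    retained = set(retained_names)
    hits = hits[hits["query"].isin(retained)]
    if len(hits):
        best = (
            hits.sort_values(
                ["query", "bitscore", "evalue", "taxon"],
                ascending=[True, False, True, True],
            )
            .groupby("query", sort=True)
            .head(1)
        )
        counts = (
            best.groupby("taxon", sort=True).size().rename("n_reads").reset_index()
        )
        n_assigned = len(best)
    else:
        counts = pd.DataFrame(columns=["taxon", "n_reads"])
        n_assigned = 0
    return TaxonAssignment(counts, n_assigned, len(retained) - n_assigned)


def _read_blast_tab(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise ValueError(
                    f"malformed BLAST tabular at line {lineno}: expected 12 columns"
                )
            try:
                rows.append(
                    {
                        "query": parts[0],
                        "taxon": parts[1],
                        "evalue": float(parts[10]),
                        "bitscore": float(parts[11]),
                    }
                )
            except ValueError as exc:
                raise ValueError(f"malformed BLAST tabular at line {lineno}: {exc}") from exc
    return pd.DataFrame(rows, columns=["query", "taxon", "evalue", "bitscore"])
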