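"""Chromosomal-quotient scan: male-specific sequence from sexed read counts.

The chromosomal quotient of a sequence span is CQ = (female alignments) /
(male alignments), counted from all zero-mismatch alignments of male- and
female-derived reads against repeat-masked sequence. Autosomal spans sit near
CQ = 1 when both sexes are sequenced to equal depth; spans from a
male-limited region (an M-locus) attract essentially no female alignments
and report CQ below a small threshold (default 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mapping import PairPlacementTable
from .seqs import INVALID, ContigSet

__all__ = [
    "CQConfig",
    "read_mask_bed",
    "mask_contigs",
    "tile_spans",
    "cq_scan",
]


@dataclass(frozen=True)
class CQConfig:
    """Span length, CQ threshold, and the male-count floor.

    ``min_male`` guards against 0/0 and low-count artifacts — a span reports
    a CQ only when it attracts at least this many male alignments. Set it to
    1 to reproduce an unguarded quotient.
    """

    span_length: int = 1_000
    cq_threshold: float = 0.01
    min_male: int = 10

    def __post_init__(self) -> None:
        if self.span_length <= 0:
            raise ValueError("span_length must be positive")
        if not (0 < self.cq_threshold < 1):
            raise ValueError("cq_threshold must be in (0, 1)")


def read_mask_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Parse a 0-based half-open repeat-mask BED; malformed rows name the line."""
    mask: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED at line {lineno}: fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED at line {lineno}: {exc}") from exc
            if start < 0 or end <= start:
                raise ValueError(f"malformed BED at line {lineno}: bad interval")
            mask.setdefault(parts[0], []).append((start, end))
    return mask


def mask_contigs(
    contigs: ContigSet, mask: dict[str, list[tuple[int, int]]]
) -> ContigSet:
    """Hard-mask: masked bases become invalid so they can never seed a count."""
    items = []
    for name in contigs:
        codes = contigs[name].copy()
        for s, e in mask.get(name, []):
            if e > len(codes):
                raise ValueError(f"mask interval [{s},{e}) beyond {name} bounds")
            codes[s:e] = INVALID
        items.append((name, codes))
    return ContigSet(items)


def tile_spans(
    contig_lengths: dict[str, int],
    mask: dict[str, list[tuple[int, int]]] | None = None,
    config: CQConfig = CQConfig(),
) -> pd.DataFrame:
    """Non-overlapping tiles from position 0 of every contig.

    A terminal short tile is kept when it is at least half a span long.
    Fully masked tiles are flagged undefined up front — with hard-masked
    counting they can never report a CQ.
    """
    mask = mask or {}
    rows = []
    L = config.span_length
    for contig, clen in contig_lengths.items():
        intervals = _merge_intervals(mask.get(contig, []))
        for s, e in intervals:
            if e > clen:
                raise ValueError(f"mask interval [{s},{e}) beyond {contig} bounds")
        start = 0
        while start < clen:
            end = min(start + L, clen)
            if end - start < (L + 1) // 2 and start > 0:
                break  # drop a too-short terminal tile
            masked = 0
            for ms, me in intervals:
                masked += max(0, min(me, end) - max(ms, start))
            frac = masked / (end - start)
            rows.append(
                {
                    "contig": contig,
                    "start": start,
                    "end": end,
                    "masked_fraction": frac,
                    "fully_masked": frac >= 1.0,
                }
            )
            start += L
    return pd.DataFrame(rows, columns=["contig", "start", "end", "masked_fraction", "fully_masked"])


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping/adjacent intervals (mask rows may overlap)."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _starts_per_contig(table: PairPlacementTable) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {}
    for pls in table.placements.values():
        for p in pls:
            out.setdefault(p.contig_id, []).append(p.start)
    return {c: np.sort(np.array(v, dtype=np.int64)) for c, v in out.items()}


def cq_scan(
    spans: pd.DataFrame,
    female: PairPlacementTable,
    male: PairPlacementTable,
    config: CQConfig = CQConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill per-span counts and CQ; summarise male-specific fractions.

    An alignment is assigned to the span containing its start coordinate, so
    counts stay additive across tiles. CQ is reported when the span is not
    fully masked and attracts at least ``min_male`` male alignments;
    male-specific means CQ < threshold. Returns (per-span table, per-contig
    summary with the fraction of reporting spans that are male-specific).
    """
    f_starts = _starts_per_contig(female)
    m_starts = _starts_per_contig(male)
    spans = spans.copy()
    fc = np.zeros(len(spans), dtype=np.int64)
    mc = np.zeros(len(spans), dtype=np.int64)
    for i, row in enumerate(spans.itertuples(index=False)):
        fs = f_starts.get(row.contig)
        ms = m_starts.get(row.contig)
        if fs is not None:
            fc[i] = np.searchsorted(fs, row.end) - np.searchsorted(fs, row.start)
        if ms is not None:
            mc[i] = np.searchsorted(ms, row.end) - np.searchsorted(ms, row.start)
    spans["female_count"] = fc
    spans["male_count"] = mc
    defined = (~spans["fully_masked"]) & (spans["male_count"] >= config.min_male)
    spans["cq"] = np.where(defined, fc / np.maximum(mc, 1), np.nan)
    spans["male_specific"] = defined & (spans["cq"] < config.cq_threshold)

    summaries = []
    for contig, grp in spans.groupby("contig", sort=True):
        reporting = int(grp["cq"].notna().sum())
        msp = int(grp["male_specific"].sum())
        summaries.append(
            {
                "contig": contig,
                "n_spans": len(grp),
                "reporting_spans": reporting,
                "male_specific_spans": msp,
                "male_specific_fraction": msp / reporting if reporting else np.nan,
            }
        )
    return spans, pd.DataFrame(summaries)
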