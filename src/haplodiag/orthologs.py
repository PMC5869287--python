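"""Single-copy-ortholog instances vs coverage classes, and missing-gene triage.

Orthologs expected single-copy per haploid genome act as probes of assembly
duplication: in a haplotype-separated assembly most of them appear twice,
once per haplotype, and almost always on SEPARATED-class contigs. The
crosstab tabulates genes by instance count against coverage classes; the
association between "exactly two instances" and "all instances on SEPARATED
contigs" is tested with a two-sided Fisher exact test computed by exact
integer enumeration of the hypergeometric tail.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import COLLAPSED, OTHER, SEPARATED

__all__ = [
    "GeneInstanceTable",
    "AssociationResult",
    "TriageThresholds",
    "ingest_gene_hits",
    "instance_crosstab",
    "association_test",
    "fisher_exact_2x2",
    "triage_missing_genes",
]

logger = logging.getLogger(__name__)

_BINS = [1, 2, 3, 4, "5-8"]


@dataclass
class GeneInstanceTable:
    """Per-gene instances with the class profile of their host contigs."""

    instances: pd.DataFrame  # gene_id, contig, start, end, score, contig_class
    per_gene: pd.DataFrame  # gene_id, instance_count, n_sep, n_col, n_other,
    #                         only_separated, only_collapsed

    @property
    def n_genes(self) -> int:
        return len(self.per_gene)


def ingest_gene_hits(
    hits: pd.DataFrame | str | Path,
    contig_classes: dict[str, str],
    fmt: str = "tsv",
) -> GeneInstanceTable:
    """Group ortholog hits by gene and attach coverage classes.

    ``fmt`` is one of ``tsv`` (gene_id, contig, start, end, score; 0-based
    half-open), ``bed`` (contig, start, end, name, score), or ``gff``
    (1-based closed; gene id from the ID attribute). Rows referencing a
    contig without a class raise with the offending names listed.
    """
    if not isinstance(hits, pd.DataFrame):
        hits = _read_hits(Path(hits), fmt)
    hits = hits.copy()
    unknown = sorted(set(hits["contig"]) - set(contig_classes))
    if unknown:
        raise ValueError(f"hits reference unknown contigs: {', '.join(unknown)}")
    hits["contig_class"] = hits["contig"].map(contig_classes)

    rows = []
    for gene, grp in hits.groupby("gene_id", sort=True):
        n_sep = int((grp["contig_class"] == SEPARATED).sum())
        n_col = int((grp["contig_class"] == COLLAPSED).sum())
        n_other = len(grp) - n_sep - n_col
        rows.append(
            {
                "gene_id": gene,
                "instance_count": len(grp),
                "n_sep": n_sep,
                "n_col": n_col,
                "n_other": n_other,
                "only_separated": n_sep == len(grp),
                "only_collapsed": n_col == len(grp),
            }
        )
    per_gene = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "instance_count",
            "n_sep",
            "n_col",
            "n_other",
            "only_separated",
            "only_collapsed",
        ],
    )
    return GeneInstanceTable(hits, per_gene)


def _read_hits(path: Path, fmt: str) -> pd.DataFrame:
    fmt = fmt.lower()
    if fmt == "tsv":
        return pd.read_csv(
            path,
            sep="\t",
            names=["gene_id", "contig", "start", "end", "score"],
            comment="#",
        )
    if fmt == "bed":
        df = pd.read_csv(
            path,
            sep="\t",
            names=["contig", "start", "end", "gene_id", "score"],
            usecols=range(5),
            comment="#",
        )
        return df[["gene_id", "contig", "start", "end", "score"]]
    if fmt == "gff":
        import re

        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                m = re.search(r"(?:ID|Name)=([^;]+)", f[8]) if len(f) > 8 else None
                rows.append(
                    {
                        "gene_id": m.group(1) if m else f[8],
                        "contig": f[0],
                        # GFF is 1-based closed; internal is 0-based half-open
                        "start": int(f[3]) - 1,
                        "end": int(f[4]),
                        "score": float(f[5]) if f[5] != "." else np.nan,
                    }
                )
        return pd.DataFrame(rows)
    raise ValueError(f"unknown hit format {fmt!r}")


# ---------------------------------------------------------------------------


def _bin_of(count: int):
    return count if count <= 4 else "5-8"


def instance_crosstab(table: GeneInstanceTable) -> tuple[pd.DataFrame, dict[str, float]]:
    """Instance-count x coverage-class crosstab plus derived percentages.

    Rows bin instance counts 1, 2, 3, 4, 5-8 (counts above 8 join the last
    bin). Columns count genes touching / confined to each class and
    instance-level totals per class. The percentage summary reports the
    two-instance share of genes, the share of two-instance genes touching a
    SEPARATED contig, and where single-instance genes sit.
    """
    pg = table.per_gene
    if pg.empty:
        raise ValueError("empty gene table")
    pg = pg.assign(bin=pg["instance_count"].map(_bin_of))
    rows = []
    for b in _BINS:
        sub = pg[pg["bin"] == b]
        rows.append(
            {
                "instances": b,
                "genes_found": len(sub),
                "genes_with_separated": int((sub["n_sep"] >= 1).sum()),
                "genes_with_collapsed": int((sub["n_col"] >= 1).sum()),
                "genes_only_separated": int(sub["only_separated"].sum()),
                "genes_only_collapsed": int(sub["only_collapsed"].sum()),
                "instances_separated": int(sub["n_sep"].sum()),
                "instances_collapsed": int(sub["n_col"].sum()),
                "instances_other": int(sub["n_other"].sum()),
            }
        )
    df = pd.DataFrame(rows).set_index("instances")
    total = {c: int(df[c].sum()) for c in df.columns}
    df.loc["total"] = pd.Series(total)

    n_genes = total["genes_found"]
    two = df.loc[2]
    one = df.loc[1]
    summary = {
        "pct_two_instance": 100.0 * two["genes_found"] / n_genes,
        "pct_two_instance_with_separated": (
            100.0 * two["genes_with_separated"] / two["genes_found"]
            if two["genes_found"]
            else np.nan
        ),
        "pct_one_instance_on_separated": (
            100.0 * one["genes_with_separated"] / one["genes_found"]
            if one["genes_found"]
            else np.nan
        ),
        "pct_one_instance_on_collapsed": (
            100.0 * one["genes_with_collapsed"] / one["genes_found"]
            if one["genes_found"]
            else np.nan
        ),
    }
    return df, summary


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table, by exact enumeration.

    The p-value sums hypergeometric probabilities not exceeding that of the
    observed table, computed in exact integer arithmetic (so ties are exact,
    not float-fuzzy). Returns (odds_ratio, p). The odds ratio applies a 0.5
    continuity correction when any cell is zero.
    """
    (a, b), (c, d) = (int(x) for x in np.asarray(table)[0]), (
        int(x) for x in np.asarray(table)[1]
    )
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        warnings.warn("degenerate margin in 2x2 table; p = 1")
        return _odds_ratio(a, b, c, d), 1.0

    obs = comb(r1, a) * comb(r2, c1 - a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    total = 0
    for x in range(lo, hi + 1):
        w = comb(r1, x) * comb(r2, c1 - x)
        if w <= obs:
            total += w
    p = float(Fraction(total, comb(n, c1)))
    return _odds_ratio(a, b, c, d), min(p, 1.0)


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


@dataclass
class AssociationResult:
    table: np.ndarray  # rows: exactly-2 vs other; cols: only-SEPARATED vs not
    odds_ratio: float
    p_value: float


def association_test(table: GeneInstanceTable) -> AssociationResult:
    """Association of two-instance genes with SEPARATED-only placement."""
    pg = table.per_gene
    two = pg["instance_count"] == 2
    only_sep = pg["only_separated"]
    t = np.array(
        [
            [int((two & only_sep).sum()), int((two & ~only_sep).sum())],
            [int((~two & only_sep).sum()), int((~two & ~only_sep).sum())],
        ]
    )
    orr, p = fisher_exact_2x2(t)
    return AssociationResult(t, orr, p)


# ---------------------------------------------------------------------------
# missing-gene triage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TriageThresholds:
    elevation_factor: float = 1.5
    end_margin: int = 10_000
    partial_fraction: float = 0.5


def triage_missing_genes(
    table: GeneInstanceTable,
    pcs,
    depth: dict[str, np.ndarray],
    modes: dict[str, int | None],
    alignments: dict[tuple[str, str], "object"] | None = None,
    partial_hits: pd.DataFrame | None = None,
    thresholds: TriageThresholds = TriageThresholds(),
) -> pd.DataFrame:
    """Categorise genes found on only one contig of a PC.

    For each such candidate, in precedence order: COVERAGE_ELEVATED if the
    locus' mean depth is at least ``elevation_factor`` x the contig mode
    (the gene is likelier higher-copy in the genome than the assembly);
    CONTIG_END if the locus falls outside the partner-alignment footprint
    within ``end_margin`` of its boundary (the cognate copy may sit in an
    assembly gap); FRAGMENTARY if the partner carries a partial hit covering
    under ``partial_fraction`` of the gene (gene decayed, not absent); else
    CLEAN_LOSS. Genes on no PC contig are skipped with a log entry.
    """
    partner_of: dict[str, list[str]] = {}
    for pc in pcs:
        partner_of.setdefault(pc.contig_a, []).append(pc.contig_b)
        partner_of.setdefault(pc.contig_b, []).append(pc.contig_a)

    footprints = {}
    if alignments:
        for (a, b), aln in alignments.items():
            # footprint on contig a in its own coordinates
            footprints[(a, b)] = (aln.ext_a[0], None)

    inst = table.instances
    rows = []
    for gene, grp in inst.groupby("gene_id", sort=True):
        contigs_hit = set(grp["contig"])
        candidates = [
            (host, partner)
            for host in contigs_hit
            for partner in partner_of.get(host, [])
            if partner not in contigs_hit
        ]
        if not candidates and not any(c in partner_of for c in contigs_hit):
            logger.info("gene %s is not on any PC contig; skipped", gene)
            continue
        for host, partner in candidates:
            locus = grp[grp["contig"] == host].iloc[0]
            s, e = int(locus.start), int(locus.end)
            mode = modes.get(host)
            darr = depth.get(host)
            ratio = np.nan
            if darr is not None and mode:
                ratio = float(darr[s:e].mean()) / mode

            dist_to_edge = np.nan
            outside_footprint = False
            key = (host, partner) if (host, partner) in (alignments or {}) else (partner, host)
            if alignments and key in alignments:
                aln = alignments[key]
                if key[0] == host:
                    fs = aln.ext_a[0]
                    fe = len(depth.get(host, [])) - aln.ext_a[1] if host in depth else None
                else:
                    fs = aln.ext_b[0]
                    fe = len(depth.get(host, [])) - aln.ext_b[1] if host in depth else None
                if fe is not None:
                    if e <= fs:
                        outside_footprint, dist_to_edge = True, fs - e
                    elif s >= fe:
                        outside_footprint, dist_to_edge = True, s - fe

            partial_frac = 0.0
            if partial_hits is not None:
                ph = partial_hits[
                    (partial_hits["gene_id"] == gene) & (partial_hits["contig"] == partner)
                ]
                if len(ph):
                    partial_frac = float(
                        (ph["end"] - ph["start"]).max() / max(e - s, 1)
                    )

            if np.isfinite(ratio) and ratio >= thresholds.elevation_factor:
                cat = "COVERAGE_ELEVATED"
            elif outside_footprint and dist_to_edge <= thresholds.end_margin:
                cat = "CONTIG_END"
            elif 0 < partial_frac < thresholds.partial_fraction:
                cat = "FRAGMENTARY"
            else:
                cat = "CLEAN_LOSS"
            rows.append(
                {
                    "gene_id": gene,
                    "contig": host,
                    "partner": partner,
                    "category": cat,
                    "depth_ratio": ratio,
                    "dist_to_footprint_edge": dist_to_edge,
                    "partner_partial_fraction": partial_frac,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "contig",
            "partner",
            "category",
            "depth_ratio",
            "dist_to_footprint_edge",
            "partner_partial_fraction",
        ],
    )
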