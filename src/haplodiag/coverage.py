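"""Per-contig depth histograms, mode coverage, class assignment, genome size.

The central statistic is the *mode coverage* of a contig: among 3-wide depth
windows [d-1, d+1] with centers d = 4, 5, 6, ... (so the lowest window is
3x-5x), the center of the window containing the most bases. A contig whose
mode falls in c +/- w (default 18 +/- 6) is called SEPARATED — it carries one
haplotype and attracts half the diploid depth — while 2c +/- w (36 +/- 6) is
COLLAPSED. The separated fraction h of assembled bases then gives the haploid
genome size as S * (h/2 + (1 - h)): separated bases are counted twice in the
assembly, collapsed bases once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mapping import BEST_ONE, PairPlacementTable
from .seqs import ContigSet

__all__ = [
    "CoverageProfile",
    "CoverageClasses",
    "GenomeSizeEstimate",
    "AssemblyStats",
    "depth_arrays",
    "depth_histogram",
    "coverage_profiles",
    "mode_coverage",
    "classify_contigs",
    "estimate_genome_size",
    "assembly_stats",
]

SEPARATED = "SEPARATED"
COLLAPSED = "COLLAPSED"
OTHER = "OTHER"


@dataclass
class CoverageProfile:
    """Depth histogram of one contig; ``histogram[d]`` = bases at depth d."""

    contig_id: str
    depth_histogram: np.ndarray
    span: int

    def __post_init__(self) -> None:
        if int(self.depth_histogram.sum()) != self.span:
            raise ValueError("histogram total must equal contig span")


@dataclass(frozen=True)
class CoverageClasses:
    """Class windows for contig modes.

    FIXED uses the given center/halfwidth; AUTO re-estimates the primary
    center as the span-weighted modal mode across contigs and sets
    w = round(c/3). Windows are closed intervals; with w < c/2 the SEPARATED
    and COLLAPSED windows cannot overlap.
    """

    center: int = 18
    halfwidth: int = 6
    estimation: str = "FIXED"  # FIXED | AUTO

    def __post_init__(self) -> None:
        if self.halfwidth >= self.center:
            raise ValueError("halfwidth must be smaller than center")
        if self.estimation not in ("FIXED", "AUTO"):
            raise ValueError("estimation must be FIXED or AUTO")

    def classify(self, mode: int | None) -> str:
        if mode is None:
            return OTHER
        c, w = self.center, self.halfwidth
        if c - w <= mode <= c + w:
            return SEPARATED
        if 2 * c - w <= mode <= 2 * c + w:
            return COLLAPSED
        return OTHER


@dataclass
class GenomeSizeEstimate:
    assembly_span: int
    separated_fraction: float

    @property
    def haploid_fraction(self) -> float:
        h = self.separated_fraction
        return h / 2 + (1 - h)

    @property
    def genome_size(self) -> float:
        return self.assembly_span * self.haploid_fraction


@dataclass
class AssemblyStats:
    n_contigs: int
    total_span: int
    n50: int
    ng50: int | None = None


# ---------------------------------------------------------------------------


def depth_arrays(
    table: PairPlacementTable, contigs: ContigSet, require_best_one: bool = True
) -> dict[str, np.ndarray]:
    """Per-base depth per contig from aligned mate spans (not fragment gaps)."""
    if require_best_one and table.mode != BEST_ONE:
        raise ValueError("depth requires a BEST_ONE placement table")
    lengths = contigs.lengths
    diff = {n: np.zeros(L + 1, dtype=np.int64) for n, L in lengths.items()}
    for pls in table.placements.values():
        for p in pls:
            if table.layout == "paired" and not p.is_concordant:
                continue
            d = diff.get(p.contig_id)
            if d is None:
                raise ValueError(f"placement on unknown contig {p.contig_id!r}")
            L = lengths[p.contig_id]
            for s, e in p.mate_spans:
                if s < 0 or e > L:
                    raise ValueError(
                        f"placement [{s},{e}) beyond bounds of {p.contig_id} (len {L})"
                    )
                d[s] += 1
                d[e] -= 1
    return {n: np.cumsum(d[:-1]) for n, d in diff.items()}


def depth_histogram(
    table: PairPlacementTable, contigs: ContigSet, contig_id: str
) -> CoverageProfile:
    """Depth histogram for one contig (mode left to :func:`mode_coverage`)."""
    depth = depth_arrays(table, contigs)[contig_id]
    hist = np.bincount(depth)
    return CoverageProfile(contig_id, hist, contigs.length(contig_id))


def coverage_profiles(
    table: PairPlacementTable, contigs: ContigSet
) -> dict[str, CoverageProfile]:
    """All contigs at once (one pass over the placement table)."""
    depths = depth_arrays(table, contigs)
    return {
        n: CoverageProfile(n, np.bincount(d), contigs.length(n))
        for n, d in depths.items()
    }


def mode_coverage(profile: CoverageProfile) -> int | None:
    """Center of the best-supported 3-wide depth window; None if all bases <3x.

    Windows slide by one (centers 4, 5, 6, ...); depths below 3 are never
    counted. Tied windows prefer the one whose center bin holds more bases
    (so a uniform-depth contig reports its own depth), then the smallest
    center.
    """
    h = profile.depth_histogram
    if h.sum() == 0:
        raise ValueError("empty histogram")
    if h[3:].sum() == 0:
        return None
    hh = np.concatenate([h, np.zeros(3, dtype=h.dtype)])
    best_center, best_key = None, (-1, -1)
    for d in range(4, len(h) + 1):
        key = (int(hh[d - 1 : d + 2].sum()), int(hh[d]))
        if key > best_key:
            best_center, best_key = d, key
    return best_center


def classify_contigs(
    profiles: dict[str, CoverageProfile] | list[CoverageProfile],
    classes: CoverageClasses = CoverageClasses(),
) -> tuple[pd.DataFrame, float, CoverageClasses]:
    """Assign a coverage class per contig and compute the separated fraction.

    Returns (per-contig table, h, resolved classes). h is the SEPARATED span
    over the total span of all contigs; contigs with undefined mode fall into
    OTHER. AUTO estimation needs at least 2 contigs.
    """
    if isinstance(profiles, dict):
        profiles = list(profiles.values())
    modes = {p.contig_id: mode_coverage(p) for p in profiles}
    spans = {p.contig_id: p.span for p in profiles}

    if classes.estimation == "AUTO":
        if len(profiles) < 2:
            raise ValueError("AUTO class estimation requires >= 2 contigs")
        weight: dict[int, int] = {}
        for n, m in modes.items():
            if m is not None:
                weight[m] = weight.get(m, 0) + spans[n]
        if not weight:
            raise ValueError("no contig has a defined mode")
        c = max(sorted(weight), key=lambda m: weight[m])
        classes = CoverageClasses(center=c, halfwidth=int(round(c / 3)), estimation="AUTO")

    rows = [
        {
            "contig": n,
            "span": spans[n],
            "mode": modes[n] if modes[n] is not None else np.nan,
            "class": classes.classify(modes[n]),
        }
        for n in modes
    ]
    df = pd.DataFrame(rows)
    total = int(df["span"].sum())
    sep = int(df.loc[df["class"] == SEPARATED, "span"].sum())
    h = sep / total if total else 0.0
    return df, h, classes


def estimate_genome_size(assembly_span: int, separated_fraction: float) -> GenomeSizeEstimate:
    """Haplotype-separation genome-size model: G = S * (h/2 + (1 - h))."""
    if not (0 <= separated_fraction <= 1):
        raise ValueError("separated fraction must be in [0, 1]")
    return GenomeSizeEstimate(assembly_span, separated_fraction)


def assembly_stats(lengths, G: int | None = None) -> AssemblyStats:
    """N50 (and NG50 given a genome size G) from contig lengths."""
    lengths = sorted(int(x) for x in lengths)
    if not lengths or lengths[0] <= 0:
        raise ValueError("lengths must be a non-empty list of positive integers")
    total = sum(lengths)
    desc = lengths[::-1]
    csum = np.cumsum(desc)

    def _nx(target: float) -> int | None:
        idx = np.searchsorted(csum, target)
        return desc[int(idx)] if idx < len(desc) else None

    n50 = _nx(total / 2)
    ng50 = _nx(G / 2) if G is not None else None
    return AssemblyStats(len(lengths), total, int(n50), ng50 if ng50 is None else int(ng50))
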