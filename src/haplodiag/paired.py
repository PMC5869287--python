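"""Paired contigs: detection from doubly-mapped pairs, similarity, and walks.

Two contigs that capture the two haplotypes of one genomic region share the
read pairs that map exactly twice — once on each. Counting those shared pairs
over a multi-placement mapping (the "best 4" table) and thresholding yields
*paired contigs* (PCs). An anchor-based alignment between the two contigs of
a PC then estimates how much of them aligns and at what identity, and where
each contig extends past the other; chains of such mutual extensions form
"walks" tiling regions longer than any single contig.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .mapping import BEST_ONE, PairPlacementTable
from .seqs import ContigSet

__all__ = [
    "PCConfig",
    "PairedContig",
    "DoublyMapped",
    "PCAlignment",
    "PCGraph",
    "doubly_mapped",
    "detect_pcs",
    "intra_pc_alignment",
    "annotate_alignments",
    "build_walks",
]


@dataclass(frozen=True)
class PCConfig:
    """Detection and alignment parameters.

    Exactly one of ``min_shared_pairs`` (absolute; fidelity default 10 000)
    and ``density_per_kb`` may be active. The density alternative exists so
    genomes far below gigabase scale can exercise detection: the effective
    threshold is ``density_per_kb * min(contig spans) / 1000``.
    """

    min_shared_pairs: int | None = 10_000
    density_per_kb: float | None = None
    anchor_k: int = 21
    max_anchor_gap: int = 500
    min_extension: int = 5_000

    def __post_init__(self) -> None:
        if (self.min_shared_pairs is None) == (self.density_per_kb is None):
            raise ValueError(
                "exactly one of min_shared_pairs and density_per_kb must be set"
            )

    def threshold_for(self, span_a: int, span_b: int) -> float:
        if self.min_shared_pairs is not None:
            return float(self.min_shared_pairs)
        return self.density_per_kb * min(span_a, span_b) / 1000.0


@dataclass
class DoublyMapped:
    """Shared-pair counts and the exactly-twice accounting.

    ``pair_counts`` maps an ordered (sorted) contig-name pair to the number
    of read pairs with exactly two concordant placements, one on each.
    Same-contig double placements are tallied separately and never feed PCs.
    """

    pair_counts: dict[tuple[str, str], int]
    intra_contig_twice: int
    n_mapped: int
    n_exactly_twice: int
    multiplicity: dict[int, int]

    @property
    def fraction_exactly_twice(self) -> float:
        return self.n_exactly_twice / self.n_mapped if self.n_mapped else 0.0


@dataclass
class PCAlignment:
    aligned_bases: int
    identity: float
    strand: str  # "+" | "-"
    n_anchors: int
    # extensions in the *aligned frame*: for "-" strand, B's sides are given
    # in reverse-complement coordinates so "left"/"right" oppose A's sides.
    ext_a: tuple[int, int]
    ext_b: tuple[int, int]


@dataclass
class PairedContig:
    contig_a: str
    contig_b: str
    shared_pairs: int
    alignment: PCAlignment | None = None


@dataclass
class PCGraph:
    graph: nx.Graph
    walks: list[list[str]]
    walk_stats: "object" = None  # pandas DataFrame


# ---------------------------------------------------------------------------


def doubly_mapped(table: PairPlacementTable) -> DoublyMapped:
    """Count read pairs placed exactly twice, split by contig-pair.

    Requires a multi-placement table: a BEST_ONE table cannot report the
    multiplicity this statistic is built on.
    """
    if table.mode == BEST_ONE:
        raise ValueError(
            "doubly_mapped requires a multi-placement (BEST_K/ALL_EXACT) table; "
            "a BEST_ONE table cannot carry multiplicity"
        )
    pair_counts: dict[tuple[str, str], int] = {}
    intra = 0
    n_mapped = 0
    n_twice = 0
    multiplicity: dict[int, int] = {}
    for pls in table.placements.values():
        if not pls:
            continue
        n_mapped += 1
        m = len(pls)
        multiplicity[m] = multiplicity.get(m, 0) + 1
        if m != 2:
            continue
        n_twice += 1
        a, b = pls[0].contig_id, pls[1].contig_id
        if a == b:
            intra += 1
        else:
            key = (a, b) if a < b else (b, a)
            pair_counts[key] = pair_counts.get(key, 0) + 1
    return DoublyMapped(pair_counts, intra, n_mapped, n_twice, multiplicity)


def detect_pcs(
    dm: DoublyMapped,
    config: PCConfig,
    contig_lengths: dict[str, int] | None = None,
) -> list[PairedContig]:
    """Keep contig pairs whose shared-pair count meets the threshold."""
    if config.density_per_kb is not None and contig_lengths is None:
        raise ValueError("density threshold requires contig lengths")
    out = []
    for (a, b), n in sorted(dm.pair_counts.items()):
        thr = config.threshold_for(
            contig_lengths[a] if contig_lengths else 0,
            contig_lengths[b] if contig_lengths else 0,
        )
        if n >= thr:
            out.append(PairedContig(a, b, n))
    out.sort(key=lambda pc: -pc.shared_pairs)
    return out


def pc_membership(pcs: list[PairedContig]) -> dict[str, int]:
    """How many PCs each contig participates in."""
    counts: dict[str, int] = {}
    for pc in pcs:
        for c in (pc.contig_a, pc.contig_b):
            counts[c] = counts.get(c, 0) + 1
    return counts


def pc_span_fraction(pcs: list[PairedContig], contig_lengths: dict[str, int]) -> float:
    """Fraction of assembled bases incorporated in PC contigs."""
    members = {c for pc in pcs for c in (pc.contig_a, pc.contig_b)}
    total = sum(contig_lengths.values())
    return sum(contig_lengths[c] for c in members) / total if total else 0.0


# ---------------------------------------------------------------------------
# anchor-based intra-PC alignment
# ---------------------------------------------------------------------------


def _unique_kmers(codes: np.ndarray, k: int) -> dict[int, int]:
    """k-mer -> position for k-mers occurring exactly once (valid bases only)."""
    n = len(codes) - k + 1
    if n <= 0:
        return {}
    vals = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        vals = (vals << np.uint64(2)) | np.minimum(codes[j : j + n], 3).astype(np.uint64)
    bad = (codes >= 4).astype(np.int64)
    cbad = np.concatenate([[0], np.cumsum(bad)])
    ok = (cbad[k:] - cbad[:-k]) == 0
    vals = np.where(ok, vals, np.uint64(0xFFFFFFFFFFFFFFFF))
    uniq, first, counts = np.unique(vals, return_index=True, return_counts=True)
    out: dict[int, int] = {}
    for v, i, c in zip(uniq, first, counts):
        if c == 1 and v != np.uint64(0xFFFFFFFFFFFFFFFF):
            out[int(v)] = int(i)
    return out


def _lis_chain(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest colinear subsequence (increasing in both coordinates)."""
    if not anchors:
        return []
    anchors.sort()
    import bisect

    tails: list[int] = []  # posB tails of active chains
    tails_idx: list[int] = []
    parent = [-1] * len(anchors)
    for i, (_, b) in enumerate(anchors):
        j = bisect.bisect_left(tails, b)
        if j == len(tails):
            tails.append(b)
            tails_idx.append(i)
        else:
            tails[j] = b
            tails_idx[j] = i
        parent[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1]
    while i != -1:
        chain.append(anchors[i])
        i = parent[i]
    return chain[::-1]


def intra_pc_alignment(
    seq_a: np.ndarray, seq_b: np.ndarray, config: PCConfig = PCConfig()
) -> PCAlignment:
    """Anchor-chain alignment between the two contigs of a PC.

    Anchors are k-mers unique in both contigs; the longest colinear chain per
    strand is kept, thinned to non-overlapping anchors, and merged into
    blocks wherever consecutive anchor gaps stay within ``max_anchor_gap``.
    Identity counts matched columns over anchors plus gap-free comparison of
    equal-length inter-anchor gaps; unequal gaps contribute nothing aligned.
    ``aligned_bases`` is the merged block footprint on contig A.
    """
    k = config.anchor_k
    if len(seq_a) < k or len(seq_b) < k:
        raise ValueError("contig shorter than anchor k")
    ka = _unique_kmers(seq_a, k)
    kb_f = _unique_kmers(seq_b, k)
    rc = seq_b[::-1].copy()
    valid = rc < 4
    rc[valid] = 3 - rc[valid]
    kb_r = _unique_kmers(rc, k)

    fwd = [(pa, kb_f[v]) for v, pa in ka.items() if v in kb_f]
    rev = [(pa, kb_r[v]) for v, pa in ka.items() if v in kb_r]
    if len(fwd) == 0 and len(rev) == 0:
        return PCAlignment(0, 0.0, "+", 0, (len(seq_a), 0), (len(seq_b), 0))

    strand, anchors, b_seq = ("+", fwd, seq_b) if len(fwd) >= len(rev) else ("-", rev, rc)
    chain = _lis_chain(anchors)

    # thin to non-overlapping anchors
    thin: list[tuple[int, int]] = []
    for pa, pb in chain:
        if not thin or (pa >= thin[-1][0] + k and pb >= thin[-1][1] + k):
            thin.append((pa, pb))
    if not thin:
        return PCAlignment(0, 0.0, strand, 0, (len(seq_a), 0), (len(seq_b), 0))

    matched = 0
    aligned_cols = 0
    footprint = 0
    block_start_a = thin[0][0]
    prev_a, prev_b = thin[0]
    matched += k
    aligned_cols += k
    for pa, pb in thin[1:]:
        ga = pa - (prev_a + k)
        gb = pb - (prev_b + k)
        if ga > config.max_anchor_gap or gb > config.max_anchor_gap:
            footprint += prev_a + k - block_start_a
            block_start_a = pa
        elif ga == gb and ga > 0:
            sa = seq_a[prev_a + k : pa]
            sb = b_seq[prev_b + k : pb]
            matched += int(np.sum((sa == sb) & (sa < 4)))
            aligned_cols += ga
        # unequal gaps within tolerance stay in the footprint but unaligned
        matched += k
        aligned_cols += k
        prev_a, prev_b = pa, pb
    footprint += prev_a + k - block_start_a

    identity = matched / aligned_cols if aligned_cols else 0.0
    first_a, first_b = thin[0]
    last_a, last_b = prev_a + k, prev_b + k
    ext_a = (first_a, len(seq_a) - last_a)
    ext_b = (first_b, len(b_seq) - last_b)
    return PCAlignment(int(footprint), float(identity), strand, len(thin), ext_a, ext_b)


def annotate_alignments(
    pcs: list[PairedContig], contigs: ContigSet, config: PCConfig = PCConfig()
) -> list[PairedContig]:
    """Fill each PC's alignment slot in place (and return the list)."""
    for pc in pcs:
        pc.alignment = intra_pc_alignment(contigs[pc.contig_a], contigs[pc.contig_b], config)
    return pcs


# ---------------------------------------------------------------------------
# walks
# ---------------------------------------------------------------------------

TILING = "TILING"
CONTAINED = "CONTAINED"


def _edge_kind(aln: PCAlignment, t: int) -> str:
    """TILING when each contig extends past the other on opposite ends."""
    a_l, a_r = (x >= t for x in aln.ext_a)
    b_l, b_r = (x >= t for x in aln.ext_b)
    if (a_l and not a_r and b_r and not b_l) or (a_r and not a_l and b_l and not b_r):
        return TILING
    return CONTAINED


def build_walks(
    pcs: list[PairedContig],
    contig_lengths: dict[str, int],
    config: PCConfig = PCConfig(),
) -> PCGraph:
    """Assemble walks: maximal simple paths over TILING edges.

    Greedy and disclosed as heuristic: walks start from the highest
    shared-pair edge and extend both ends toward the heaviest incident
    TILING edge leading to an unused contig, so walks are vertex-disjoint.
    """
    import pandas as pd

    g = nx.Graph()
    for pc in pcs:
        if pc.alignment is None:
            raise ValueError("build_walks requires annotated alignments")
        kind = _edge_kind(pc.alignment, config.min_extension)
        g.add_edge(pc.contig_a, pc.contig_b, shared=pc.shared_pairs, kind=kind)

    tiling = [
        (d["shared"], a, b) for a, b, d in g.edges(data=True) if d["kind"] == TILING
    ]
    tiling.sort(reverse=True)
    used: set[str] = set()
    walks: list[list[str]] = []
    for shared, a, b in tiling:
        if a in used or b in used:
            continue
        path = [a, b]
        used.update(path)
        for endpoint_side in (0, 1):
            while True:
                end = path[0] if endpoint_side == 0 else path[-1]
                nxt = None
                best = -1
                for nb in g.neighbors(end):
                    d = g.edges[end, nb]
                    if d["kind"] == TILING and nb not in used and d["shared"] > best:
                        nxt, best = nb, d["shared"]
                if nxt is None:
                    break
                used.add(nxt)
                if endpoint_side == 0:
                    path.insert(0, nxt)
                else:
                    path.append(nxt)
        walks.append(path)

    rows = [
        {
            "walk": i,
            "n_contigs": len(w),
            "n_pcs": len(w) - 1,
            "span": sum(contig_lengths[c] for c in w),
            "contigs": ",".join(w),
        }
        for i, w in enumerate(walks)
    ]
    stats = pd.DataFrame(rows, columns=["walk", "n_contigs", "n_pcs", "span", "contigs"])
    return PCGraph(g, walks, stats)
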