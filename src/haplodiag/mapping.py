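"""Read-pair placement: an exact-seed / mismatch-verify mapper and ingestion.

The internal mapper is substitution-only: candidate diagonals come from exact
k-mer seeds (both strands), each candidate is verified end-to-end by counting
mismatching columns, and only concordant pair placements (both mates on one
contig, FR, fragment length within bounds) are reported. Three modes mirror
the mapping contracts used throughout the analysis:

* ``BEST_ONE``  – one minimum-mismatch placement per pair, ties broken by a
  seeded RNG (the coverage substrate).
* ``BEST_K``    – up to ``max_placements`` best placements (the "best 4"
  substrate for paired-contig detection).
* ``ALL_EXACT`` – every zero-mismatch placement, uncapped (the chromosomal
  quotient substrate). In this mode the seed scheme is lossless: an exact
  occurrence always shares a seed, so results equal brute-force search.

Gapped alignment is out of scope; users with indel-bearing real data supply
SAM/BAM/PAF, which :func:`ingest_alignments` normalises to the same table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .seqs import ContigSet, ReadSet

__all__ = [
    "Placement",
    "PairPlacementTable",
    "MapperConfig",
    "KmerIndex",
    "build_index",
    "map_pairs",
    "map_single",
    "best_one_of",
    "ingest_alignments",
    "write_sam",
]

BEST_ONE = "BEST_ONE"
BEST_K = "BEST_K"
ALL_EXACT = "ALL_EXACT"


@dataclass(slots=True)
class Placement:
    """One candidate placement of a read pair (or single read) on a contig.

    ``start``/``end`` are 0-based half-open over the full footprint;
    ``mate_spans`` holds the aligned span of each mate separately (one span
    for single-end data). Concordant implies FR orientation with both mates
    on this contig and fragment length within the configured bounds.
    """

    contig_id: str
    start: int
    end: int
    orientation: str  # FR/RF/FF for pairs, F/R for single-end
    mismatches: int
    is_concordant: bool
    mate_spans: tuple[tuple[int, int], ...]


@dataclass
class PairPlacementTable:
    """Per-query placements, sorted by (mismatches, contig_id, start).

    Queries with no reported placement are absent from ``placements`` but
    counted in ``n_queries``.
    """

    mode: str
    layout: str  # "paired" | "single"
    placements: dict[str, list[Placement]]
    n_queries: int

    @property
    def n_mapped(self) -> int:
        return sum(1 for v in self.placements.values() if v)

    @property
    def mapped_fraction(self) -> float:
        return self.n_mapped / self.n_queries if self.n_queries else 0.0


@dataclass(frozen=True)
class MapperConfig:
    seed: int = 0
    mode: str = BEST_ONE
    max_placements: int = 1
    max_mismatches: int = 18
    fragment_bounds: tuple[int, int] = (50, 1200)
    k: int = 13

    def __post_init__(self) -> None:
        if self.max_placements < 1:
            raise ValueError("max_placements must be >= 1")
        if self.mode == ALL_EXACT and self.max_mismatches != 0:
            raise ValueError("ALL_EXACT requires max_mismatches = 0")
        if self.mode not in (BEST_ONE, BEST_K, ALL_EXACT):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def best_one(cls, seed: int = 0, **kw) -> "MapperConfig":
        return cls(seed=seed, mode=BEST_ONE, max_placements=1, **kw)

    @classmethod
    def best4(cls, seed: int = 0, **kw) -> "MapperConfig":
        """The "best 4" preset used for paired-contig detection."""
        return cls(seed=seed, mode=BEST_K, max_placements=4, **kw)

    @classmethod
    def all_exact(cls, seed: int = 0, **kw) -> "MapperConfig":
        kw.setdefault("max_placements", 1_000_000)
        return cls(seed=seed, mode=ALL_EXACT, max_mismatches=0, **kw)


class KmerIndex:
    """Exact k-mer location index over the forward strand of every contig.

    Reverse-strand hits are found by querying the reverse complement of the
    read, so the index itself stays single-stranded. Windows containing
    non-ACGT bases (e.g. hard-masked repeats) are never indexed.
    """

    def __init__(self, contigs: ContigSet, k: int = 13):
        if len(contigs) == 0:
            raise ValueError("contigs must be non-empty")
        if not (1 <= k <= 31):
            raise ValueError("k must be in [1, 31]")
        self.k = k
        self.contigs = contigs
        self.names = contigs.names
        lens = np.array([contigs.length(n) for n in self.names], dtype=np.int64)
        self.contig_lengths = lens
        self.offsets = np.concatenate([[0], np.cumsum(lens)])[:-1]
        self.concat = np.concatenate([contigs[n] for n in self.names])
        total = self.concat.shape[0]

        n_win = total - k + 1
        if n_win <= 0:
            raise ValueError("all contigs shorter than k")
        vals = np.zeros(n_win, dtype=np.uint64)
        for j in range(k):
            vals = (vals << np.uint64(2)) | np.minimum(
                self.concat[j : j + n_win], 3
            ).astype(np.uint64)
        bad = (self.concat >= 4).astype(np.int64)
        cbad = np.concatenate([[0], np.cumsum(bad)])
        window_bad = (cbad[k:] - cbad[:-k]) > 0
        allowed = np.zeros(n_win, dtype=bool)
        for off, ln in zip(self.offsets, lens):
            if ln >= k:
                allowed[off : off + ln - k + 1] = True
        keep = allowed & ~window_bad
        positions = np.flatnonzero(keep).astype(np.int64)
        kmers = vals[positions]
        order = np.argsort(kmers, kind="stable")
        self._kmers = kmers[order]
        self._pos = positions[order]

    def n_kmers(self) -> int:
        return self._kmers.shape[0]

    def lookup(self, kmer: str | int) -> list[tuple[str, int]]:
        """All (contig, position) occurrences of one k-mer (forward strand)."""
        if isinstance(kmer, str):
            from .seqs import encode

            codes = encode(kmer)
            if len(codes) != self.k or np.any(codes >= 4):
                raise ValueError("k-mer length/content mismatch")
            val = 0
            for c in codes:
                val = (val << 2) | int(c)
        else:
            val = kmer
        val = np.uint64(val)
        lo = np.searchsorted(self._kmers, val, "left")
        hi = np.searchsorted(self._kmers, val, "right")
        out = []
        for g in self._pos[lo:hi]:
            ci = int(np.searchsorted(self.offsets, g, "right") - 1)
            out.append((self.names[ci], int(g - self.offsets[ci])))
        return out

    def contig_of(self, gpos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.offsets, gpos, "right") - 1


def build_index(contigs: ContigSet, k: int = 13) -> KmerIndex:
    return KmerIndex(contigs, k)


# ---------------------------------------------------------------------------
# candidate generation + verification (vectorised core)
# ---------------------------------------------------------------------------

_MAX_HITS_PER_SEED = 64


def _seed_offsets(read_len: int, k: int) -> np.ndarray:
    offs = list(range(0, read_len - k + 1, k))
    if offs[-1] != read_len - k:
        offs.append(read_len - k)
    return np.array(offs, dtype=np.int64)


def _query_kmers(mat: np.ndarray, offs: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(n_reads, n_seeds) kmer values + validity mask."""
    n = mat.shape[0]
    vals = np.zeros((n, len(offs)), dtype=np.uint64)
    valid = np.ones((n, len(offs)), dtype=bool)
    for si, s in enumerate(offs):
        window = mat[:, s : s + k]
        valid[:, si] = ~np.any(window >= 4, axis=1)
        v = np.zeros(n, dtype=np.uint64)
        for j in range(k):
            v = (v << np.uint64(2)) | np.minimum(window[:, j], 3).astype(np.uint64)
        vals[:, si] = v
    return vals, valid


def _candidates_one_orientation(
    mat: np.ndarray, index: KmerIndex
) -> tuple[np.ndarray, np.ndarray]:
    """Unique (read_idx, global_start) candidate diagonals for one orientation."""
    n, L = mat.shape
    k = index.k
    if L < k:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    offs = _seed_offsets(L, k)
    vals, valid = _query_kmers(mat, offs, k)

    flat_vals = vals.ravel()
    flat_valid = valid.ravel()
    lo = np.searchsorted(index._kmers, flat_vals, "left")
    hi = np.searchsorted(index._kmers, flat_vals, "right")
    cnt = hi - lo
    cnt[~flat_valid] = 0
    cnt[cnt > _MAX_HITS_PER_SEED] = 0  # repeat seeds carry no placement signal

    total = int(cnt.sum())
    if total == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    rep = np.repeat(np.arange(flat_vals.shape[0]), cnt)
    within = np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt)
    gpos = index._pos[np.repeat(lo, cnt) + within]
    seed_off = offs[rep % len(offs)]
    read_idx = rep // len(offs)
    start = gpos - seed_off

    ok = start >= 0
    read_idx, start = read_idx[ok], start[ok]
    ci = index.contig_of(start)
    end_ok = start + L <= index.offsets[ci] + index.contig_lengths[ci]
    begin_ok = start >= index.offsets[ci]
    read_idx, start = read_idx[ok2 := (end_ok & begin_ok)], start[ok2]

    key = read_idx * np.int64(index.concat.shape[0] + L + 1) + start
    _, uniq = np.unique(key, return_index=True)
    return read_idx[uniq], start[uniq]


def _verify(
    mat: np.ndarray,
    index: KmerIndex,
    read_idx: np.ndarray,
    start: np.ndarray,
    max_mismatches: int,
    chunk: int = 200_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """End-to-end mismatch count; keeps candidates within tolerance."""
    L = mat.shape[1]
    keep_r, keep_s, keep_m = [], [], []
    window = np.arange(L)
    for i in range(0, read_idx.shape[0], chunk):
        r = read_idx[i : i + chunk]
        s = start[i : i + chunk]
        ref = index.concat[s[:, None] + window]
        reads = mat[r]
        mism = np.count_nonzero((ref != reads) | (ref >= 4), axis=1)
        ok = mism <= max_mismatches
        keep_r.append(r[ok])
        keep_s.append(s[ok])
        keep_m.append(mism[ok])
    if not keep_r:
        return (np.empty(0, np.int64),) * 3
    return np.concatenate(keep_r), np.concatenate(keep_s), np.concatenate(keep_m)


def _end_to_end_hits(
    mat: np.ndarray, index: KmerIndex, max_mismatches: int
) -> list[list[tuple[int, int, str, int]]]:
    """Per-read list of (contig_idx, local_start, orient, mismatches)."""
    n, L = mat.shape
    per_read: list[list[tuple[int, int, str, int]]] = [[] for _ in range(n)]
    rc = mat[:, ::-1].copy()
    rc_valid = rc < 4
    rc[rc_valid] = 3 - rc[rc_valid]
    for orient, m in (("F", mat), ("R", rc)):
        ridx, start = _candidates_one_orientation(m, index)
        ridx, start, mism = _verify(m, index, ridx, start, max_mismatches)
        ci = index.contig_of(start)
        local = start - index.offsets[ci]
        for r, c, s, mm in zip(ridx, ci, local, mism):
            per_read[int(r)].append((int(c), int(s), orient, int(mm)))
    return per_read


# ---------------------------------------------------------------------------
# public mapping operations
# ---------------------------------------------------------------------------


def map_pairs(reads: ReadSet, index: KmerIndex, config: MapperConfig) -> PairPlacementTable:
    """Place read pairs; only concordant placements are reported.

    A pair with zero concordant placements is reported unmapped (absent from
    the table but counted). BEST_ONE applies a seeded random tie-break among
    equal-mismatch placements; BEST_K truncates to ``max_placements`` after a
    deterministic sort plus a seeded shuffle of the tie group at the cut.
    """
    if not reads.is_paired:
        raise ValueError("map_pairs requires paired reads; use map_single")
    if reads.read_length < index.k:
        raise ValueError("read length shorter than index k")
    L = reads.read_length
    hits1 = _end_to_end_hits(reads.r1, index, config.max_mismatches)
    hits2 = _end_to_end_hits(reads.r2, index, config.max_mismatches)
    fmin, fmax = config.fragment_bounds
    rng = np.random.default_rng(config.seed)

    placements: dict[str, list[Placement]] = {}
    for i, name in enumerate(reads.names):
        cands: list[Placement] = []
        for a, b in ((hits1[i], hits2[i]), (hits2[i], hits1[i])):
            for ca, sa, oa, ma in a:
                if oa != "F":
                    continue
                for cb, sb, ob, mb in b:
                    if ob != "R" or cb != ca or sb < sa:
                        continue
                    frag = sb + L - sa
                    if not (fmin <= frag <= fmax):
                        continue
                    cands.append(
                        Placement(
                            contig_id=index.names[ca],
                            start=sa,
                            end=sb + L,
                            orientation="FR",
                            mismatches=ma + mb,
                            is_concordant=True,
                            mate_spans=((sa, sa + L), (sb, sb + L)),
                        )
                    )
        if not cands:
            continue
        # identical footprints reached via both mate orders collapse to one
        seen = {}
        for p in cands:
            seen.setdefault((p.contig_id, p.start, p.end), p)
        cands = sorted(seen.values(), key=lambda p: (p.mismatches, p.contig_id, p.start))
        placements[name] = _select(cands, config, rng)

    return PairPlacementTable(config.mode, "paired", placements, reads.n)


def map_single(reads: ReadSet, index: KmerIndex, config: MapperConfig) -> PairPlacementTable:
    """Single-end variant (RNA counting, CQ, and subtraction use)."""
    if reads.is_paired:
        reads = reads.to_single()
    if reads.read_length < index.k:
        raise ValueError("read length shorter than index k")
    L = reads.read_length
    hits = _end_to_end_hits(reads.r1, index, config.max_mismatches)
    rng = np.random.default_rng(config.seed)
    placements: dict[str, list[Placement]] = {}
    for i, name in enumerate(reads.names):
        if not hits[i]:
            continue
        cands = [
            Placement(index.names[c], s, s + L, o, m, False, ((s, s + L),))
            for c, s, o, m in hits[i]
        ]
        cands.sort(key=lambda p: (p.mismatches, p.contig_id, p.start))
        placements[name] = _select(cands, config, rng)
    return PairPlacementTable(config.mode, "single", placements, reads.n)


def _select(cands: list[Placement], config: MapperConfig, rng) -> list[Placement]:
    if config.mode == ALL_EXACT:
        return cands
    if config.mode == BEST_ONE:
        best = cands[0].mismatches
        ties = [p for p in cands if p.mismatches == best]
        return [ties[int(rng.integers(len(ties)))]] if len(ties) > 1 else [ties[0]]
    # BEST_K
    kmax = config.max_placements
    if len(cands) <= kmax:
        return cands
    cut_m = cands[kmax - 1].mismatches
    strictly = [p for p in cands if p.mismatches < cut_m]
    tied = [p for p in cands if p.mismatches == cut_m]
    rng.shuffle(tied)
    return strictly + tied[: kmax - len(strictly)]


def best_one_of(table: PairPlacementTable, seed: int = 0) -> PairPlacementTable:
    """Reduce a BEST_K/ALL_EXACT table to BEST_ONE with a seeded tie-break."""
    rng = np.random.default_rng(seed)
    out: dict[str, list[Placement]] = {}
    for name, pls in table.placements.items():
        if not pls:
            continue
        best = min(p.mismatches for p in pls)
        ties = [p for p in pls if p.mismatches == best]
        out[name] = [ties[int(rng.integers(len(ties)))]] if len(ties) > 1 else [ties[0]]
    return PairPlacementTable(BEST_ONE, table.layout, out, table.n_queries)


# ---------------------------------------------------------------------------
# ingestion of external alignments
# ---------------------------------------------------------------------------


def ingest_alignments(path: str | Path, dialect: str) -> PairPlacementTable:
    """Normalise SAM/BAM or PAF alignments into a placement table.

    Coordinates become 0-based half-open (SAM POS p -> start p-1; PAF is
    already 0-based). Secondary records count toward multi-placements;
    supplementary records are dropped. Pairing is by read name held fully in
    memory, so name-sorted input is not required. PAF yields single-end
    placements only.
    """
    dialect = dialect.upper()
    if dialect in ("SAM", "BAM"):
        return _ingest_sam(path, binary=dialect == "BAM")
    if dialect == "PAF":
        return _ingest_paf(path)
    raise ValueError(f"unknown alignment dialect: {dialect!r}")


def _ingest_sam(path: str | Path, binary: bool) -> PairPlacementTable:
    mode = "rb" if binary else "r"
    rec1: dict[str, list] = {}
    rec2: dict[str, list] = {}
    singles: dict[str, list] = {}
    qnames: set[str] = set()
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            qnames.add(rec.query_name)
            if rec.is_unmapped or rec.is_supplementary:
                continue
            entry = (
                rec.reference_name,
                rec.reference_start,
                rec.reference_end
                if rec.reference_end is not None
                else rec.reference_start + (rec.query_length or 0),
                "R" if rec.is_reverse else "F",
                int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
            )
            if not rec.is_paired:
                singles.setdefault(rec.query_name, []).append(entry)
            elif rec.is_read2:
                rec2.setdefault(rec.query_name, []).append(entry)
            else:
                rec1.setdefault(rec.query_name, []).append(entry)

    placements: dict[str, list[Placement]] = {}
    layout = "paired" if (rec1 or rec2) else "single"
    for name, entries in singles.items():
        placements[name] = sorted(
            (Placement(c, s, e, o, nm, False, ((s, e),)) for c, s, e, o, nm in entries),
            key=lambda p: (p.mismatches, p.contig_id, p.start),
        )
    for name in set(rec1) | set(rec2):
        a = rec1.get(name, [])
        b = rec2.get(name, [])
        used_b: set[int] = set()
        pls = []
        for c1, s1, e1, o1, nm1 in a:
            for j, (c2, s2, e2, o2, nm2) in enumerate(b):
                if j in used_b or c2 != c1 or o2 == o1:
                    continue
                used_b.add(j)
                start, end = min(s1, s2), max(e1, e2)
                fwd_first = (o1 == "F" and s1 <= s2) or (o2 == "F" and s2 <= s1)
                pls.append(
                    Placement(
                        c1,
                        start,
                        end,
                        "FR" if fwd_first else "RF",
                        nm1 + nm2,
                        fwd_first,
                        ((s1, e1), (s2, e2)),
                    )
                )
                break
        if pls:
            placements[name] = sorted(pls, key=lambda p: (p.mismatches, p.contig_id, p.start))
    return PairPlacementTable("INGESTED", layout, placements, len(qnames))


def _ingest_paf(path: str | Path) -> PairPlacementTable:
    placements: dict[str, list[Placement]] = {}
    n = 0
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise ValueError(f"malformed PAF at line {lineno}: expected >=12 columns")
            qname, strand, tname = parts[0], parts[4], parts[5]
            tstart, tend = int(parts[7]), int(parts[8])
            matches, alnlen = int(parts[9]), int(parts[10])
            if qname not in seen:
                seen.add(qname)
                n += 1
            placements.setdefault(qname, []).append(
                Placement(
                    tname,
                    tstart,
                    tend,
                    "F" if strand == "+" else "R",
                    alnlen - matches,
                    False,
                    ((tstart, tend),),
                )
            )
    for pls in placements.values():
        pls.sort(key=lambda p: (p.mismatches, p.contig_id, p.start))
    return PairPlacementTable("INGESTED", "single", placements, n)


def write_sam(
    table: PairPlacementTable, contigs: ContigSet, path: str | Path
) -> None:
    """Write a placement table as SAM (round-trip fidelity, not polish)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": contigs.length(n)} for n in contigs.names],
    }
    tid = {n: i for i, n in enumerate(contigs.names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for name, pls in table.placements.items():
            for rank, p in enumerate(pls):
                secondary = 256 if rank > 0 else 0
                if table.layout == "single":
                    rec = pysam.AlignedSegment()
                    rec.query_name = name
                    rec.flag = secondary | (16 if p.orientation == "R" else 0)
                    rec.reference_id = tid[p.contig_id]
                    rec.reference_start = p.start
                    rec.mapping_quality = 60
                    rec.cigarstring = f"{p.end - p.start}M"
                    rec.set_tag("NM", p.mismatches)
                    out.write(rec)
                    continue
                (s1, e1), (s2, e2) = p.mate_spans
                for mate, (s, e), rev in ((1, (s1, e1), False), (2, (s2, e2), True)):
                    rec = pysam.AlignedSegment()
                    rec.query_name = name
                    flag = 1 | 2 | secondary
                    flag |= 64 if mate == 1 else 128
                    flag |= 16 if rev else 32
                    rec.flag = flag
                    rec.reference_id = tid[p.contig_id]
                    rec.reference_start = s
                    rec.next_reference_id = tid[p.contig_id]
                    rec.next_reference_start = s2 if mate == 1 else s1
                    rec.template_length = (p.end - p.start) * (1 if mate == 1 else -1)
                    rec.mapping_quality = 60
                    rec.cigarstring = f"{e - s}M"
                    rec.set_tag("NM", p.mismatches if mate == 1 else 0)
                    out.write(rec)
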