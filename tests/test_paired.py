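"""Paired contigs: doubly-mapped accounting, detection, alignment, walks."""

import numpy as np
import pytest

from haplodiag.mapping import PairPlacementTable, Placement
from haplodiag.paired import (
    PCConfig,
    PairedContig,
    annotate_alignments,
    build_walks,
    detect_pcs,
    doubly_mapped,
    intra_pc_alignment,
    pc_span_fraction,
)
from haplodiag.seqs import ContigSet
from haplodiag.simulate import GenomeSimSpec, ReadSimSpec, simulate_diploid_genome, simulate_reads
from haplodiag.mapping import KmerIndex, MapperConfig, map_pairs


def _pair_table(entries, mode="BEST_K"):
    """entries: list of per-pair contig lists, e.g. [["A","B"], ["A"]]."""
    d = {}
    for i, contigs in enumerate(entries):
        d[f"p{i}"] = [
            Placement(c, 0, 300, "FR", 0, True, ((0, 150), (150, 300)))
            for c in contigs
        ]
    return PairPlacementTable(mode, "paired", d, len(entries))


class TestDoublyMapped:
    def test_cross_contig_pair_counts_once(self):
        dm = doubly_mapped(_pair_table([["A", "B"]]))
        assert dm.pair_counts == {("A", "B"): 1}
        assert dm.fraction_exactly_twice == 1.0

    def test_same_contig_double_is_excluded(self):
        dm = doubly_mapped(_pair_table([["A", "A"]]))
        assert dm.pair_counts == {}
        assert dm.intra_contig_twice == 1
        assert dm.n_exactly_twice == 1

    def test_best_one_table_rejected(self):
        with pytest.raises(ValueError, match="BEST_ONE"):
            doubly_mapped(_pair_table([["A"]], mode="BEST_ONE"))

    def test_counts_are_order_symmetric(self):
        a = doubly_mapped(_pair_table([["A", "B"], ["B", "A"], ["A", "B"]]))
        assert a.pair_counts == {("A", "B"): 3}

    def test_matches_brute_force_enumeration(self, small_world):
        table = small_world["best4"]
        dm = doubly_mapped(table)
        counts = {}
        intra = mapped = twice = 0
        for pls in table.placements.values():
            if not pls:
                continue
            mapped += 1
            if len(pls) != 2:
                continue
            twice += 1
            a, b = sorted(p.contig_id for p in pls)
            if a == b:
                intra += 1
            else:
                counts[(a, b)] = counts.get((a, b), 0) + 1
        assert dm.pair_counts == counts
        assert dm.intra_contig_twice == intra
        assert dm.n_mapped == mapped
        assert dm.n_exactly_twice == twice

    def test_multiplicity_conserves_mapped_pairs(self, small_world):
        dm = doubly_mapped(small_world["best4"])
        assert sum(dm.multiplicity.values()) == dm.n_mapped


class TestDetect:
    def test_threshold_boundary_inclusive(self):
        dm = doubly_mapped(_pair_table([["A", "B"]] * 10_000))
        assert len(detect_pcs(dm, PCConfig())) == 1

    def test_one_below_threshold_excluded(self):
        dm = doubly_mapped(_pair_table([["A", "B"]] * 9_999))
        assert detect_pcs(dm, PCConfig()) == []

    def test_exactly_one_threshold_mode_allowed(self):
        with pytest.raises(ValueError):
            PCConfig(min_shared_pairs=10, density_per_kb=1.0)
        with pytest.raises(ValueError):
            PCConfig(min_shared_pairs=None, density_per_kb=None)

    def test_truth_pairs_recovered_without_false_positives(self, small_world):
        asm = small_world["assembly"]
        dm = doubly_mapped(small_world["best4"])
        pcs = detect_pcs(
            dm,
            PCConfig(min_shared_pairs=None, density_per_kb=4.5),
            asm.contigs.lengths,
        )
        detected = {tuple(sorted((p.contig_a, p.contig_b))) for p in pcs}
        truth = {tuple(sorted(t)) for t in asm.pc_truth}
        assert detected == truth

    def test_fraction_twice_drops_on_collapsed_assembly(self, small_world):
        g = small_world["genome"]
        reads = simulate_reads(g, ReadSimSpec(seed=50, depth_total=8, error_rate=0.0))
        sep_frac = doubly_mapped(
            map_pairs(reads, small_world["index"], MapperConfig.best4(seed=0))
        ).fraction_exactly_twice
        collapsed = ContigSet({"hapA": g.haplotypes[0][0]})
        col_frac = doubly_mapped(
            map_pairs(reads, KmerIndex(collapsed), MapperConfig.best4(seed=0))
        ).fraction_exactly_twice
        assert sep_frac > col_frac + 0.3

    def test_span_fraction(self):
        lengths = {"A": 60, "B": 30, "C": 10}
        pcs = [PairedContig("A", "B", 100)]
        assert pc_span_fraction(pcs, lengths) == pytest.approx(0.9)


class TestIntraPCAlignment:
    def test_identical_contigs_align_fully(self, rng):
        a = rng.integers(0, 4, 20_000, dtype=np.uint8)
        aln = intra_pc_alignment(a, a.copy())
        assert aln.identity > 0.999
        assert aln.aligned_bases > 0.99 * len(a)

    def test_identity_tracks_true_divergence(self, rng):
        a = rng.integers(0, 4, 50_000, dtype=np.uint8)
        b = a.copy()
        pos = rng.choice(len(a), int(0.05 * len(a)), replace=False)
        b[pos] = (b[pos] + rng.integers(1, 4, len(pos), dtype=np.uint8)) % 4
        aln = intra_pc_alignment(a, b)
        assert abs(aln.identity - 0.95) <= 0.01

    def test_reverse_strand_pair_detected(self, rng):
        a = rng.integers(0, 4, 20_000, dtype=np.uint8)
        rc = (3 - a)[::-1].copy()
        aln = intra_pc_alignment(a, rc)
        assert aln.strand == "-"
        assert aln.identity > 0.999

    def test_unrelated_contigs_share_nothing(self, rng):
        a = rng.integers(0, 4, 5_000, dtype=np.uint8)
        b = rng.integers(0, 4, 5_000, dtype=np.uint8)
        aln = intra_pc_alignment(a, b)
        assert aln.aligned_bases <= 100  # chance anchors only

    def test_contig_shorter_than_k_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            intra_pc_alignment(np.zeros(5, dtype=np.uint8), np.zeros(100, dtype=np.uint8))


def _staggered_region(rng, n_contigs=3, step=80_000, clen=120_000, div=0.05):
    """Contigs tiling one region, alternating haplotype copies."""
    span = step * (n_contigs - 1) + clen
    hap1 = rng.integers(0, 4, span, dtype=np.uint8)
    hap2 = hap1.copy()
    pos = rng.choice(span, int(div * span), replace=False)
    hap2[pos] = (hap2[pos] + rng.integers(1, 4, len(pos), dtype=np.uint8)) % 4
    items = {}
    for i in range(n_contigs):
        src = hap1 if i % 2 == 0 else hap2
        items[chr(ord("A") + i)] = src[i * step : i * step + clen]
    return ContigSet(items), span


class TestWalks:
    def test_chain_of_tiling_edges_forms_one_walk(self, rng):
        contigs, span = _staggered_region(rng)
        pcs = [PairedContig("A", "B", 200), PairedContig("B", "C", 150)]
        annotate_alignments(pcs, contigs)
        g = build_walks(pcs, contigs.lengths)
        assert g.walks == [["A", "B", "C"]]
        row = g.walk_stats.iloc[0]
        assert row.n_pcs == 2
        # summed contig span; exceeds the region span by the overlaps
        assert row.span == sum(contigs.lengths.values())
        assert row.span > span

    def test_star_walks_stay_simple(self, rng):
        contigs, _ = _staggered_region(rng, n_contigs=2)
        a, b = contigs["A"], contigs["B"]
        items = {"A": a, "B": b, "C": b.copy(), "D": b.copy()}
        cs = ContigSet(items)
        pcs = [PairedContig("A", "B", 300), PairedContig("A", "C", 200),
               PairedContig("A", "D", 100)]
        annotate_alignments(pcs, cs)
        g = build_walks(pcs, cs.lengths)
        for walk in g.walks:
            assert len(walk) == len(set(walk))
            assert len(walk) <= 3  # at most 2 edges through A
        all_contigs = [c for w in g.walks for c in w]
        assert len(all_contigs) == len(set(all_contigs))

    def test_contained_pairs_form_no_walks(self, rng):
        a = rng.integers(0, 4, 30_000, dtype=np.uint8)
        b = a.copy()
        pos = rng.choice(len(a), 1500, replace=False)
        b[pos] = (b[pos] + rng.integers(1, 4, len(pos), dtype=np.uint8)) % 4
        cs = ContigSet({"A": a, "B": b})
        pcs = [PairedContig("A", "B", 500)]
        annotate_alignments(pcs, cs)
        g = build_walks(pcs, cs.lengths)
        assert g.walks == []
        assert g.graph.edges["A", "B"]["kind"] == "CONTAINED"
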