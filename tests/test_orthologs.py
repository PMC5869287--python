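"""Ortholog-duplication analysis: ingestion, crosstab, Fisher test, triage."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from haplodiag.orthologs import (
    TriageThresholds,
    association_test,
    fisher_exact_2x2,
    ingest_gene_hits,
    instance_crosstab,
    triage_missing_genes,
)
from haplodiag.paired import PCConfig, annotate_alignments, detect_pcs, doubly_mapped
from haplodiag.coverage import classify_contigs, coverage_profiles, depth_arrays, mode_coverage
from haplodiag.mapping import KmerIndex, MapperConfig, best_one_of, map_pairs
from haplodiag.simulate import (
    GenomeSimSpec,
    ReadSimSpec,
    simulate_assembly,
    simulate_diploid_genome,
    simulate_reads,
)


def _hits(rows):
    return pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end", "score"])


CLASSES = {"s1": "SEPARATED", "s2": "SEPARATED", "c1": "COLLAPSED", "o1": "OTHER"}


class TestIngest:
    def test_two_separated_instances(self):
        t = ingest_gene_hits(
            _hits([("g", "s1", 0, 100, 1.0), ("g", "s2", 0, 100, 1.0)]), CLASSES
        )
        row = t.per_gene.iloc[0]
        assert row.instance_count == 2
        assert row.only_separated
        assert not row.only_collapsed

    def test_unknown_contig_is_named(self):
        with pytest.raises(ValueError, match="nope"):
            ingest_gene_hits(_hits([("g", "nope", 0, 1, 1.0)]), CLASSES)

    def test_gff_coordinates_become_half_open(self, tmp_path):
        gff = tmp_path / "x.gff"
        gff.write_text("s1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1\n")
        t = ingest_gene_hits(gff, CLASSES, fmt="gff")
        row = t.instances.iloc[0]
        assert (row.start, row.end) == (100, 200)
        assert row.gene_id == "g1"

    def test_profile_matches_hand_count(self):
        rows = [
            ("g1", "s1", 0, 10, 1.0), ("g1", "c1", 0, 10, 1.0),
            ("g2", "s1", 0, 10, 1.0),
            ("g3", "c1", 0, 10, 1.0), ("g3", "c1", 20, 30, 1.0),
            ("g4", "o1", 0, 10, 1.0),
            ("g5", "s1", 0, 10, 1.0), ("g5", "s2", 0, 10, 1.0), ("g5", "o1", 0, 10, 1.0),
        ]
        t = ingest_gene_hits(_hits(rows), CLASSES)
        pg = t.per_gene.set_index("gene_id")
        assert pg.loc["g1", "n_sep"] == 1 and pg.loc["g1", "n_col"] == 1
        assert bool(pg.loc["g3", "only_collapsed"])
        assert pg.loc["g5", "instance_count"] == 3 and pg.loc["g5", "n_other"] == 1


class TestCrosstab:
    def test_all_single_instance(self):
        rows = [(f"g{i}", "s1", 0, 10, 1.0) for i in range(5)]
        xtab, summary = instance_crosstab(ingest_gene_hits(_hits(rows), CLASSES))
        assert summary["pct_two_instance"] == 0.0
        assert xtab.loc[1, "genes_found"] == 5

    def test_row_sums_conserve_genes_and_instances(self):
        rng = np.random.default_rng(0)
        rows = []
        contigs = list(CLASSES)
        for i in range(60):
            for j in range(int(rng.integers(1, 10))):
                rows.append((f"g{i}", contigs[int(rng.integers(4))], 0, 10, 1.0))
        t = ingest_gene_hits(_hits(rows), CLASSES)
        xtab, _ = instance_crosstab(t)
        body = xtab.drop(index="total")
        assert body["genes_found"].sum() == t.n_genes
        inst_cols = ["instances_separated", "instances_collapsed", "instances_other"]
        assert int(body[inst_cols].to_numpy().sum()) == int(
            t.per_gene["instance_count"].sum()
        )
        assert xtab.loc["total", "genes_found"] == t.n_genes


def _fraction_oracle(table):
    """Two-sided Fisher p by exact rational enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    p = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        q = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        if q <= obs:
            p += q
    return p


class TestFisher:
    def test_balanced_table_is_null(self):
        _, p = fisher_exact_2x2([[10, 10], [10, 10]])
        assert p == 1.0

    def test_matches_rational_oracle_small_margins(self, rng):
        for _ in range(200):
            t = rng.integers(0, 30, size=(2, 2))
            if t.sum(axis=1).min() == 0 or t.sum(axis=0).min() == 0:
                continue
            _, p = fisher_exact_2x2(t)
            oracle = float(_fraction_oracle(t.tolist()))
            assert p == pytest.approx(oracle, rel=1e-12)

    def test_agrees_with_scipy(self, rng):
        for _ in range(50):
            t = rng.integers(1, 80, size=(2, 2))
            _, p = fisher_exact_2x2(t)
            assert p == pytest.approx(scipy_fisher(t)[1], rel=1e-9)

    def test_degenerate_margin_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            _, p = fisher_exact_2x2([[0, 0], [5, 7]])
        assert p == 1.0

    def test_zero_cell_odds_ratio_uses_continuity_correction(self):
        orr, _ = fisher_exact_2x2([[5, 0], [2, 3]])
        assert orr == pytest.approx((5.5 * 3.5) / (0.5 * 2.5))

    def test_association_builds_expected_table(self):
        rows = (
            [(f"a{i}", "s1", 0, 9, 1.0) for i in range(4)]
            + [(f"a{i}", "s2", 0, 9, 1.0) for i in range(4)]  # 4 two-instance, only sep
            + [(f"b{i}", "c1", 0, 9, 1.0) for i in range(3)]  # 3 singles on collapsed
        )
        t = ingest_gene_hits(_hits(rows), CLASSES)
        res = association_test(t)
        assert res.table.tolist() == [[4, 0], [0, 3]]
        assert 0 < res.p_value <= 1


class TestTriage:
    def _world(self):
        """Hand-built evidence: one PC (H, P), genes in controlled spots."""
        depth = {"H": np.full(100_000, 18.0), "P": np.full(100_000, 18.0)}
        depth["H"][40_000:42_000] = 40.0  # elevated locus
        modes = {"H": 18, "P": 18}

        class FakeAln:
            # footprint on H: [5_000, 95_000); P fully aligned
            ext_a = (5_000, 5_000)
            ext_b = (0, 0)

        pcs = [type("PC", (), {"contig_a": "H", "contig_b": "P"})()]
        alignments = {("H", "P"): FakeAln()}
        return depth, modes, pcs, alignments

    def _table(self, gene_rows):
        classes = {"H": "SEPARATED", "P": "SEPARATED"}
        return ingest_gene_hits(_hits(gene_rows), classes)

    def test_elevated_coverage_flagged(self):
        depth, modes, pcs, aln = self._world()
        t = self._table([("g", "H", 40_000, 42_000, 1.0)])
        out = triage_missing_genes(t, pcs, depth, modes, aln)
        assert out.iloc[0].category == "COVERAGE_ELEVATED"
        assert out.iloc[0].depth_ratio == pytest.approx(40 / 18)

    def test_locus_outside_footprint_near_end(self):
        depth, modes, pcs, aln = self._world()
        t = self._table([("g", "H", 1_000, 3_000, 1.0)])
        out = triage_missing_genes(t, pcs, depth, modes, aln)
        assert out.iloc[0].category == "CONTIG_END"

    def test_partner_partial_hit_is_fragmentary(self):
        depth, modes, pcs, aln = self._world()
        t = self._table([("g", "H", 60_000, 62_000, 1.0)])
        partial = _hits([("g", "P", 60_000, 60_600, 1.0)])
        out = triage_missing_genes(t, pcs, depth, modes, aln, partial_hits=partial)
        assert out.iloc[0].category == "FRAGMENTARY"
        assert out.iloc[0].partner_partial_fraction == pytest.approx(0.3)

    def test_default_is_clean_loss(self):
        depth, modes, pcs, aln = self._world()
        t = self._table([("g", "H", 60_000, 62_000, 1.0)])
        out = triage_missing_genes(t, pcs, depth, modes, aln)
        assert out.iloc[0].category == "CLEAN_LOSS"

    def test_synthetic_losses_recovered_as_losses(self):
        gspec = GenomeSimSpec(seed=41, chrom_length=150_000, gene_count=40,
                              gene_loss_rate=0.3, gene_length=2_000)
        genome = simulate_diploid_genome(gspec)
        asm = simulate_assembly(genome)
        reads = simulate_reads(genome, ReadSimSpec(seed=42, depth_total=36,
                                                   error_rate=0.005))
        best4 = map_pairs(reads, KmerIndex(asm.contigs, 13), MapperConfig.best4(seed=2))
        b1 = best_one_of(best4, 3)
        profiles = coverage_profiles(b1, asm.contigs)
        class_df, _, _ = classify_contigs(profiles)
        depth = depth_arrays(b1, asm.contigs)
        modes = {p.contig_id: mode_coverage(p) for p in profiles.values()}
        dm = doubly_mapped(best4)
        cfg = PCConfig(min_shared_pairs=None, density_per_kb=4.5)
        pcs = detect_pcs(dm, cfg, asm.contigs.lengths)
        annotate_alignments(pcs, asm.contigs, cfg)
        alignments = {(p.contig_a, p.contig_b): p.alignment for p in pcs}
        table = ingest_gene_hits(
            asm.gene_hits(genome), dict(zip(class_df["contig"], class_df["class"]))
        )
        out = triage_missing_genes(table, pcs, depth, modes, alignments)
        gt = genome.gene_truth
        lost_once = set(
            gt.loc[gt.hap_a_present != gt.hap_b_present, "gene_id"]
        )
        candidates = out[out.gene_id.isin(lost_once)]
        assert len(candidates) >= 0.5 * len(lost_once)  # most losses become candidates
        loss_like = candidates.category.isin(["CLEAN_LOSS", "FRAGMENTARY"])
        assert loss_like.mean() >= 0.9
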