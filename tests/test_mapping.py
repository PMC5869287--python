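"""Mapper: index correctness, placement oracles, ingestion round-trips."""

import numpy as np
import pytest

from haplodiag.mapping import (
    KmerIndex,
    MapperConfig,
    map_pairs,
    map_single,
    ingest_alignments,
    write_sam,
)
from haplodiag.seqs import ContigSet, ReadSet, decode, encode, revcomp
from haplodiag.simulate import GenomeSimSpec, ReadSimSpec, simulate_diploid_genome, simulate_reads


class TestIndex:
    def test_kmer_count_of_short_contig(self):
        idx = KmerIndex(ContigSet({"c": "ACGTACGT"}), k=4)
        assert idx.n_kmers() == 5

    def test_lookup_returns_true_origin(self, rng):
        seq = decode(rng.integers(0, 4, 5000, dtype=np.uint8))
        idx = KmerIndex(ContigSet({"c": seq}), k=13)
        for _ in range(20):
            pos = int(rng.integers(0, 5000 - 13))
            hits = idx.lookup(seq[pos : pos + 13])
            assert ("c", pos) in hits

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ContigSet([("a", "ACGT"), ("a", "ACGT")])

    def test_masked_bases_never_indexed(self):
        codes = encode("ACGTACGTACGTACGT")
        codes[4:8] = 255
        idx = KmerIndex(ContigSet({"c": codes}), k=4)
        # valid windows: starts 0 and 8..12
        assert idx.n_kmers() == 6


class TestMapSingle:
    def test_reverse_complement_read_found_on_opposite_strand(self, rng):
        seq = decode(rng.integers(0, 4, 2000, dtype=np.uint8))
        idx = KmerIndex(ContigSet({"c": seq}))
        read = revcomp(seq[500:650])
        table = map_single(ReadSet(["r"], encode(read)), idx, MapperConfig.all_exact())
        [p] = table.placements["r"]
        assert (p.start, p.end, p.orientation) == (500, 650, "R")

    def test_all_exact_equals_brute_force(self, rng):
        # a reference with planted duplications, queried with sampled reads
        base = rng.integers(0, 4, 30_000, dtype=np.uint8)
        seq = np.concatenate([base, base[5_000:8_000]])  # duplicated block
        contigs = ContigSet({"c1": seq[:20_000], "c2": seq[20_000:]})
        idx = KmerIndex(contigs)
        s1, s2 = contigs.sequence("c1"), contigs.sequence("c2")
        reads = []
        for _ in range(60):
            src = s1 if rng.random() < 0.5 else s2
            pos = int(rng.integers(0, len(src) - 150))
            r = src[pos : pos + 150]
            reads.append(r if rng.random() < 0.5 else revcomp(r))
        rs = ReadSet([f"r{i}" for i in range(len(reads))], np.vstack([encode(r) for r in reads]))
        table = map_single(rs, idx, MapperConfig.all_exact())

        def brute(read):
            out = set()
            for name, ref in (("c1", s1), ("c2", s2)):
                for q, orient in ((read, "F"), (revcomp(read), "R")):
                    start = ref.find(q)
                    while start != -1:
                        out.add((name, start, orient))
                        start = ref.find(q, start + 1)
            return out

        for i, r in enumerate(reads):
            got = {
                (p.contig_id, p.start, p.orientation)
                for p in table.placements.get(f"r{i}", [])
            }
            assert got == brute(r)


class TestMapPairs:
    def test_best_one_recovers_truth_origin(self):
        g = simulate_diploid_genome(
            GenomeSimSpec(seed=20, chrom_length=50_000, heterozygosity_target=0.0,
                          gene_count=0)
        )
        reads = simulate_reads(g, ReadSimSpec(seed=21, depth_total=4, error_rate=0.0))
        ref = ContigSet({"chr1": g.haplotypes[0][0]})
        table = map_pairs(reads, KmerIndex(ref), MapperConfig.best_one(seed=0))
        checked = 0
        for name, pls in table.placements.items():
            _, chrom, hap, start, flen = name.split("|")
            [p] = pls
            assert p.start == int(start)
            assert p.end == int(start) + int(flen)
            checked += 1
        assert checked > 0.99 * reads.n

    def test_two_copy_locus_yields_exactly_two_placements(self, rng):
        block = decode(rng.integers(0, 4, 3000, dtype=np.uint8))
        pad1 = decode(rng.integers(0, 4, 2000, dtype=np.uint8))
        pad2 = decode(rng.integers(0, 4, 2000, dtype=np.uint8))
        contigs = ContigSet({"x": pad1 + block, "y": block + pad2})
        idx = KmerIndex(contigs)
        frag = block[1000:1350]
        r1, r2 = frag[:150], revcomp(frag)[:150]
        rs = ReadSet(["p"], encode(r1), encode(r2))
        table = map_pairs(rs, idx, MapperConfig.best4(seed=0))
        pls = table.placements["p"]
        assert len(pls) == 2
        assert {p.contig_id for p in pls} == {"x", "y"}

    def test_foreign_pair_is_unmapped(self, rng):
        contigs = ContigSet({"c": decode(rng.integers(0, 4, 10_000, dtype=np.uint8))})
        idx = KmerIndex(contigs)
        rs = ReadSet(
            ["p"],
            rng.integers(0, 4, (1, 150), dtype=np.uint8),
            rng.integers(0, 4, (1, 150), dtype=np.uint8),
        )
        table = map_pairs(rs, idx, MapperConfig.best4(seed=0))
        assert "p" not in table.placements
        assert table.n_queries == 1

    def test_mapped_fraction_of_error_free_reads(self, small_world):
        g = small_world["genome"]
        reads = simulate_reads(g, ReadSimSpec(seed=99, depth_total=4, error_rate=0.0))
        ref = ContigSet({"hapA": g.haplotypes[0][0], "hapB": g.haplotypes[0][1]})
        table = map_pairs(reads, KmerIndex(ref), MapperConfig.best_one(seed=0))
        assert table.mapped_fraction >= 0.99

    def test_tie_break_is_seed_deterministic(self, rng):
        block = decode(rng.integers(0, 4, 2000, dtype=np.uint8))
        contigs = ContigSet({"x": block, "y": block})  # perfect two-way tie
        idx = KmerIndex(contigs)
        frag = block[200:550]
        rs = ReadSet(
            [f"p{i}" for i in range(30)],
            np.vstack([encode(frag[:150])] * 30),
            np.vstack([encode(revcomp(frag)[:150])] * 30),
        )
        picks = []
        for _ in range(2):
            t = map_pairs(rs, idx, MapperConfig.best_one(seed=7))
            picks.append([t.placements[f"p{i}"][0].contig_id for i in range(30)])
        assert picks[0] == picks[1]
        assert set(picks[0]) == {"x", "y"}  # the tie is actually exercised


class TestIngestion:
    def test_sam_round_trip(self, small_world, tmp_path):
        table = small_world["best4"]
        contigs = small_world["assembly"].contigs
        sub = {k: table.placements[k] for k in list(table.placements)[:200]}
        import dataclasses

        small = dataclasses.replace(table, placements=sub, n_queries=len(sub))
        path = tmp_path / "out.sam"
        write_sam(small, contigs, path)
        back = ingest_alignments(path, "SAM")
        assert set(back.placements) == set(sub)
        for name, pls in sub.items():
            got = back.placements[name]
            assert len(got) == len(pls)
            assert {(p.contig_id, p.start, p.end) for p in got} == {
                (p.contig_id, p.start, p.end) for p in pls
            }

    def test_paf_coordinates_stay_zero_based(self, tmp_path):
        path = tmp_path / "a.paf"
        path.write_text(
            "q1\t150\t0\t150\t+\tctg\t5000\t42\t192\t150\t150\t60\n"
        )
        table = ingest_alignments(path, "PAF")
        [p] = table.placements["q1"]
        assert (p.start, p.end, p.orientation, p.mismatches) == (42, 192, "F", 0)

    def test_secondary_counted_supplementary_dropped(self, tmp_path):
        sam = (
            "@HD\tVN:1.6\n@SQ\tSN:ctg\tLN:10000\n"
            "r1\t0\tctg\t101\t60\t150M\t*\t0\t0\t*\t*\tNM:i:0\n"
            "r1\t256\tctg\t501\t0\t150M\t*\t0\t0\t*\t*\tNM:i:2\n"
            "r1\t2048\tctg\t901\t60\t75M\t*\t0\t0\t*\t*\tNM:i:0\n"
        )
        path = tmp_path / "b.sam"
        path.write_text(sam)
        table = ingest_alignments(path, "SAM")
        pls = table.placements["r1"]
        assert len(pls) == 2  # primary + secondary; supplementary gone
        assert {p.start for p in pls} == {100, 500}  # SAM POS is 1-based

    def test_unknown_dialect_raises(self, tmp_path):
        path = tmp_path / "c.txt"
        path.write_text("")
        with pytest.raises(ValueError, match="dialect"):
            ingest_alignments(path, "CRAM2")
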