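import numpy as np
import pytest

from tecis.intervals import (
    GeneModel,
    GenomicInterval,
    PeakSet,
    TermMap,
    associate_regions_to_genes,
    count_intersections,
    merge_resize,
    parse_bed,
    parse_repeatmasker,
    regulatory_domains,
    term_enrichment,
    total_overlap_bp,
    write_bed,
    write_repeatmasker,
)
from tecis.intervals import TEFragment


def _iv(chrom, s, e, strand="."):
    return GenomicInterval(chrom, s, e, strand)


class TestGenomicInterval:
    def test_rejects_inverted_coordinates(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 600, 100)

    def test_rejects_empty_chrom(self):
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)


class TestBedIO:
    def test_three_column_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t600\n")
        ps = parse_bed(p)
        assert len(ps) == 1
        assert ps.intervals[0] == _iv("chr1", 100, 600)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("")
        assert len(parse_bed(p)) == 0

    def test_coordinate_order_error_names_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t1\t2\nchr1\t600\t100\n")
        with pytest.raises(ValueError, match="line 2"):
            parse_bed(p)

    def test_roundtrip_byte_identical(self, tmp_path):
        text = "chr1\t100\t600\tpk1\nchr2\t0\t50\tpk2\n"
        p = tmp_path / "a.bed"
        p.write_text(text)
        ps = parse_bed(p)
        q = tmp_path / "b.bed"
        write_bed(ps, q)
        assert q.read_text() == text


class TestRepeatMaskerIO:
    ROW = ("1000 1.0 0.0 0.0 chr1 1001 1100 (0) + MER130 DNA/hAT "
           "201 300 (0) 1\n")

    def test_coordinate_shift(self, tmp_path):
        p = tmp_path / "te.out"
        p.write_text(self.ROW)
        frs = parse_repeatmasker(p)
        assert len(frs) == 1
        fr = frs[0]
        assert (fr.interval.start, fr.interval.end) == (1000, 1100)
        assert fr.interval.strand == "+"
        assert fr.consensus_span == (201, 300)

    def test_c_strand_maps_to_minus(self, tmp_path):
        p = tmp_path / "te.out"
        p.write_text("1000 1.0 0.0 0.0 chr1 1001 1100 (0) C MER130 DNA "
                     "(0) 300 201 1\n")
        fr = parse_repeatmasker(p)[0]
        assert fr.interval.strand == "-"
        assert fr.consensus_span == (201, 300)

    def test_simple_repeat_excluded(self, tmp_path):
        p = tmp_path / "te.out"
        p.write_text(self.ROW +
                     "10 1.0 0.0 0.0 chr1 2001 2050 (0) + (CA)n "
                     "Simple_repeat 1 50 (0) 2\n"
                     "10 1.0 0.0 0.0 chr1 3001 3050 (0) + SATMIN "
                     "Satellite 1 50 (0) 3\n")
        frs = parse_repeatmasker(p)
        assert [f.subfamily for f in frs] == ["MER130"]

    def test_unknown_strand_errors(self, tmp_path):
        p = tmp_path / "te.out"
        p.write_text("10 1.0 0.0 0.0 chr1 1001 1100 (0) ? X DNA 1 100 (0) 1\n")
        with pytest.raises(ValueError, match="strand"):
            parse_repeatmasker(p)

    def test_writer_roundtrip(self, tmp_path):
        frags = [TEFragment(_iv("chr1", 1000, 1100, "+"), "MER130", "DNA",
                            (201, 300), "f0"),
                 TEFragment(_iv("chr2", 5, 55, "-"), "B2_Mm1", "SINE",
                            (10, 59), "f1")]
        p = tmp_path / "te.out"
        write_repeatmasker(frags, p)
        back = parse_repeatmasker(p)
        assert [(f.interval, f.subfamily, f.consensus_span) for f in back] == \
            [(f.interval, f.subfamily, f.consensus_span) for f in frags]


class TestOverlap:
    def test_partial_overlap(self):
        assert total_overlap_bp([_iv("chr1", 100, 200)],
                                [_iv("chr1", 150, 250)]) == 50

    def test_disjoint(self):
        assert total_overlap_bp([_iv("chr1", 0, 10)],
                                [_iv("chr1", 20, 30)]) == 0

    def test_self_overlap_counts_union(self):
        a = [_iv("chr1", 0, 100), _iv("chr1", 200, 300)]
        assert total_overlap_bp(a, a) == 200

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            def rand_set():
                out = []
                for _ in range(rng.integers(1, 8)):
                    s = int(rng.integers(0, 9_900))
                    out.append(_iv("chr1", s, s + int(rng.integers(1, 120))))
                return out
            a, b = rand_set(), rand_set()
            cover_a = np.zeros(10_100, dtype=bool)
            cover_b = np.zeros(10_100, dtype=bool)
            for iv in a:
                cover_a[iv.start:iv.end] = True
            for iv in b:
                cover_b[iv.start:iv.end] = True
            assert total_overlap_bp(a, b) == int((cover_a & cover_b).sum())
            assert total_overlap_bp(a, b) == total_overlap_bp(b, a)

    def test_count_intersections_pairs(self):
        peaks = PeakSet([_iv("chr1", 0, 100), _iv("chr1", 200, 300)])
        frags = [
            TEFragment(_iv("chr1", 50, 250), "A", "DNA", (1, 200)),
            TEFragment(_iv("chr1", 90, 95), "A", "DNA", (1, 5)),
            TEFragment(_iv("chr1", 500, 600), "A", "DNA", (1, 100)),
        ]
        # fragment 1 overlaps both peaks (2 pairs), fragment 2 one, 3 none
        assert count_intersections(peaks, frags) == 3


class TestMergeResize:
    SIZES = {"chr1": 10_000}

    def test_center_and_width(self):
        ps = PeakSet([_iv("chr1", 1000, 1200)], chrom_sizes=self.SIZES)
        out = merge_resize(ps, width=500)
        assert (out.intervals[0].start, out.intervals[0].end) == (850, 1350)

    def test_clipped_at_chromosome_start(self):
        ps = PeakSet([_iv("chr1", 0, 100)], chrom_sizes=self.SIZES)
        out = merge_resize(ps, width=500)
        assert (out.intervals[0].start, out.intervals[0].end) == (0, 300)

    def test_overlapping_inputs_merged_first(self):
        ps = PeakSet([_iv("chr1", 100, 300), _iv("chr1", 250, 500)],
                     chrom_sizes=self.SIZES)
        out = merge_resize(ps, width=500)
        assert len(out) == 1
        # merged span [100,500), midpoint 300
        assert (out.intervals[0].start, out.intervals[0].end) == (50, 550)

    def test_output_widths(self):
        rng = np.random.default_rng(5)
        ivs = [_iv("chr1", int(s), int(s) + int(rng.integers(10, 400)))
               for s in rng.integers(0, 9_000, size=12)]
        out = merge_resize(PeakSet(ivs, chrom_sizes=self.SIZES), width=500)
        for iv in out:
            clipped = iv.start == 0 or iv.end == self.SIZES["chr1"]
            assert len(iv) == 500 or clipped
        # outputs originate from merged inputs, hence cannot overlap pairwise
        ordered = sorted(out.intervals, key=lambda x: x.start)
        centers = [(iv.start + iv.end) // 2 for iv in ordered]
        assert centers == sorted(centers)


class TestGeneAssociation:
    def test_extension_reaches_distant_region(self):
        genes = [GeneModel("g1", "chr1", 100_000, "+")]
        regions = PeakSet([_iv("chr1", 200_000, 200_500)], ids=["r1"])
        assoc = associate_regions_to_genes(regions, genes)
        assert assoc["r1"] == {"g1"}
        dom = regulatory_domains(genes)["g1"]
        assert dom == ("chr1", 0, 1_101_000)

    def test_region_in_basal_domain(self):
        genes = [GeneModel("g1", "chr1", 100_000, "+")]
        regions = PeakSet([_iv("chr1", 99_000, 99_100)], ids=["r1"])
        assert associate_regions_to_genes(regions, genes)["r1"] == {"g1"}

    def test_two_gene_extension_stops_at_neighbor_basal(self):
        genes = [GeneModel("g1", "chr1", 100_000, "+"),
                 GeneModel("g2", "chr1", 400_000, "+")]
        regions = PeakSet([_iv("chr1", 200_000, 200_100)], ids=["r1"])
        doms = regulatory_domains(genes)
        # g1 extends downstream to g2's basal start (395000); g2 extends
        # upstream to g1's basal end (101000): the region lies in both.
        assert doms["g1"][2] == 395_000
        assert doms["g2"][1] == 101_000
        assert associate_regions_to_genes(regions, genes)["r1"] == {"g1", "g2"}

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(23)
        glen = 100_000
        for _ in range(10):
            n_genes = int(rng.integers(1, 6))
            genes = [GeneModel(f"g{i}", "chr1",
                               int(rng.integers(6_000, glen - 6_000)),
                               "+" if rng.random() < 0.5 else "-")
                     for i in range(n_genes)]
            doms = regulatory_domains(genes, {"chr1": glen},
                                      max_ext=20_000)
            owner = {}
            for gid, (_c, s, e) in doms.items():
                for b in range(max(0, s), min(glen, e)):
                    owner.setdefault(b, set()).add(gid)
            s = int(rng.integers(0, glen - 200))
            region = PeakSet([_iv("chr1", s, s + 200)], ids=["r"],
                             chrom_sizes={"chr1": glen})
            got = associate_regions_to_genes(region, genes, max_ext=20_000)["r"]
            expected = set()
            for b in range(s, s + 200):
                expected |= owner.get(b, set())
            assert got == expected


class TestTermEnrichment:
    def test_exact_term_has_minimal_p(self):
        bg = {f"g{i}" for i in range(200)}
        terms = TermMap({"T1": {"g0", "g1", "g2"},
                         "T2": {f"g{i}" for i in range(50, 100)}}, bg)
        out = term_enrichment({"g0", "g1", "g2"}, terms)
        assert out.iloc[0]["term"] == "T1"
        assert out.iloc[0]["p"] < 1e-5

    def test_zero_overlap_p_one(self):
        bg = {f"g{i}" for i in range(20)}
        terms = TermMap({"T": {"g10", "g11"}}, bg)
        out = term_enrichment({"g0"}, terms)
        assert out["p"].iloc[0] == 1.0

    def test_query_equals_background(self):
        bg = {"a", "b", "c"}
        out = term_enrichment(bg, TermMap({"T": {"a"}}, bg))
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_empty_query_errors(self):
        with pytest.raises(ValueError):
            term_enrichment(set(), TermMap({"T": {"a"}}, {"a"}))

    def test_bh_q_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        bg = {f"g{i}" for i in range(100)}
        terms = {f"T{j}": set(rng.choice(sorted(bg), size=10, replace=False))
                 for j in range(8)}
        out = term_enrichment({f"g{i}" for i in range(30)},
                              TermMap(terms, bg))
        q = out["q"].to_numpy()
        assert (np.diff(q) >= -1e-12).all()
        assert (q <= 1.0 + 1e-12).all()
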