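import math

import numpy as np
import pytest

from tecis.accessibility import BackgroundPeakSets, BinaryAccessibilityMatrix
from tecis.enrichment import (
    ContingencyTable,
    background_corrected_es_z,
    contingency_fisher,
    detect_te_derived_accessible_motifs,
    enrichment_score_motif,
    enrichment_score_peak,
    enrichment_table_motif,
    enrichment_table_peak,
    per_cell_te_fraction,
    te_class_composition,
    transplant_hits,
)
from tecis.intervals import GenomicInterval, PeakSet, TEFragment
from tecis.motifs import MotifHit


def _iv(chrom, s, e, strand="."):
    return GenomicInterval(chrom, s, e, strand)


def _frag(chrom, s, e, sub="MER130", cls="DNA", fid=""):
    return TEFragment(_iv(chrom, s, e, "+"), sub, cls, (1, e - s), fid)


class TestESPeak:
    def test_hand_computation(self):
        # overlap 100 of 1000 peak bp; subfamily 1000 bp of 100000 genome
        peaks = PeakSet([_iv("chr1", 0, 1000)])
        frags = [_frag("chr1", 900, 1400),  # 100 bp overlap
                 _frag("chr1", 5000, 5250),
                 _frag("chr1", 6000, 6250)]
        # three intersections needed: add touching fragments
        peaks = PeakSet([_iv("chr1", 0, 1000), _iv("chr1", 5000, 5001),
                         _iv("chr1", 6000, 6001)])
        # recompute by hand: overlap = 100 + 1 + 1 = 102 of 1002 peak bp
        es = enrichment_score_peak(peaks, frags, genome_len=100_000)
        expected = math.log2((102 / 1002) / (1000 / 100_000))
        assert es == pytest.approx(expected)

    def test_ratio_one_gives_zero(self):
        # overlap fraction equals genomic fraction
        peaks = PeakSet([_iv("chr1", 0, 1000)])
        frags = [_frag("chr1", 0, 10, fid="a"), _frag("chr1", 20, 30, fid="b"),
                 _frag("chr1", 40, 70, fid="c"),
                 _frag("chr1", 5000, 9950, fid="d")]
        # subfamily bp = 5000, genome 100000 -> fraction 0.05
        # overlap = 50 of 1000 -> 0.05
        es = enrichment_score_peak(peaks, frags, genome_len=100_000)
        assert es == pytest.approx(0.0)

    def test_intersection_filter_excludes(self):
        peaks = PeakSet([_iv("chr1", 0, 1000)])
        frags = [_frag("chr1", 500, 600), _frag("chr1", 700, 800)]
        assert enrichment_score_peak(peaks, frags, 100_000) is None

    def test_invariant_to_fragment_split(self):
        peaks = PeakSet([_iv("chr1", 0, 1000), _iv("chr1", 2000, 2500),
                         _iv("chr1", 4000, 4600)])
        whole = [_frag("chr1", 500, 700, fid="w"),
                 _frag("chr1", 2100, 2200, fid="x"),
                 _frag("chr1", 4100, 4200, fid="y")]
        split = [_frag("chr1", 500, 600, fid="w1"),
                 _frag("chr1", 600, 700, fid="w2"),
                 _frag("chr1", 2100, 2200, fid="x"),
                 _frag("chr1", 4100, 4200, fid="y")]
        assert enrichment_score_peak(peaks, whole, 50_000) == pytest.approx(
            enrichment_score_peak(peaks, split, 50_000))

    def test_matches_per_base_brute_force(self):
        rng = np.random.default_rng(17)
        glen = 20_000
        checked = 0
        for _ in range(10):
            peaks = []
            for _ in range(8):
                s = int(rng.integers(0, glen - 400))
                peaks.append(_iv("chr1", s, s + int(rng.integers(50, 400))))
            frags = []
            for i in range(10):
                s = int(rng.integers(0, glen - 300))
                frags.append(_frag("chr1", s, s + int(rng.integers(30, 300)),
                                   fid=f"f{i}"))
            peak_cov = np.zeros(glen, dtype=bool)
            for iv in peaks:
                peak_cov[iv.start:iv.end] = True
            frag_cov = np.zeros(glen, dtype=bool)
            sub_bp = 0
            for fr in frags:
                frag_cov[fr.interval.start:fr.interval.end] = True
                sub_bp += len(fr.interval)
            overlap = int((peak_cov & frag_cov).sum())
            if overlap == 0:
                continue
            es = enrichment_score_peak(PeakSet(peaks), frags, glen,
                                       min_intersections=0)
            expected = math.log2((overlap / peak_cov.sum()) / (sub_bp / glen))
            assert es == pytest.approx(expected)
            checked += 1
        assert checked >= 5


def _hits_for(peaks, positions, motif="m1"):
    """positions: peak_id -> list of (start, end) 1-based within the peak."""
    return {pid: [MotifHit(pid, s, e, "+", 10.0, 1e-5, motif)
                  for s, e in positions.get(pid, [])]
            for pid in (peaks.ids or [])}


class TestESMotif:
    def _setup(self):
        # 50 peaks of 100 bp; 5 carry the motif inside a fragment
        peaks = PeakSet([_iv("chr1", i * 200, i * 200 + 100)
                         for i in range(50)],
                        ids=[f"p{i}" for i in range(50)])
        positions = {f"p{i}": [(21, 27)] for i in range(10)}  # 10 motif peaks
        frags = [_frag("chr1", i * 200, i * 200 + 50, fid=f"f{i}")
                 for i in range(5)]  # motif (offset 20-27 0-based) inside
        return peaks, _hits_for(peaks, positions), frags

    def test_hand_computation(self):
        peaks, hits, frags = self._setup()
        es = enrichment_score_motif(peaks, hits, frags, genome_len=100_000)
        # 5 of 10 motif peaks qualify; subfamily 250 bp of 100000
        assert es == pytest.approx(math.log2((5 / 10) / (250 / 100_000)))

    def test_partial_containment_disqualifies(self):
        peaks = PeakSet([_iv("chr1", 0, 100)], ids=["p0"])
        hits = _hits_for(peaks, {"p0": [(45, 51)]})
        frags = [_frag("chr1", 0, 50, fid="f")]  # hit covers 44..51 0-based
        es = enrichment_score_motif(peaks, hits, frags, 100_000,
                                    min_intersections=0)
        assert es is None  # overlaps 6 of 7 bases -> no qualifying peak

    def test_qualifying_fraction_equal_genomic_fraction(self):
        peaks = PeakSet([_iv("chr1", i * 200, i * 200 + 100)
                         for i in range(10)],
                        ids=[f"p{i}" for i in range(10)])
        hits = _hits_for(peaks, {f"p{i}": [(11, 17)] for i in range(10)})
        # 5 of 10 qualify; subfamily bp = 50000 of 100000
        frags = [_frag("chr1", i * 200, i * 200 + 30, fid=f"f{i}")
                 for i in range(5)]
        frags.append(_frag("chr1", 50_000, 50_000 + 50_000 - 150, fid="big"))
        es = enrichment_score_motif(peaks, hits, frags, 100_000)
        assert es == pytest.approx(0.0)

    def test_no_motif_peaks_errors(self):
        peaks = PeakSet([_iv("chr1", 0, 100)], ids=["p0"])
        with pytest.raises(ValueError):
            enrichment_score_motif(peaks, {"p0": []}, [], 1000)


class TestContingency:
    def test_enhancer_table_significant(self):
        oratio, p = contingency_fisher(ContingencyTable(7449, 3118,
                                                        12201, 21402))
        assert p < 0.01
        assert oratio == pytest.approx(4.19, abs=0.01)

    def test_balanced_table(self):
        _, p = contingency_fisher(ContingencyTable(1, 1, 1, 1))
        assert p == pytest.approx(1.0)

    def test_subfamily_vs_all_tes(self):
        _, p = contingency_fisher(ContingencyTable(22, 68, 4821, 3_579_641))
        assert p < 0.01


class TestSignificanceTables:
    def test_single_subfamily_q_equals_p(self):
        peaks = PeakSet([_iv("chr1", 0, 1000)])
        frags = [_frag("chr1", 100, 200, fid="a"),
                 _frag("chr1", 300, 400, fid="b"),
                 _frag("chr1", 500, 600, fid="c")]
        tbl = enrichment_table_peak(peaks, frags, 100_000)
        assert len(tbl) == 1
        assert tbl["q"].iloc[0] == pytest.approx(tbl["fisher_p"].iloc[0])

    def test_planted_subfamily_smallest_q(self, planted_dataset):
        ds = planted_dataset
        tbl = enrichment_table_peak(ds.chip_peaks["Neurod2"], ds.te_fragments,
                                    ds.genome_len)
        assert tbl.iloc[0]["subfamily"] == "MER130"
        assert tbl.iloc[0]["q"] == tbl["q"].min()


class TestBackgroundZ:
    def test_identity_background_undefined(self):
        peaks = PeakSet([_iv("chr1", i * 200, i * 200 + 100)
                         for i in range(10)],
                        ids=[f"p{i}" for i in range(10)])
        hits = _hits_for(peaks, {f"p{i}": [(11, 17)] for i in range(5)})
        frags = [_frag("chr1", i * 200, i * 200 + 50, fid=f"f{i}")
                 for i in range(5)]
        bg = BackgroundPeakSets(np.tile(np.arange(10)[:, None], (1, 6)), 6)
        es = enrichment_score_motif(peaks, hits, frags, 100_000)
        z = background_corrected_es_z(es, peaks, hits, frags, 100_000, bg)
        assert math.isnan(z)

    def test_transplant_preserves_relative_offset(self):
        peaks = PeakSet([_iv("chr1", 0, 100), _iv("chr1", 500, 600)],
                        ids=["p0", "p1"])
        hits = _hits_for(peaks, {"p0": [(21, 27)]})
        bg = BackgroundPeakSets(np.array([[1], [0]]), 1)
        moved = transplant_hits(peaks, hits, bg, 0)
        assert moved["p0"] == []
        assert len(moved["p1"]) == 1
        assert (moved["p1"][0].start, moved["p1"][0].end) == (21, 27)


class TestDetectTEDerived:
    def test_containment_rules(self):
        peaks = PeakSet([_iv("chr1", 0, 100), _iv("chr1", 200, 300)],
                        ids=["p0", "p1"])
        hits = {
            "p0": [MotifHit("p0", 21, 27, "+", 1.0, 1e-5, "m1")],  # in TE
            "p1": [MotifHit("p1", 21, 27, "+", 1.0, 1e-5, "m1")],  # not in TE
        }
        frags = [_frag("chr1", 0, 50, fid="f0"),
                 _frag("chr1", 400, 450, fid="f1")]
        tbl, records = detect_te_derived_accessible_motifs(peaks, hits, frags)
        assert len(records) == 1
        assert records[0][2] == "MER130"
        assert tbl.iloc[0]["n_hits"] == 1

    def test_hit_spanning_two_fragments_not_counted(self):
        peaks = PeakSet([_iv("chr1", 0, 100)], ids=["p0"])
        hits = {"p0": [MotifHit("p0", 48, 54, "+", 1.0, 1e-5, "m1")]}
        frags = [_frag("chr1", 0, 50, fid="a"), _frag("chr1", 50, 100, fid="b")]
        _, records = detect_te_derived_accessible_motifs(peaks, hits, frags)
        assert records == []


class TestClassComposition:
    def test_chip_mode_percent(self):
        peaks = PeakSet([_iv("chr1", 0, 1_236_918)])
        frags = [_frag("chr1", 0, 63_777, cls="DNA")]
        comp = te_class_composition(peaks, frags, mode="chip")
        assert comp.attrs["te_percent"] == 5.2

    def test_atac_mode_counts(self):
        peaks = PeakSet([_iv("chr1", 0, 100), _iv("chr1", 200, 300),
                         _iv("chr1", 400, 500)])
        frags = [_frag("chr1", 50, 60, cls="DNA"),
                 _frag("chr1", 250, 260, cls="SINE/B2")]
        comp = te_class_composition(peaks, frags, mode="atac")
        assert comp.attrs["te_numerator"] == 2
        assert comp.attrs["te_denominator"] == 3

    def test_no_te_overlap(self):
        peaks = PeakSet([_iv("chr1", 0, 100)])
        comp = te_class_composition(peaks, [], mode="chip")
        assert comp.attrs["te_fraction"] == 0.0
        assert len(comp) == 0


class TestPerCellTEFraction:
    def test_half_fraction(self):
        V = np.array([[1], [1]])
        X = BinaryAccessibilityMatrix(V, ["te", "nonte"], ["c0"],
                                      {"c0": "a"})
        # single group cannot be tested; check the fraction path via 2 groups
        V2 = np.array([[1, 1], [1, 0]])
        X2 = BinaryAccessibilityMatrix(V2, ["te", "nonte"], ["c0", "c1"],
                                       {"c0": "a", "c1": "b"})
        per_cell, _, _ = per_cell_te_fraction(X2, [True, False], seed=0)
        assert per_cell.loc[per_cell.cell_id == "c0",
                            "te_fraction"].iloc[0] == 0.5
        assert per_cell.loc[per_cell.cell_id == "c1",
                            "te_fraction"].iloc[0] == 1.0

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        V = (rng.random((30, 80)) < 0.5).astype(int)
        V[:, V.sum(axis=0) == 0] = 1
        labels = {f"c{j}": ("a" if j < 40 else "b") for j in range(80)}
        X = BinaryAccessibilityMatrix(V, [f"p{i}" for i in range(30)],
                                      list(labels), labels)
        flags = rng.random(30) < 0.4
        _, pw, kw_p = per_cell_te_fraction(X, flags, seed=1)
        assert kw_p > 0.05
        assert (pw["q"] > 0.05).all()

    def test_planted_te_rich_population(self, planted_dataset):
        ds = planted_dataset
        flags = np.array([ds.truth["peak_is_te"][p]
                          for p in ds.matrix.peak_ids])
        per_cell, pw, kw_p = per_cell_te_fraction(ds.matrix, flags, seed=0)
        med = per_cell.groupby("group")["te_fraction"].median()
        assert kw_p < 0.01
        # populations owning planted TE peaks are TE-richer than glia
        assert med["progenitor"] > med["glia"]
        assert med["neuron"] > med["glia"]
        rows = pw[(pw.group_a == "glia") | (pw.group_b == "glia")]
        assert (rows["q"] < 0.05).all()

    def test_subsampling_balances_groups(self, planted_dataset):
        ds = planted_dataset
        flags = np.array([ds.truth["peak_is_te"][p]
                          for p in ds.matrix.peak_ids])
        per_cell, pw, _ = per_cell_te_fraction(ds.matrix, flags,
                                               subsample_n=50, seed=0)
        assert (pw["q"] < 0.05).any()
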