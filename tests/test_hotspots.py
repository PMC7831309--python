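"""Hotspot construction, carrier logic and Fisher-exact association."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb

from rohscan.hotspots import (associate_hotspots, build_hotspots,
                              carrier_matrix, fisher_exact_2x2,
                              manhattan_export, snp_assoc_fisher,
                              snp_incidence)
from rohscan.roh import ROHSegment

from conftest import make_dataset


def marker_map(n, chrom="1", spacing=10_000):
    return make_dataset(np.zeros((1, n), dtype=np.int8), chrom=chrom,
                        positions=np.arange(1, n + 1) * spacing).markers


class TestIncidence:
    def test_no_segments_all_zero(self):
        mm = marker_map(50)
        assert snp_incidence([], mm).sum() == 0

    def test_two_identical_segments_count_two_inside(self):
        mm = marker_map(50)
        segs = [ROHSegment(s, "1", 100_000, 200_000, 11) for s in "ab"]
        inc = snp_incidence(segs, mm)
        inside = (mm["bp"] >= 100_000) & (mm["bp"] <= 200_000)
        assert (inc[inside.to_numpy()] == 2).all()
        assert (inc[~inside.to_numpy()] == 0).all()

    def test_same_sample_overlap_counts_once(self):
        mm = marker_map(50)
        segs = [ROHSegment("a", "1", 100_000, 200_000, 11),
                ROHSegment("a", "1", 150_000, 300_000, 16)]
        assert snp_incidence(segs, mm).max() == 1

    def test_matches_brute_force_on_random_fixture(self, rng):
        mm = marker_map(200)
        bp = mm["bp"].to_numpy()
        samples = [f"s{i}" for i in range(8)]
        segs = []
        for s in samples:
            for _ in range(rng.integers(0, 4)):
                lo = int(rng.integers(0, 150))
                hi = lo + int(rng.integers(5, 50))
                segs.append(ROHSegment(s, "1", int(bp[lo]),
                                       int(bp[min(hi, 199)]), hi - lo + 1))
        brute = np.array([
            len({g.sample_id for g in segs
                 if g.start_bp <= p <= g.end_bp}) for p in bp])
        np.testing.assert_array_equal(snp_incidence(segs, mm), brute)

    def test_unknown_chromosome_rejected(self):
        mm = marker_map(10)
        with pytest.raises(ValueError, match="unknown chromosome"):
            snp_incidence([ROHSegment("a", "7", 1, 2, 1)], mm)


class TestBuildHotspots:
    def test_low_incidence_yields_nothing(self):
        mm = marker_map(50)
        assert build_hotspots(np.ones(50, dtype=int), mm) == []

    @pytest.mark.parametrize("run_len,expected", [(9, 0), (10, 1)])
    def test_min_snps_threshold(self, run_len, expected):
        mm = marker_map(50)
        inc = np.zeros(50, dtype=int)
        inc[5:5 + run_len] = 2
        assert len(build_hotspots(inc, mm)) == expected

    def test_single_low_snp_splits_two_hotspots(self):
        mm = marker_map(50)
        inc = np.full(50, 3)
        inc[25] = 1
        spots = build_hotspots(inc, mm)
        assert len(spots) == 2
        assert spots[0].snp_end == 24 and spots[1].snp_start == 26

    def test_maximality_flanking_snps_below_share(self):
        mm = marker_map(50)
        inc = np.zeros(50, dtype=int)
        inc[10:30] = 2
        (h,) = build_hotspots(inc, mm)
        assert inc[h.snp_start - 1] < 2 and inc[h.snp_end + 1] < 2
        assert (inc[h.snp_start:h.snp_end + 1] >= 2).all()

    def test_runs_do_not_cross_chromosomes(self):
        ds = make_dataset(np.zeros((1, 40), dtype=np.int8),
                          chrom=["1"] * 20 + ["2"] * 20,
                          positions=list(range(1, 21)) * 2)
        mm = ds.markers.assign(bp=np.tile(np.arange(1, 21) * 10_000, 2))
        spots = build_hotspots(np.full(40, 5), mm)
        assert [h.chrom for h in spots] == ["1", "2"]


class TestCarrierMatrix:
    def setup_method(self):
        self.mm = marker_map(100)
        bp = self.mm["bp"].to_numpy()
        inc = np.zeros(100, dtype=int)
        inc[40:60] = 2
        (self.hot,) = build_hotspots(inc, self.mm)
        self.bp = bp

    def test_spanning_segment_is_carrier(self):
        segs = [ROHSegment("a", "1", self.bp[30], self.bp[70], 41)]
        mat = carrier_matrix([self.hot], segs, ["a"], self.mm,
                             overlap_fraction=1.0)
        assert mat.loc["a"].item()

    def test_no_roh_on_chromosome_not_carrier(self):
        segs = [ROHSegment("a", "2", 1, 10**7, 100)]
        mm2 = pd.concat([self.mm, self.mm.assign(chrom="2")],
                        ignore_index=True)
        mat = carrier_matrix([self.hot], segs, ["a"], mm2)
        assert not mat.loc["a"].item()

    def test_half_coverage_depends_on_fraction(self):
        # covers SNPs 40..49 = 10 of the hotspot's 20
        segs = [ROHSegment("a", "1", self.bp[40], self.bp[49], 10)]
        strict = carrier_matrix([self.hot], segs, ["a"], self.mm,
                                overlap_fraction=1.0)
        half = carrier_matrix([self.hot], segs, ["a"], self.mm,
                              overlap_fraction=0.5)
        assert not strict.loc["a"].item()
        assert half.loc["a"].item()

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            carrier_matrix([self.hot], [], ["a"], self.mm,
                           overlap_fraction=0.0)


def fisher_enumeration(a, b, c, d):
    """Hypergeometric enumeration oracle for the two-sided p-value."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1, exact=True)
    probs = []
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs.append((x, comb(r1, x, exact=True)
                      * comb(r2, c1 - x, exact=True)))
    p_obs = dict(probs)[a]
    return sum(p for _, p in probs if p <= p_obs) / denom


class TestFisherExact:
    def test_balanced_table_is_one(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == 1.0

    def test_perfect_separation_small(self):
        assert fisher_exact_2x2(5, 0, 0, 5) == pytest.approx(
            2 / comb(10, 5, exact=True), rel=1e-12)

    @settings(max_examples=80, deadline=None)
    @given(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8),
           st.integers(0, 8))
    def test_matches_enumeration(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or (a + c == 0 and b + d == 0):
            return
        if a + b + c + d == 0:
            return
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            fisher_enumeration(a, b, c, d), rel=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 0, 0)


class TestAssociation:
    def _carriers(self, pattern, hotspot="S1"):
        return pd.DataFrame({hotspot: pattern},
                            index=pd.Index([f"i{k}" for k
                                            in range(len(pattern))],
                                           name="sample_id"))

    def _groups(self, n_cases, n_controls):
        labels = ["case"] * n_cases + ["control"] * n_controls
        return pd.Series(labels, index=[f"i{k}" for k in range(len(labels))])

    def test_perfectly_separating_hotspot_hits_floor_p(self):
        carriers = self._carriers([True] * 58 + [False] * 13)
        assoc = associate_hotspots(carriers, self._groups(58, 13))
        row = assoc.iloc[0]
        floor = fisher_enumeration(58, 0, 0, 13)
        assert row["p_value"] == pytest.approx(floor, rel=1e-9)
        assert row["significant"]

    def test_single_hotspot_threshold_is_alpha(self):
        carriers = self._carriers([True] * 5 + [False] * 5)
        assoc = associate_hotspots(carriers, self._groups(5, 5), alpha=0.05)
        assert assoc["bonferroni_threshold"].iloc[0] == 0.05

    def test_threshold_divides_by_hotspot_count(self):
        carriers = pd.concat([self._carriers([True] * 4 + [False] * 4,
                                             f"S{j}") for j in range(1, 6)],
                             axis=1)
        assoc = associate_hotspots(carriers, self._groups(4, 4), alpha=0.05)
        assert (assoc["bonferroni_threshold"] == 0.01).all()

    def test_unlabelled_individual_rejected(self):
        carriers = self._carriers([True, False, True])
        groups = pd.Series(["case", "control"], index=["i0", "i1"])
        with pytest.raises(ValueError, match="label"):
            associate_hotspots(carriers, groups)

    def test_manhattan_export_fields(self):
        mm = marker_map(30)
        inc = np.zeros(30, dtype=int)
        inc[5:20] = 2
        spots = build_hotspots(inc, mm)
        carriers = self._carriers([True] * 3 + [False] * 3,
                                  spots[0].hotspot_id)
        assoc = associate_hotspots(carriers, self._groups(3, 3))
        exp = manhattan_export(assoc, spots)
        assert list(exp.columns) == ["hotspot_id", "chrom", "midpoint_bp",
                                     "neg_log10_p"]
        assert exp["neg_log10_p"].iloc[0] == pytest.approx(
            -np.log10(assoc["p_value"].iloc[0]))


class TestSnpAssoc:
    def _dataset(self, case_geno, ctrl_geno):
        g = np.array([case_geno] * 6 + [ctrl_geno] * 6, dtype=np.int8)
        ds = make_dataset(g[:, None].repeat(3, axis=1))
        return ds

    def _groups(self, ds):
        labels = ["case"] * 6 + ["control"] * 6
        return pd.Series(labels,
                         index=ds.samples["sample_id"].astype(str))

    def test_identical_frequencies_give_one(self):
        ds = self._dataset(1, 1)
        out = snp_assoc_fisher(ds, self._groups(ds), ("1", 1, 10**6))
        assert (out["p_value"] == 1.0).all()

    def test_fully_diagnostic_snp_hits_floor(self):
        ds = self._dataset(2, 0)
        out = snp_assoc_fisher(ds, self._groups(ds), ("1", 1, 10**6))
        floor = fisher_enumeration(12, 0, 0, 12)
        assert out["p_value"].iloc[0] == pytest.approx(floor, rel=1e-9)
        assert out["significant"].all()

    def test_monomorphic_snp_is_one(self):
        ds = self._dataset(0, 0)
        out = snp_assoc_fisher(ds, self._groups(ds), ("1", 1, 10**6))
        assert (out["p_value"] == 1.0).all()

    def test_region_without_snps_rejected(self):
        ds = self._dataset(0, 0)
        with pytest.raises(ValueError, match="no SNPs"):
            snp_assoc_fisher(ds, self._groups(ds), ("1", 10**8, 10**9))
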