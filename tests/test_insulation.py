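"""Insulation scores, TAD calling, conservation, and breakpoint
association."""

import numpy as np
import pytest

from aneuhic import (
    AneuhicError,
    ContactMatrix,
    GenomeDef,
    ScalarTrack,
    assemble_tads,
    breakpoint_boundary_distances,
    call_boundaries,
    conserved_tads,
    distance_null_test,
    insulation_score,
    make_binmap,
    random_site_null,
    site_insulation_profile,
    tad_stats,
)
from aneuhic.insulation import InsulationTrack, TADSet


def flat_binmap(n_bins, resolution=40_000):
    g = GenomeDef(("chr1",), (n_bins * resolution,))
    return make_binmap(g, resolution)


def brute_force_insulation(values, masked, w):
    """Direct double-loop oracle for the square-window score."""
    m = len(values)
    raw = np.full(m, np.nan)
    for i in range(m):
        if masked[i] or i - w < 0 or i + w + 1 > m:
            continue
        vals = []
        for r in range(i - w, i):
            for c in range(i + 1, i + w + 1):
                if not masked[r] and not masked[c]:
                    vals.append(values[r, c])
        if len(vals) < 0.5 * w * w:
            continue
        raw[i] = np.mean(vals)
    defined = np.isfinite(raw) & (raw > 0)
    out = np.full(m, np.nan)
    out[defined] = np.log2(raw[defined] / raw[defined].mean())
    return out


class TestInsulationScore:
    def test_constant_matrix_scores_zero(self):
        bm = flat_binmap(20)
        m = ContactMatrix(bm, np.full((20, 20), 4.0))
        track = insulation_score(m, 160_000)
        defined = np.isfinite(track.values)
        assert defined.any()
        np.testing.assert_allclose(track.values[defined], 0.0, atol=1e-12)

    def test_two_block_matrix_valley_at_junction(self):
        n = 20
        bm = flat_binmap(n)
        v = np.ones((n, n))
        v[:10, :10] = 10.0
        v[10:, 10:] = 10.0
        m = ContactMatrix(bm, v)
        track = insulation_score(m, 160_000)  # w = 4 bins
        defined = np.flatnonzero(np.isfinite(track.values))
        argmin = defined[np.argmin(track.values[defined])]
        assert argmin in (9, 10)
        oracle = brute_force_insulation(v, bm.masked, 4)
        np.testing.assert_allclose(track.values, oracle, atol=1e-12)

    def test_matches_brute_force_oracle_with_masking(self):
        g = GenomeDef(
            ("chr1", "chr2"), (800_000, 600_000), (("chr1", 300_000, 350_000),)
        )
        bm = make_binmap(g, 40_000)
        rng = np.random.default_rng(10)
        u = np.triu(rng.uniform(1, 20, (bm.n_bins, bm.n_bins)))
        vals = u + np.triu(u, 1).T
        vals[bm.masked, :] = 0
        vals[:, bm.masked] = 0
        m = ContactMatrix(bm, vals)
        track = insulation_score(m, 120_000)  # w = 3
        for chrom in ("chr1", "chr2"):
            lo, hi = bm.chrom_range(chrom)
            oracle = brute_force_insulation(
                vals[lo:hi, lo:hi], bm.masked[lo:hi], 3
            )
            np.testing.assert_allclose(track.values[lo:hi], oracle, atol=1e-12)

    def test_chromosome_edges_missing(self):
        bm = flat_binmap(20)
        m = ContactMatrix(bm, np.full((20, 20), 2.0))
        track = insulation_score(m, 160_000)
        assert np.isnan(track.values[:4]).all()
        assert np.isnan(track.values[-4:]).all()

    def test_window_below_two_bins_errors(self):
        bm = flat_binmap(10)
        m = ContactMatrix(bm, np.ones((10, 10)))
        with pytest.raises(AneuhicError):
            insulation_score(m, 40_000)


def make_track(values, resolution=40_000):
    bm = flat_binmap(len(values), resolution)
    t = InsulationTrack(bm, np.asarray(values, dtype=float), "insulation")
    t.window_bp = 0
    return t


class TestCallBoundaries:
    def test_monotone_track_has_no_boundaries(self):
        t = make_track(np.linspace(-1, 1, 30))
        assert call_boundaries(t, 120_000, 0.0) == []

    def test_single_valley_found_at_minimum(self):
        x = np.abs(np.arange(30) - 14).astype(float) / 5.0  # V with min at 14
        t = make_track(x)
        bounds = call_boundaries(t, 120_000, 0.1)
        assert bounds == [("chr1", 14 * 40_000)]

    def test_deep_valleys_found_shallow_rejected(self):
        # three separated V valleys: depths 1.0, 0.05, 0.8; with the
        # 0.3 amplitude requirement only the two deep ones qualify
        def valley(center, depth, width, n):
            return -depth * np.clip(1 - np.abs(np.arange(n) - center) / width, 0, 1)

        n = 60
        x = valley(10, 1.0, 6, n) + valley(30, 0.05, 6, n) + valley(50, 0.8, 6, n)
        t = make_track(x)
        bounds = call_boundaries(t, 120_000, 0.3)
        assert sorted(p // 40_000 for _c, p in bounds) == [10, 50]

    def test_fully_missing_track_warns_empty(self):
        t = make_track([np.nan] * 10)
        with pytest.warns(RuntimeWarning):
            assert call_boundaries(t) == []

    def test_benchmark_boundary_recovery_noise_free(self, bench):
        from aneuhic import ice_normalize
        from conftest import boundary_recovery

        iced, _ = ice_normalize(bench["expected"])
        ins = insulation_score(iced, 480_000)
        bounds = call_boundaries(ins, 120_000, 0.1)
        assert boundary_recovery(bench["model"], ins, bounds) >= 0.9


class TestAssembleTads:
    def test_short_interval_dropped(self):
        bm = flat_binmap(50)
        tads = assemble_tads(
            [("chr1", 1_000_000), ("chr1", 1_160_000)], bm, min_size=200_000
        )
        assert tads.intervals == []

    def test_long_interval_kept(self):
        bm = flat_binmap(50)
        tads = assemble_tads([("chr1", 1_000_000), ("chr1", 1_600_000)], bm)
        assert tads.intervals == [("chr1", 1_000_000, 1_600_000)]

    def test_gap_overlapping_interval_dropped(self):
        g = GenomeDef(("chr1",), (2_000_000,), (("chr1", 1_200_000, 1_300_000),))
        bm = make_binmap(g, 40_000)
        tads = assemble_tads([("chr1", 1_000_000), ("chr1", 1_600_000)], bm)
        assert tads.intervals == []


class TestConservedTads:
    def tset(self, intervals):
        return TADSet(list(intervals), [], "")

    def test_identical_sets_all_conserved(self):
        a = self.tset([("chr1", 0, 1_000_000), ("chr1", 1_000_000, 1_600_000)])
        pairs, ca, cb = conserved_tads(a, a)
        assert len(pairs) == 2 and ca == [] and cb == []

    def test_reciprocal_rule_rejects_one_sided_overlap(self):
        a = self.tset([("chr1", 0, 1_000_000)])
        b = self.tset([("chr1", 0, 600_000)])
        pairs, ca, cb = conserved_tads(a, b)
        assert pairs == [] and ca == [0] and cb == [0]

    def test_exactly_seventy_percent_counts_as_conserved(self):
        a = self.tset([("chr1", 0, 1_000_000)])
        b = self.tset([("chr1", 300_000, 1_300_000)])  # overlap 700k of both
        pairs, _ca, _cb = conserved_tads(a, b, frac=0.70)
        assert pairs == [(0, 0)]

    def test_symmetry(self):
        a = self.tset(
            [("chr1", 0, 800_000), ("chr1", 800_000, 1_400_000), ("chr2", 0, 600_000)]
        )
        b = self.tset(
            [("chr1", 40_000, 840_000), ("chr1", 900_000, 1_400_000), ("chr2", 0, 560_000)]
        )
        p1, ca1, cb1 = conserved_tads(a, b)
        p2, cb2, ca2 = conserved_tads(b, a)
        assert sorted((j, i) for i, j in p1) == sorted(p2)
        assert ca1 == ca2 and cb1 == cb2


class TestTadStats:
    def test_median_of_three(self):
        t = TADSet(
            [("chr1", 0, 400_000), ("chr1", 400_000, 1_000_000), ("chr1", 1_000_000, 1_800_000)],
            [], "")
        count, median, mean = tad_stats(t)
        assert (count, median) == (3, 600_000.0)
        assert mean == pytest.approx(600_000.0)

    def test_empty_set(self):
        assert tad_stats(TADSet([], [], "")) == (0, None, None)

    def test_single_tad(self):
        t = TADSet([("chr1", 0, 400_000)], [], "")
        assert tad_stats(t) == (1, 400_000.0, 400_000.0)


class TestBreakpointDistances:
    def test_exact_hit_distance_zero(self):
        d, s = breakpoint_boundary_distances(
            [("chr1", 1_000_000)], [("chr1", 1_000_000)]
        )
        assert d == [0.0] and s["frac_exact"] == 1.0

    def test_within_120kb_counted(self):
        d, s = breakpoint_boundary_distances(
            [("chr1", 1_120_000)], [("chr1", 1_000_000), ("chr1", 2_000_000)]
        )
        assert d == [120_000.0]
        assert s["frac_near"] == 1.0 and s["frac_exact"] == 0.0

    def test_chromosome_without_boundaries_missing(self):
        d, s = breakpoint_boundary_distances(
            [("chr2", 500_000), ("chr1", 100_000)], [("chr1", 0)]
        )
        assert np.isnan(d[0]) and s["n"] == 1


class TestNullTest:
    def test_identical_samples_give_half_p(self):
        obs = [1.0, 2.0, 3.0, 4.0]
        _stat, p = distance_null_test(obs, obs)
        assert p == pytest.approx(0.5, abs=0.05)

    def test_complete_separation_small_p(self):
        obs = [0.0] * 12
        null = list(np.arange(1, 13, dtype=float))
        _stat, p = distance_null_test(obs, null)
        assert p < 0.01

    def test_null_sites_count_matched_per_chromosome(self, bench):
        bps = bench["model"].planted_breakpoints()
        sites = random_site_null(bps, bench["raw"].binmap, np.random.default_rng(0))
        count = lambda xs: {c: sum(1 for cc, _ in xs if cc == c) for c, _ in xs}
        assert count(sites) == count(bps)


class TestSiteProfile:
    def test_constant_track_flat_profile(self):
        bm = flat_binmap(60)
        t = ScalarTrack(bm, np.full(60, 1.5), "x")
        prof = site_insulation_profile([("chr1", 1_200_000)], t, 400_000)
        np.testing.assert_allclose(prof.means, 1.5)

    def test_empty_sites_error(self):
        bm = flat_binmap(10)
        t = ScalarTrack(bm, np.zeros(10), "x")
        with pytest.raises(AneuhicError):
            site_insulation_profile([], t)

    def test_edge_sites_contribute_partial_offsets(self):
        bm = flat_binmap(30)
        t = ScalarTrack(bm, np.arange(30, dtype=float), "x")
        prof = site_insulation_profile([("chr1", 0)], t, 200_000)  # F = 5
        assert prof.n_sites[0] == 0  # offset -5 off the chromosome
        assert prof.n_sites[-1] == 1

    def test_breakpoint_profile_dips_at_center(self, bench):
        from aneuhic.cnv import blocks_and_breakpoints

        _blocks, bps = blocks_and_breakpoints(bench["profile"])
        prof = site_insulation_profile(bps, bench["insulation"], 1_000_000)
        center = prof.means[len(prof.means) // 2]
        flanks = np.nanmean(np.r_[prof.means[:5], prof.means[-5:]])
        assert center < flanks
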