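"""The synthetic aneuploid-genome generator and its planted truth."""

import numpy as np
import pytest

from aneuhic import SimConfig, make_binmap
from aneuhic.normalize import median_block_diagonal
from aneuhic.simulate import (
    expected_hic,
    perturb_labels,
    simulate_expression,
    simulate_gene_density,
    simulate_genome_model,
    simulate_hic,
    simulate_junction_candidates,
    simulate_wgs_depth,
    stage_rng,
)


def small_config(**kw) -> SimConfig:
    base = dict(n_chroms=2, chrom_length=6_000_000, gap_length=0,
                n_translocations=1, blocks_per_chrom=(2, 3), min_block_bins=10,
                sv_resolution=1_000_000, seed=7)
    base.update(kw)
    return SimConfig(**base)


class TestGenomeModel:
    def test_same_seed_identical_model(self):
        cfg = small_config()
        a = simulate_genome_model(cfg)
        b = simulate_genome_model(cfg)
        assert a.cnv_blocks == b.cnv_blocks
        assert a.tad_intervals == b.tad_intervals
        assert (a.compartment_labels == b.compartment_labels).all()
        assert a.translocations == b.translocations

    def test_full_alignment_puts_breakpoints_on_boundaries(self):
        cfg = small_config(boundary_alignment_fraction=1.0)
        m = simulate_genome_model(cfg)
        boundaries = set(m.planted_boundaries())
        assert m.planted_breakpoints()  # something to check
        for bp in m.planted_breakpoints():
            assert bp in boundaries

    def test_zero_alignment_keeps_breakpoints_off_boundaries(self):
        cfg = small_config(boundary_alignment_fraction=0.0)
        m = simulate_genome_model(cfg)
        boundaries = set(m.planted_boundaries())
        for bp in m.planted_breakpoints():
            assert bp not in boundaries

    def test_blocks_tile_and_levels_cover(self):
        cfg = SimConfig(seed=3)
        m = simulate_genome_model(cfg)
        # tiling enforced by the GenomeModel validator on construction;
        # every requested non-baseline level appears genome-wide
        present = {b[3] for b in m.cnv_blocks}
        assert set(cfg.cnv_levels) <= present


class TestExpectedHic:
    def test_no_trans_signal_when_beta_and_sigma_zero(self):
        cfg = small_config(inter_scale=0.0, stripe_scale=0.0)
        m = simulate_genome_model(cfg)
        E = expected_hic(m, cfg)
        bm = E.binmap
        inter = bm.chrom_ids[:, None] != bm.chrom_ids[None, :]
        assert E.values[inter].sum() == 0

    def test_distance_decay_ratio_closed_form(self):
        # uniform copy number, factors switched off by tiny epsilon:
        # E[i,i+1]/E[i,i+2] must equal (3/2)^alpha within the same TAD
        cfg = small_config(
            alpha=1.0, tad_factor=1 + 1e-12, compartment_factor=1 + 1e-12,
            cnv_levels=(2,), blocks_per_chrom=(1, 1), n_translocations=0,
        )
        m = simulate_genome_model(cfg)
        E = expected_hic(m, cfg)
        i = 5
        ratio = E.values[i, i + 1] / E.values[i, i + 2]
        assert ratio == pytest.approx((3 / 2) ** cfg.alpha, rel=1e-9)

    def test_copy_number_homogeneity_degree_two(self):
        cfg = small_config(stripe_scale=0.0, n_translocations=0)
        m = simulate_genome_model(cfg)
        E1 = expected_hic(m, cfg)
        doubled = [(c, s, e, 2 * cn) for c, s, e, cn in m.cnv_blocks]
        m2 = type(m)(
            genome=m.genome, ploidy=m.ploidy, cnv_blocks=doubled,
            tad_intervals=m.tad_intervals,
            compartment_labels=m.compartment_labels,
            coarse_binmap=m.coarse_binmap, translocations=m.translocations,
        )
        E2 = expected_hic(m2, cfg)
        np.testing.assert_allclose(E2.values, 4 * E1.values, rtol=1e-12)

    def test_intra_total_scales_linearly_with_s(self):
        cfg = small_config(n_translocations=0, inter_scale=0.0)
        m = simulate_genome_model(cfg)
        E1 = expected_hic(m, cfg)
        cfg2 = small_config(
            n_translocations=0, inter_scale=0.0, intra_scale=2 * cfg.intra_scale
        )
        E2 = expected_hic(m, cfg2)
        assert E2.values.sum() == pytest.approx(2 * E1.values.sum(), rel=1e-12)

    def test_block_medians_increase_with_copy_number(self):
        """Diagonal medians recomputed from E directly order with CN."""
        cfg = SimConfig(seed=5)
        m = simulate_genome_model(cfg)
        E = expected_hic(m, cfg)
        meds = {}
        for block in m.cnv_blocks:
            v = median_block_diagonal(E, block, band_width=0)
            if v is not None:
                meds.setdefault(block[3], []).append(v)
        per_cn = {cn: np.median(v) for cn, v in meds.items()}
        cns = sorted(per_cn)
        assert all(per_cn[a] < per_cn[b] for a, b in zip(cns, cns[1:]))


class TestSimulateHic:
    def test_determinism(self):
        cfg = small_config()
        m = simulate_genome_model(cfg)
        a = simulate_hic(m, cfg, np.random.default_rng(11))
        b = simulate_hic(m, cfg, np.random.default_rng(11))
        np.testing.assert_array_equal(a.values, b.values)

    def test_counts_are_integer_and_symmetric(self):
        cfg = small_config()
        m = simulate_genome_model(cfg)
        x = simulate_hic(m, cfg)
        assert np.array_equal(x.values, np.rint(x.values))
        assert np.array_equal(x.values, x.values.T)


class TestDepth:
    def test_mean_matches_poisson_rate(self):
        cfg = small_config(cnv_levels=(2,), blocks_per_chrom=(1, 1))
        m = simulate_genome_model(cfg)
        d = simulate_wgs_depth(m, cfg, np.random.default_rng(0))
        vals = d.values[np.isfinite(d.values)]
        se = np.sqrt(cfg.depth_per_copy / len(vals))
        assert abs(vals.mean() - cfg.depth_per_copy) < 3 * se

    def test_zero_copy_block_gives_zero_depth(self):
        cfg = small_config()
        m = simulate_genome_model(cfg)
        blocks = list(m.cnv_blocks)
        blocks[0] = (blocks[0][0], blocks[0][1], blocks[0][2], 0)
        m2 = type(m)(
            genome=m.genome, ploidy=m.ploidy, cnv_blocks=blocks,
            tad_intervals=m.tad_intervals,
            compartment_labels=m.compartment_labels,
            coarse_binmap=m.coarse_binmap, translocations=m.translocations,
        )
        d = simulate_wgs_depth(m2, cfg, np.random.default_rng(0))
        bm = d.binmap
        chrom, s, e, _ = blocks[0]
        lo, hi = bm.chrom_range(chrom)
        sel = (bm.starts[lo:hi] >= s) & (bm.starts[lo:hi] < e)
        vals = d.values[lo:hi][sel]
        assert np.nansum(vals) == 0

    def test_determinism(self):
        cfg = small_config()
        m = simulate_genome_model(cfg)
        a = simulate_wgs_depth(m, cfg, np.random.default_rng(4))
        b = simulate_wgs_depth(m, cfg, np.random.default_rng(4))
        np.testing.assert_array_equal(a.values, b.values)


class TestJunctions:
    def test_true_records_pass_and_decoys_fail(self):
        cfg = SimConfig(seed=2)
        m = simulate_genome_model(cfg)
        df = simulate_junction_candidates(m, cfg)
        true = df[df.is_true]
        assert len(true) == cfg.n_translocations
        assert (true.supportA / true.totalA > 0.2).all()
        assert (true.supportB / true.totalB > 0.2).all()
        assert (true.supportA + true.supportB > 60).all()
        decoys = df[~df.is_true]
        frac_ok = (decoys.supportA / decoys.totalA > 0.10) & (
            decoys.supportB / decoys.totalB > 0.10
        )
        sum_ok = decoys.supportA + decoys.supportB > 40
        assert not (frac_ok & sum_ok).any()

    def test_no_translocations_emits_only_decoys(self):
        cfg = small_config(n_translocations=0)
        m = simulate_genome_model(cfg)
        df = simulate_junction_candidates(m, cfg)
        assert not df.is_true.any()
        assert len(df) == cfg.n_decoys


class TestExpression:
    def test_planted_shift_recovered(self):
        cfg = small_config(expr_delta=1.0, expr_sd=0.1)
        m = simulate_genome_model(cfg)
        ea, _eb = simulate_expression(
            m.compartment_labels, m.compartment_labels, m.coarse_binmap, cfg,
            np.random.default_rng(0),
        )
        a = ea.values[(m.compartment_labels == "A") & np.isfinite(ea.values)]
        b = ea.values[(m.compartment_labels == "B") & np.isfinite(ea.values)]
        se = cfg.expr_sd * np.sqrt(1 / len(a) + 1 / len(b))
        assert abs((a.mean() - b.mean()) - 1.0) < 3 * se

    def test_zero_delta_means_equal_within_noise(self):
        cfg = small_config(expr_delta=0.0, expr_sd=0.1)
        m = simulate_genome_model(cfg)
        ea, _ = simulate_expression(
            m.compartment_labels, m.compartment_labels, m.coarse_binmap, cfg,
            np.random.default_rng(1),
        )
        a = ea.values[(m.compartment_labels == "A") & np.isfinite(ea.values)]
        b = ea.values[(m.compartment_labels == "B") & np.isfinite(ea.values)]
        se = cfg.expr_sd * np.sqrt(1 / len(a) + 1 / len(b))
        assert abs(a.mean() - b.mean()) < 3 * se

    def test_gene_density_higher_in_a(self):
        cfg = SimConfig(seed=1)
        m = simulate_genome_model(cfg)
        gd = simulate_gene_density(m, cfg)
        a = gd.values[(m.compartment_labels == "A") & np.isfinite(gd.values)]
        b = gd.values[(m.compartment_labels == "B") & np.isfinite(gd.values)]
        assert a.mean() > b.mean()


def test_stage_rng_stable_and_distinct():
    a = stage_rng(5, "hic").integers(1 << 30)
    b = stage_rng(5, "hic").integers(1 << 30)
    c = stage_rng(5, "depth").integers(1 << 30)
    assert a == b != c


def test_perturb_labels_flips_requested_fraction():
    labels = np.array(["A", "B"] * 50)
    out = perturb_labels(labels, 0.2, np.random.default_rng(0))
    assert (labels != out).sum() == 20
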