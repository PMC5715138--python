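import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aneuhic import (
    GenomeDef,
    SimConfig,
    call_cnv_from_depth,
    ice_normalize,
    make_binmap,
    mask_zero_coverage,
    simulate_genome_model,
    simulate_hic,
    simulate_wgs_depth,
)
from aneuhic.insulation import call_boundaries, insulation_score
from aneuhic.simulate import stage_rng

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

BENCHMARK_SEED = 0


@pytest.fixture(scope="session")
def tiny_genome() -> GenomeDef:
    """Three short chromosomes with one declared gap."""
    return GenomeDef(
        ("chr1", "chr2", "chr3"),
        (400_000, 280_000, 200_000),
        (("chr1", 200_000, 240_000),),
    )


@pytest.fixture(scope="session")
def tiny_binmap(tiny_genome):
    return make_binmap(tiny_genome, 40_000)


@pytest.fixture(scope="session")
def bench_config() -> SimConfig:
    """The standard synthetic benchmark at its fixed seed."""
    return SimConfig(seed=BENCHMARK_SEED)


@pytest.fixture(scope="session")
def bench(bench_config):
    """Shared seed-0 benchmark bundle: model, matrices, calls.

    Session-scoped because the full simulation plus ICE plus insulation
    is the expensive part of the suite and is reused by many tests.
    """
    cfg = bench_config
    model = simulate_genome_model(cfg)
    raw = mask_zero_coverage(simulate_hic(model, cfg, stage_rng(cfg.seed, "hic")))
    expected = mask_zero_coverage(simulate_hic(model, cfg, noise=False))
    depth = simulate_wgs_depth(model, cfg, stage_rng(cfg.seed, "depth"))
    profile = call_cnv_from_depth(depth, cfg.ploidy)
    iced, ice_bias = ice_normalize(raw)
    ins = insulation_score(iced, 480_000)
    bounds = call_boundaries(ins, 120_000, 0.1)
    return {
        "config": cfg,
        "model": model,
        "raw": raw,
        "expected": expected,
        "depth": depth,
        "profile": profile,
        "iced": iced,
        "ice_bias": ice_bias,
        "insulation": ins,
        "boundaries": bounds,
    }


def boundary_recovery(model, ins, bounds) -> float:
    """Fraction of planted TAD boundaries recovered within +/- 1 bin,
    among boundaries where the insulation score is defined."""
    bm = ins.binmap
    res = bm.resolution
    bset = set(bounds)
    n_eval = n_hit = 0
    for chrom, pos in model.planted_boundaries():
        i = bm.bin_at(chrom, pos)
        if not np.isfinite(ins.values[i]):
            continue
        n_eval += 1
        if any((chrom, pos + d * res) in bset for d in (-1, 0, 1)):
            n_hit += 1
    return n_hit / n_eval if n_eval else float("nan")
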