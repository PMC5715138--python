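"""End-to-end orchestration: simulate -> normalize -> CNV -> SV -> TADs
-> compartments -> expression association, with a machine-readable
report.

A single global seed fans out to per-stage child seeds derived by
stable hashing of stage names, so adding a stage never perturbs the
randomness of earlier stages. Every analysis parameter is echoed into
the run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import (
    AneuhicError,
    ContactMatrix,
    ScalarTrack,
    coarsen_matrix,
    mask_zero_coverage,
)
from . import io as aio
from .cnv import (
    blocks_and_breakpoints,
    call_cnv_from_depth,
    correlate_cnv,
    hic_coverage_track,
)
from .compartments import (
    classify_switches,
    compartment_eigenvector,
    switch_expression_association,
    switch_proportions,
)
from .insulation import (
    assemble_tads,
    breakpoint_boundary_distances,
    call_boundaries,
    conserved_tads,
    distance_null_test,
    insulation_score,
    random_site_null,
    site_insulation_profile,
    tad_stats,
)
from .normalize import cnv_bias_regression, covnorm_normalize, ice_normalize
from .simulate import (
    GenomeModel,
    SimConfig,
    perturb_labels,
    simulate_covariates,
    simulate_expression,
    simulate_gene_density,
    simulate_genome_model,
    simulate_hic,
    simulate_junction_candidates,
    simulate_wgs_depth,
    stage_rng,
)

logger = logging.getLogger(__name__)


class PipelineError(AneuhicError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All parameters of one pipeline run.

    ``sim`` holds the synthetic-benchmark settings; the remaining
    fields are analysis parameters, every one of which the run
    manifest echoes.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    use_depth: bool = True  # False: derive CNV from Hi-C coverage only
    band_width: int = 0
    ice_max_iter: int = 200
    ice_tol: float = 1e-5
    smooth_window: int = 5
    min_block_bins: int = 5
    top_k: int = 20
    insulation_window_bp: int = 480_000
    delta_window_bp: int = 120_000
    boundary_strength_min: float = 0.1
    min_tad_size: int = 200_000
    conserved_frac: float = 0.70
    near_bp: int = 120_000
    profile_flank: int = 1_000_000
    normal_tad_size_bins: tuple[int, int] = (15, 35)

    def __post_init__(self) -> None:
        self.sim = replace(self.sim, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_keys = {f.name for f in dataclasses.fields(SimConfig)}
        run_keys = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        sim_kwargs = raw.pop("sim", {}) or {}
        unknown = set(sim_kwargs) - sim_keys
        if unknown:
            raise AneuhicError(f"unknown sim config keys: {sorted(unknown)}")
        unknown = set(raw) - run_keys
        if unknown:
            raise AneuhicError(f"unknown config keys: {sorted(unknown)}")
        return cls(sim=SimConfig(**sim_kwargs), **raw)

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        text = json.dumps(self.manifest(), sort_keys=True, default=str)
        return hashlib.sha1(text.encode()).hexdigest()[:12]


def derive_normal_model(
    model: GenomeModel, config: RunConfig, rng: np.random.Generator
) -> GenomeModel:
    """Diploid companion of a tumor model: uniform copy number, larger
    TADs, perturbed compartment labels, no translocations."""
    sim = replace(
        config.sim,
        tad_size_bins=config.normal_tad_size_bins,
        blocks_per_chrom=(1, 1),
        n_translocations=0,
        boundary_alignment_fraction=0.0,
    )
    normal = simulate_genome_model(sim, rng)
    labels = perturb_labels(model.compartment_labels, config.sim.normal_flip_fraction, rng)
    return replace(
        normal,
        cnv_blocks=[
            (c, 0, model.genome.chrom_length(c), model.ploidy)
            for c in model.genome.chrom_names
        ],
        compartment_labels=labels,
    )


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute all analysis stages on the synthetic benchmark.

    Returns the run report; when ``outdir`` is given, intermediate
    artifacts (contact COO, depth bedGraph, junction TSV, truth BEDs,
    called tracks) and the report JSON are written there. Any stage
    error aborts with the stage name; partial outputs are retained
    alongside a FAILED marker.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "parameters": config.manifest(),
    }
    stage = "setup"
    try:
        sim = config.sim

        stage = "simulate"
        model = simulate_genome_model(sim, stage_rng(config.seed, "model"))
        raw = simulate_hic(model, sim, stage_rng(config.seed, "hic"))
        raw = mask_zero_coverage(raw)
        depth = simulate_wgs_depth(model, sim, stage_rng(config.seed, "depth"))
        junctions = simulate_junction_candidates(model, sim, stage_rng(config.seed, "junctions"))
        covs = simulate_covariates(raw.binmap, stage_rng(config.seed, "covariates"))
        if out is not None:
            _write_truth(out, model, depth, junctions, raw)

        stage = "cnv"
        profile_hic = call_cnv_from_depth(
            hic_coverage_track(raw), sim.ploidy,
            config.min_block_bins, config.smooth_window, source="hic",
        )
        if config.use_depth:
            profile = call_cnv_from_depth(
                depth, sim.ploidy, config.min_block_bins, config.smooth_window
            )
        else:
            profile = profile_hic
        blocks, breakpoints = blocks_and_breakpoints(profile)
        truth = model.copy_number_per_bin(profile.binmap)
        un = ~profile.binmap.masked
        report["cnv"] = {
            "source": profile.source,
            "n_blocks": len(blocks),
            "n_breakpoints": len(breakpoints),
            "bin_accuracy_vs_truth": float(
                (profile.copy_number[un] == truth[un]).mean()
            ),
            "wgs_hic_correlation": correlate_cnv(profile, profile_hic)
            if config.use_depth
            else None,
        }

        stage = "normalize"
        iced, bias_vec = ice_normalize(raw, config.ice_max_iter, config.ice_tol)
        covn = covnorm_normalize(raw, covs)
        report["bias"] = {}
        for name, mat in (("raw", raw), ("covnorm", covn), ("ice", iced)):
            res = cnv_bias_regression(mat, profile, config.band_width)
            report["bias"][name] = {
                "slope": res.slope,
                "intercept": res.intercept,
                "f_statistic": res.f_statistic,
                "p_value": res.p_value,
                "n_blocks": res.n_blocks,
            }
        report["bias"]["ice_converged"] = bias_vec.converged
        report["bias"]["ice_final_cv"] = bias_vec.final_cv

        stage = "translocation"
        from .translocation import (
            filter_junctions,
            junction_enrichment,
            top_interchrom_pairs,
        )

        filtered = filter_junctions(junctions)
        sv = coarsen_matrix(raw, sim.sv_resolution)
        top = top_interchrom_pairs(sv, config.top_k)
        enr = junction_enrichment(filtered, top, sv.binmap)
        report["translocation"] = {
            "n_candidates": int(len(filtered)),
            "n_passed": int(filtered["passed_filters"].sum()),
            "n_universe": enr.n_universe,
            "n_marked": enr.n_marked,
            "k_top": enr.k_top,
            "overlap": enr.overlap,
            "expected": enr.expected,
            "obs_exp_ratio": enr.obs_exp_ratio,
            "p_value": enr.p_value,
        }

        stage = "tads"
        ins = insulation_score(iced, config.insulation_window_bp)
        bounds = call_boundaries(ins, config.delta_window_bp, config.boundary_strength_min)
        tads = assemble_tads(bounds, ins.binmap, config.min_tad_size, source="tumor")

        normal_model = derive_normal_model(model, config, stage_rng(config.seed, "normal_model"))
        raw_n = mask_zero_coverage(
            simulate_hic(normal_model, sim, stage_rng(config.seed, "normal_hic"))
        )
        iced_n, _ = ice_normalize(raw_n, config.ice_max_iter, config.ice_tol)
        ins_n = insulation_score(iced_n, config.insulation_window_bp)
        bounds_n = call_boundaries(ins_n, config.delta_window_bp, config.boundary_strength_min)
        tads_n = assemble_tads(bounds_n, ins_n.binmap, config.min_tad_size, source="normal")
        pairs, changed_t, changed_n = conserved_tads(tads, tads_n, config.conserved_frac)
        for label, ts in (("tumor", tads), ("normal", tads_n)):
            count, med, mean = tad_stats(ts)
            report.setdefault("tads", {})[label] = {
                "count": count,
                "median_size": med,
                "mean_size": mean,
            }
        report["tads"]["conserved"] = len(pairs)
        report["tads"]["changed_tumor"] = len(changed_t)
        report["tads"]["changed_normal"] = len(changed_n)

        stage = "breakpoint_association"
        dists, summary = breakpoint_boundary_distances(breakpoints, bounds, config.near_bp)
        null_sites = random_site_null(breakpoints, profile.binmap, stage_rng(config.seed, "null_sites"))
        null_dists, _ = breakpoint_boundary_distances(null_sites, bounds, config.near_bp)
        stat, p = distance_null_test(dists, null_dists)
        prof_bp = site_insulation_profile(breakpoints, ins, config.profile_flank, "breakpoints")
        center = prof_bp.means[len(prof_bp.means) // 2]
        flank_mean = np.nanmean(
            np.concatenate([prof_bp.means[:5], prof_bp.means[-5:]])
        )
        report["breakpoint_association"] = {
            **summary,
            "ranksum_statistic": stat,
            "ranksum_p": p,
            "profile_center": float(center),
            "profile_flank_mean": float(flank_mean),
        }

        stage = "compartments"
        gene_density = simulate_gene_density(model, sim, stage_rng(config.seed, "gene_density"))
        model_t2 = replace(
            model,
            compartment_labels=perturb_labels(
                model.compartment_labels,
                sim.second_tumor_flip_fraction,
                stage_rng(config.seed, "t2_labels"),
            ),
        )
        raw_t2 = mask_zero_coverage(
            simulate_hic(model_t2, sim, stage_rng(config.seed, "t2_hic"))
        )
        comp = {}
        truth_labels = {
            "tumor1": model.compartment_labels,
            "tumor2": model_t2.compartment_labels,
            "normal": normal_model.compartment_labels,
        }
        for label, mat in (("tumor1", raw), ("tumor2", raw_t2), ("normal", raw_n)):
            coarse = coarsen_matrix(mat, sim.coarse_resolution)
            iced_c, _ = ice_normalize(coarse, config.ice_max_iter, config.ice_tol)
            comp[label] = compartment_eigenvector(iced_c, gene_density)
        acc = {}
        for label, track in comp.items():
            defined = track.labels != ""
            acc[label] = float(
                (track.labels[defined] == truth_labels[label][defined]).mean()
            )
        switches = classify_switches(comp["normal"], comp["tumor1"], comp["tumor2"])
        report["compartments"] = {
            "label_accuracy": acc,
            "switch_proportions": switch_proportions(switches),
        }

        stage = "expression"
        expr_normal, expr_tumor = simulate_expression(
            normal_model.compartment_labels,
            model.compartment_labels,
            model.coarse_binmap,
            sim,
            stage_rng(config.seed, "expression"),
        )
        assoc = switch_expression_association(switches, expr_normal, expr_tumor)
        report["expression_association"] = assoc.to_dict(orient="records")

        if out is not None:
            _write_outputs(
                out, profile, blocks, breakpoints, ins, bounds, tads,
                comp, expr_normal, expr_tumor,
            )
            (out / "report.json").write_text(json.dumps(report, indent=2, default=_json_default))
        return report
    except AneuhicError as exc:
        if out is not None:
            (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc


def _json_default(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


def _write_truth(out: Path, model: GenomeModel, depth, junctions, raw) -> None:
    aio.write_intervals_bed(model.tad_intervals, out / "truth_tads.bed")
    aio.write_intervals_bed(
        [(c, p, p + 1) for c, p in model.planted_boundaries()],
        out / "truth_boundaries.bed",
    )
    aio.write_intervals_bed(model.cnv_blocks, out / "truth_cnv_blocks.bed")
    junctions.to_csv(out / "junctions.tsv", sep="\t", index=False)
    aio.write_track_bedgraph(depth, out / "depth.bedgraph")
    aio.write_contacts_coo(raw, out / "contacts_raw.coo.tsv")
    cb = model.coarse_binmap
    with open(out / "truth_compartments.bedgraph", "w") as fh:
        for i in range(cb.n_bins):
            fh.write(
                f"{cb.chrom_name(i)}\t{int(cb.starts[i])}\t{int(cb.ends[i])}\t"
                f"{1 if model.compartment_labels[i] == 'A' else -1}\n"
            )
    with open(out / "truth_translocations.tsv", "w") as fh:
        fh.write("chromA\tposA\tchromB\tposB\n")
        for ca, pa, cb_, pb in model.translocations:
            fh.write(f"{ca}\t{pa}\t{cb_}\t{pb}\n")


def _write_outputs(
    out, profile, blocks, breakpoints, ins, bounds, tads, comp,
    expr_normal, expr_tumor,
) -> None:
    bm = profile.binmap
    cn_track = ScalarTrack(bm, np.where(bm.masked, np.nan, profile.copy_number.astype(float)), "cn")
    aio.write_track_bedgraph(cn_track, out / "cnv_profile.bedgraph")
    aio.write_intervals_bed(blocks, out / "cnv_blocks.bed")
    aio.write_intervals_bed([(c, p, p + 1) for c, p in breakpoints], out / "cnv_breakpoints.bed")
    aio.write_track_bedgraph(ins, out / "insulation.bedgraph")
    aio.write_intervals_bed([(c, p, p + 1) for c, p in bounds], out / "tad_boundaries.bed")
    aio.write_intervals_bed(tads.intervals, out / "tads.bed")
    for label, track in comp.items():
        ev = ScalarTrack(track.binmap, track.eigenvector, "eigenvector")
        aio.write_track_bedgraph(ev, out / f"compartments_{label}.bedgraph")
    aio.write_track_bedgraph(expr_normal, out / "expression_normal.bedgraph")
    aio.write_track_bedgraph(expr_tumor, out / "expression_tumor.bedgraph")
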