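"""End-to-end orchestration: simulate/load -> filter -> distances ->
threshold -> assignment -> diversity -> spatial -> MSN.

Every stage's output is persisted under the run's output directory and
echoed into a machine-readable ``report.json``.  A single global seed is
fanned out deterministically into per-stage child seeds, so identical
config + seed reproduces every artifact byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import io as ckio
from .assignment import (
    assign_genets,
    gap_threshold,
    plateau_threshold,
    sexual_threshold,
)
from .distances import pairwise_matrix
from .diversity import diversity_stats, within_genet_variation
from .filtering import FilterParams, depth_sensitivity, run_filters
from .model import Dataset, GenetAssignment
from .msn import msn_from_assignment, write_graphml
from .sim import SimConfig, make_main_plot_preset, make_validation_preset
from .spatial import (
    genet_correlogram,
    genet_representatives,
    mantel_correlogram,
    moran_identity_correlogram,
)

log = logging.getLogger("clonekit")

_STAGES = ("simulate", "sexual", "spatial_identity", "spatial_within", "spatial_genet")


@dataclass
class RunConfig:
    # exactly one input source: a preset name, or file paths
    preset: str | None = None  # validation | main_plot
    vcf: str | None = None
    ssr: str | None = None
    coords: str | None = None
    filter_params: FilterParams = field(default_factory=FilterParams)
    model: str = "iam"
    threshold_method: str = "plateau"  # plateau | gap | sexual
    linkage: str = "single"
    n_perm: int = 1000
    max_dist: float = 18.0
    min_pairs: int = 2
    depth_scan: bool = False
    seed: int = 0
    outdir: str = "clonekit_run"

    def __post_init__(self) -> None:
        sources = [s for s in (self.preset, self.vcf, self.ssr) if s]
        if len(sources) != 1:
            raise ValueError("exactly one input source (preset, vcf or ssr) required")


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STAGES, children)}


def load_input(cfg: RunConfig, rng) -> tuple[Dataset, object | None]:
    """Dataset from the configured source; truth only for presets."""
    if cfg.preset == "validation":
        return make_validation_preset(rng)
    if cfg.preset == "main_plot":
        return make_main_plot_preset(rng)
    if cfg.preset is not None:
        raise ValueError(f"unknown preset {cfg.preset!r}")
    if cfg.vcf:
        gt, depths = ckio.read_vcf(cfg.vcf)
        sheet = ckio.read_coords(cfg.coords) if cfg.coords else None
        if sheet is not None:
            ckio.check_ids_match(gt, sheet)
        return Dataset(gt, depths, sheet), None
    gt = ckio.read_ssr_table(cfg.ssr)
    sheet = ckio.read_coords(cfg.coords) if cfg.coords else None
    if sheet is not None:
        ckio.check_ids_match(gt, sheet)
    return Dataset(gt, None, sheet), None


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in order; returns the report dict."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rngs = _stage_rngs(cfg.seed)
    report: dict = {"config": _config_dict(cfg), "seed": cfg.seed}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    ds, truth = stage("input", load_input, cfg, rngs["simulate"])
    ckio.write_dataset(out, ds, prefix="input")
    if truth is not None:
        ckio.write_truth(out / "truth.csv", truth)
        (out / "sim_manifest.json").write_text(
            json.dumps(truth.manifest, indent=2, sort_keys=True, default=str)
        )
    log.info("input: %d samples x %d loci", ds.genotypes.n_samples, ds.genotypes.n_loci)

    filtered, masked, freport = stage("filtering", run_filters, ds, cfg.filter_params)
    freport.to_frame().to_csv(out / "filter_report.csv", index=False)
    (out / "filter_report.json").write_text(
        json.dumps(
            {
                "counts": freport.to_frame().set_index("stage")["count"].to_dict(),
                "locus_fail_reason": freport.locus_fail_reason,
                "sample_fail_reason": freport.sample_fail_reason,
            },
            indent=2,
            sort_keys=True,
        )
    )
    log.info(
        "filtering: %d -> %d loci, %d -> %d samples (min depth %d)",
        freport.n_loci_input, freport.n_loci_maf,
        freport.n_samples_input, freport.n_samples_retained, cfg.filter_params.min_depth,
    )
    report["filter"] = {
        "n_loci": freport.n_loci_maf,
        "n_samples": freport.n_samples_retained,
    }

    dm = stage("distances", pairwise_matrix, masked, model=cfg.model)
    ckio.write_matrix(out / "distances.csv", dm)
    np.savetxt(
        out / "distance_histogram.csv",
        np.column_stack([np.arange(len(dm.histogram())), dm.histogram()]),
        fmt="%d", delimiter=",", header="distance,n_pairs", comments="",
    )

    if cfg.threshold_method == "plateau":
        diag = stage("threshold", plateau_threshold, dm, cfg.linkage)
    elif cfg.threshold_method == "gap":
        diag = stage("threshold", gap_threshold, dm, cfg.linkage)
    elif cfg.threshold_method == "sexual":
        diag = stage(
            "threshold", sexual_threshold, masked, rng=rngs["sexual"], model=cfg.model
        )
    else:
        raise ValueError(f"unknown threshold method {cfg.threshold_method!r}")
    log.info("threshold (%s): %.3f", diag.method, diag.threshold)
    (out / "threshold.json").write_text(
        json.dumps(
            {
                "method": diag.method,
                "threshold": diag.threshold,
                "low_mode": diag.low_mode,
                "high_mode": diag.high_mode,
                "valley": diag.valley,
                "plateau_run": diag.plateau_run,
                "extras": diag.extras,
            },
            indent=2, sort_keys=True, default=str,
        )
    )
    if diag.curve_t is not None:
        np.savetxt(
            out / "genet_count_curve.csv",
            np.column_stack([diag.curve_t, diag.curve_n_genets]),
            fmt="%d", delimiter=",", header="threshold,n_genets", comments="",
        )

    assignment = stage("assignment", assign_genets, dm, diag.threshold, cfg.linkage)
    ckio.write_assignment(out / "assignment.csv", assignment, filtered.sheet)
    log.info("assignment: %d genets at threshold %.3f", assignment.n_genets, diag.threshold)
    report["threshold"] = {"method": diag.method, "value": diag.threshold}
    report["n_genets"] = assignment.n_genets

    stats = stage("diversity", diversity_stats, assignment)
    (out / "diversity.json").write_text(json.dumps(stats.as_dict(), indent=2, sort_keys=True))
    within_genet_variation(filtered, assignment).to_csv(
        out / "within_genet_variation.csv", index=False
    )
    report["diversity"] = {
        "richness": stats.richness, "simpson_d": stats.simpson_d, "gini": stats.gini
    }
    log.info(
        "diversity: G/N=%.3f D=%.3f Gini=%.3f", stats.richness, stats.simpson_d, stats.gini
    )

    if truth is not None:
        report["truth"] = compare_assignments(assignment, truth.as_assignment())

    report["spatial"] = {}
    if filtered.sheet is not None:
        sheet = filtered.sheet
        kw = dict(n_perm=cfg.n_perm, max_dist=cfg.max_dist, min_pairs=cfg.min_pairs)
        if assignment.n_genets >= 2:
            corr = stage(
                "spatial_identity", moran_identity_correlogram,
                sheet, assignment, rng=rngs["spatial_identity"], **kw,
            )
            ckio.write_correlogram(out / "correlogram_identity.csv", corr)
            report["spatial"]["identity_significant_classes"] = corr.significant_classes()
        members = assignment.members(1)
        if len(members) >= 3:
            sub_dm = dm.subset(members)
            try:
                corr = mantel_correlogram(
                    sheet.subset(members), sub_dm, rng=rngs["spatial_within"], **kw
                )
                ckio.write_correlogram(out / "correlogram_within_g1.csv", corr)
                report["spatial"]["within_g1_significant_classes"] = corr.significant_classes()
            except ValueError as exc:  # constant distances: no structure measurable
                report["spatial"]["within_g1_flag"] = str(exc)
        if assignment.n_genets >= 3:
            reps, rep_sheet = genet_representatives(sheet, assignment)
            rep_dm = dm.subset(reps)
            try:
                corr = genet_correlogram(
                    rep_sheet, rep_dm, rng=rngs["spatial_genet"], **kw
                )
                ckio.write_correlogram(out / "correlogram_genet.csv", corr)
                report["spatial"]["genet_significant_classes"] = corr.significant_classes()
            except ValueError as exc:
                report["spatial"]["genet_flag"] = str(exc)

    graph, _ = stage("msn", msn_from_assignment, filtered, assignment)
    write_graphml(out / "msn.graphml", graph)
    report["msn"] = {"n_nodes": graph.number_of_nodes(), "n_edges": graph.number_of_edges()}

    if cfg.depth_scan:
        table = stage("depth_scan", depth_sensitivity, ds, params=cfg.filter_params,
                      linkage=cfg.linkage, model=cfg.model)
        table.to_csv(out / "depth_sensitivity.csv", index=False)
        report["depth_scan"] = table.to_dict(orient="records")

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    return report


def _config_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d["filter_params"] = asdict(cfg.filter_params)
    return d


def compare_assignments(a: GenetAssignment, b: GenetAssignment) -> dict:
    """Agreement between two partitions of the same samples.

    Adjusted Rand index (chance-corrected; 1 iff identical partitions),
    the fraction of unordered pairs on which the partitions agree, and
    both genet counts.
    """
    if set(a.samples) != set(b.samples):
        raise ValueError("assignments cover different sample sets")
    order = [b.samples.index(s) for s in a.samples]
    la = a.genet_ids
    lb = b.genet_ids[order]
    ari = float(adjusted_rand_score(la, lb))
    same_a = la[:, None] == la[None, :]
    same_b = lb[:, None] == lb[None, :]
    iu = np.triu_indices(len(la), k=1)
    agree = float((same_a[iu] == same_b[iu]).mean()) if len(la) > 1 else 1.0
    return {
        "ari": ari,
        "pairwise_agreement": agree,
        "n_genets_a": a.n_genets,
        "n_genets_b": b.n_genets,
    }
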