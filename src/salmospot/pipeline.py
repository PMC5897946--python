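"""End-to-end pipeline: simulate -> quantify -> cluster -> summarise -> scan.

The pipeline is configured by a plain mapping (usually loaded from YAML).
Schema (all sections optional unless noted):

    seed: int                      # single global seed, split per stage
    patterns:                      # image branch
      n_images: int
      process: poisson | thomas-cluster | hard-core
      intensity: float             # points / cm^2
      cluster_sd: float            # thomas only, cm
      mean_per_cluster: float      # thomas only
      min_dist: float              # hard-core only, cm
      window: [width_cm, height_cm]
      scale: float                 # cm per pixel
      radius_mean: float           # spot radius, cm
      noise_sd: float              # pixel noise
      min_area_cm2: float          # particle filter
      min_spots_for_ann: int
    cohort:                        # genetics branch; CohortSpec field names
      strains: [..]
      n_families_per_cross: int
      n_offspring_per_family: int
      variance_fractions: [v_strain, v_poly, v_qtl, v_residual]
      qtl_group: str
      qtl_position_cM: float
    scan:
      enabled: bool
      step_cM: float | null        # null scans markers only
      n_perm: int
      alpha: float

Every stage writes its tables under the run directory and the manifest
(`manifest.json`) is written last: config snapshot, per-stage seeds, digests
of all outputs, software version, timestamps and the exclusion log.  For a
fixed seed all stages are deterministic, so re-running reproduces every
output bit for bit (timestamps aside).
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genedrop import GeneticMap
from .groupstats import group_summaries, strain_family_shares
from .io import file_digest, write_genotypes, write_json, write_map, write_pedigree, write_table
from .patterns import PatternSpec, PointPattern, gen_pattern
from .phenosim import CohortSpec, simulate_cohort
from .render import render_spot_image
from .scan import heritability, qtl_variance_fractions, scan_genome
from .spatial import ann_ratio
from .spots import apply_exclusions, construct_roi, detect_spots, spot_density

__all__ = ["run_pipeline", "validate_config"]

_TOP_KEYS = {"seed", "patterns", "cohort", "scan"}
_PATTERN_KEYS = {
    "n_images", "process", "intensity", "cluster_sd", "mean_per_cluster",
    "min_dist", "window", "scale", "radius_mean", "noise_sd", "min_area_cm2",
    "min_spots_for_ann",
}
_COHORT_KEYS = {
    "strains", "n_families_per_cross", "n_offspring_per_family",
    "variance_fractions", "qtl_group", "qtl_position_cM", "qtl_allele_freq",
    "founder_allele_freqs", "half_sib", "trait_name", "total_variance",
    "map_n_groups", "map_n_markers_per_group", "map_spacing_cM",
}
_SCAN_KEYS = {"enabled", "step_cM", "n_perm", "alpha"}


def validate_config(config: dict) -> None:
    """Reject unknown keys anywhere in the config."""
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for section, allowed in (
        ("patterns", _PATTERN_KEYS), ("cohort", _COHORT_KEYS), ("scan", _SCAN_KEYS)
    ):
        extra = set(config.get(section, {})) - allowed
        if extra:
            raise ValueError(f"unknown key(s) in {section!r}: {sorted(extra)}")


def run_pipeline(config: dict, out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute the configured stages and write a reproducibility manifest.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    stage_seeds = {
        name: int(s) & 0x7FFFFFFF
        for name, s in zip(
            ("patterns", "cohort", "scan"),
            np.random.SeedSequence(seed).generate_state(3),
        )
    }
    manifest: dict = {
        "command": "run",
        "config": config,
        "seed": seed,
        "stage_seeds": stage_seeds,
        "software_version": __version__,
        "started": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": {},
        "exclusions": [],
    }

    try:
        if "patterns" in config:
            _run_pattern_stage(config["patterns"], out, stage_seeds["patterns"], manifest)
        if "cohort" in config:
            _run_cohort_stage(config, out, stage_seeds, manifest)
    except Exception as err:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline aborted: {err}") from err

    manifest["finished"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.tsv")):
        manifest["outputs"][p.name] = file_digest(p)
    write_json(manifest, out / "manifest.json")
    return manifest


def _run_pattern_stage(cfg: dict, out: Path, seed: int, manifest: dict) -> None:
    n_images = int(cfg.get("n_images", 20))
    window = cfg.get("window", [8.0, 5.0])
    scale = float(cfg.get("scale", 0.02))
    min_spots = int(cfg.get("min_spots_for_ann", 10))
    rows = []
    spot_rows = []
    for i in range(n_images):
        spec = PatternSpec(
            width=float(window[0]),
            height=float(window[1]),
            process=cfg.get("process", "poisson"),
            intensity=float(cfg.get("intensity", 1.5)),
            cluster_sd=float(cfg.get("cluster_sd", 0.3)),
            mean_per_cluster=float(cfg.get("mean_per_cluster", 8.0)),
            min_dist=float(cfg.get("min_dist", 0.0)),
            seed=seed + i,
        )
        pattern = gen_pattern(spec)
        image = render_spot_image(
            pattern,
            scale=scale,
            radius_mean=float(cfg.get("radius_mean", 0.08)),
            noise_sd=float(cfg.get("noise_sd", 0.0)),
            seed=seed + i,
        )
        roi = construct_roi(image.landmarks, image.pixels.shape, image.scale)
        det = detect_spots(
            image.pixels, roi, image.scale,
            min_area_cm2=float(cfg.get("min_area_cm2", 0.005)),
        )
        fish_id = f"img{i:03d}"
        density = spot_density(det.count, roi.area_cm2) if det.count else None
        record = {
            "id": fish_id,
            "spot_count": det.count,
            "roi_area_cm2": roi.area_cm2,
            "spot_density": density,
        }
        if det.count >= max(min_spots, 2):
            detected = PointPattern(
                det.centroids_cm[:, 0], det.centroids_cm[:, 1],
                roi.width * image.scale, roi.height * image.scale,
            )
            ann = ann_ratio(detected)
            record["ann_ratio"] = ann.ratio
            record["ann_class"] = ann.classification
        rows.append(record)
        spot_rows.append(det.to_frame(fish_id))

    fish = pd.DataFrame(rows)
    kept, log = apply_exclusions(fish, "density")
    manifest["exclusions"].extend(
        {"stage": "patterns", **rec} for rec in log.to_dict("records")
    )
    write_table(fish, out / "fish_spots.csv")
    write_table(pd.concat(spot_rows, ignore_index=True), out / "per_spot.csv")
    write_table(kept, out / "fish_spots_filtered.csv")


def _run_cohort_stage(config: dict, out: Path, stage_seeds: dict, manifest: dict) -> None:
    cfg = dict(config.get("cohort", {}))
    gmap = GeneticMap.regular(
        n_groups=int(cfg.pop("map_n_groups", 3)),
        n_markers_per_group=int(cfg.pop("map_n_markers_per_group", 4)),
        spacing_cM=float(cfg.pop("map_spacing_cM", 25.0)),
    )
    if "strains" in cfg:
        cfg["strains"] = tuple(cfg["strains"])
    if "variance_fractions" in cfg:
        cfg["variance_fractions"] = tuple(cfg["variance_fractions"])
    spec = CohortSpec(gmap=gmap, seed=stage_seeds["cohort"], **cfg)
    cohort, ped, geno, truth = simulate_cohort(spec)

    write_table(cohort, out / "cohort.csv")
    write_pedigree(ped, out / "pedigree.csv")
    write_genotypes(geno, out / "genotypes.csv", dialect="dosage")
    write_map(gmap, out / "map.tsv")
    write_table(truth.to_frame(), out / "truth.csv")

    trait = spec.trait_name
    write_table(group_summaries(cohort, "strain", trait), out / "strain_summary.csv")
    shares = strain_family_shares(cohort, trait)
    summary: dict = {
        "trait": trait,
        "variance_shares": {
            "strain": shares.share_strain,
            "family": shares.share_family,
            "residual": shares.share_residual,
        },
        "true_h2": spec.true_h2,
    }

    scan_cfg = config.get("scan", {})
    if scan_cfg.get("enabled", False):
        result = scan_genome(
            cohort, ped, geno, trait=trait,
            step_cM=scan_cfg.get("step_cM", 5.0),
            n_perm=int(scan_cfg.get("n_perm", 200)),
            alpha=float(scan_cfg.get("alpha", 0.05)),
            seed=stage_seeds["scan"],
        )
        write_table(result.table, out / "scan.tsv")
        summary["scan"] = {
            "top_linkage_group": result.top_linkage_group,
            "top_position_cM": result.top_position_cM,
            "top_lrt": result.top_lrt,
            "threshold": result.threshold,
            "alpha": result.alpha,
            "genomewide_p": result.genomewide_p,
            "significant": result.significant,
        }
        if result.null_fit is not None:
            summary["h2_polygenic_model"] = heritability(result.null_fit)
    write_json(summary, out / "summary.json")
    manifest["summary"] = summary
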