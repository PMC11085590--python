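"""End-to-end orchestration: simulate -> fit -> traits -> scan -> CCA.

All randomness derives from a single config seed through named substreams
(one per stage), so reruns with the same config are byte-identical and no
stage touches a global generator.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gravimetrics, io, kinematics, qtlscan, synthdata
from .types import TRAIT_NAMES, VelocityProfileParams

log = logging.getLogger("rootkin")


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible child generator of the global seed."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


@dataclass
class PipelineConfig:
    """Resolved options for a full pipeline run."""

    seed: int = 0
    out_dir: str = "rootkin_run"
    # simulation
    n_rils: int = 160
    n_replicates_per_ril: tuple[int, int] = (7, 10)
    n_markers: int = 234
    chrom_lengths: tuple[float, ...] = synthdata.DEFAULT_CHROM_LENGTHS
    planted_qtl: list[synthdata.PlantedQTL] = field(
        default_factory=lambda: [
            synthdata.PlantedQTL("chr1", 21.5, "vf", 0.5),
            synthdata.PlantedQTL("chr3", 39.7, "k", 0.5),
            synthdata.PlantedQTL("chr5", 76.7, "x0", 0.5),
        ]
    )
    heritability: dict[str, float] = field(
        default_factory=lambda: {p: 0.5 for p in synthdata.BASELINE_PARAMS}
    )
    background_sd: dict[str, float] = field(
        default_factory=lambda: {p: 0.3 for p in synthdata.BASELINE_PARAMS}
    )
    missing_rate: float = 0.03
    velocity_noise_sd: float = 0.02
    points_per_cloud: int = 120
    # kinematics
    zone_fraction: float = 0.2
    # scan
    step_cM: float = 1.0
    error_rate: float = 0.001
    n_perm: int = 1000
    scan_quantile: float = 0.95
    lod_drop: float = 1.5
    # gravitropism
    n_experiments: int = 2
    n_pc: int = 5
    swing_window: int = 5
    cca_n_perm: int = 1000
    cca_quantile: float = 0.95

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "planted_qtl" in raw:
            raw["planted_qtl"] = [
                synthdata.PlantedQTL(
                    str(q["chromosome"]), float(q["position"]),
                    str(q["parameter"]), float(q["effect"]),
                )
                for q in raw["planted_qtl"]
            ]
        for key in ("n_replicates_per_ril", "chrom_lengths"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_qtl"] = [dataclasses.asdict(q) for q in self.planted_qtl]
        return d

    def sim_config(self) -> synthdata.SimulationConfig:
        return synthdata.SimulationConfig(
            n_rils=self.n_rils,
            n_replicates_per_ril=self.n_replicates_per_ril,
            planted_qtl=list(self.planted_qtl),
            heritability=dict(self.heritability),
            background_sd=dict(self.background_sd),
            velocity_noise_sd=self.velocity_noise_sd,
            points_per_cloud=self.points_per_cloud,
            missing_rate=self.missing_rate,
            seed=self.seed,
        )


@dataclass
class PipelineResult:
    """Key objects and tables from a full run."""

    out_dir: Path
    traits: pd.DataFrame
    lod_profile: object
    thresholds: dict[str, float]
    hits: list
    pct_variance: dict[str, float]
    pc_summaries: list
    cca_solutions: list
    correlations: pd.DataFrame


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in dependency order and write all tables.

    The resolved configuration, a log, and every intermediate table land
    in ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.resolved.yaml").write_text(yaml.safe_dump(config.to_dict()))
    seed = config.seed

    # --- simulate -------------------------------------------------------
    log.info("stage simulate: %d RILs, %d markers", config.n_rils, config.n_markers)
    gmap = synthdata.make_genetic_map(
        config.chrom_lengths, config.n_markers, seed=substream(seed, "map")
    )
    genotypes_true = synthdata.simulate_ril_genotypes(
        gmap, config.n_rils, missing_rate=0.0, seed=substream(seed, "genotypes")
    )
    mask_rng = substream(seed, "missing")
    genotypes_obs = genotypes_true.mask(
        mask_rng.random(genotypes_true.shape) < config.missing_rate
    )
    sim = config.sim_config()
    true_params = synthdata.simulate_kinematic_phenotypes(
        genotypes_true, gmap, sim, seed=substream(seed, "phenotypes")
    )
    clouds = synthdata.simulate_replicate_clouds(
        true_params, sim, seed=substream(seed, "clouds")
    )
    io.write_map_csv(gmap, out / "map.csv")
    io.write_genotype_csv(genotypes_obs, out / "genotypes.csv")
    io.write_phenotype_csv(true_params, out / "true_params.csv")

    # --- fit + traits ---------------------------------------------------
    log.info("stage fit: %d clouds", sum(len(v) for v in clouds.values()))
    fit_rows, trait_rows = [], []
    for ril, ril_clouds in clouds.items():
        fits = []
        for c in ril_clouds:
            f = kinematics.fit_velocity_profile(c)
            fits.append(f)
            fit_rows.append(
                {"root_id": c.root_id, "ril": ril, "vf": f.params.vf,
                 "x0": f.params.x0, "k": f.params.k, "n": f.params.n,
                 "rss": f.rss, "converged": f.converged}
            )
        avg, traits = kinematics.traits_from_cloud_fits(
            fits, zone_fraction=config.zone_fraction
        )
        trait_rows.append({"ril": ril, "vf": avg.vf, "x0": avg.x0,
                           "k": avg.k, "n": avg.n, **traits.as_dict()})
    pd.DataFrame(fit_rows).to_csv(out / "fits.csv", index=False)
    trait_table = pd.DataFrame(trait_rows).set_index("ril")
    io.write_phenotype_csv(trait_table, out / "traits.csv")
    kin = trait_table[list(TRAIT_NAMES)]

    # --- scan -----------------------------------------------------------
    log.info("stage scan: step %.3g cM, error rate %g", config.step_cM, config.error_rate)
    cross = qtlscan.build_cross(
        gmap, genotypes_obs, step=config.step_cM, error_rate=config.error_rate
    )
    profile = qtlscan.hk_scan(cross, kin)
    io.write_lod_csv(profile, out / "lod.csv")
    thresholds = {
        t: qtlscan.permutation_threshold(
            cross, kin[t], n_perm=config.n_perm, quantile=config.scan_quantile,
            seed=substream(seed, f"perm:{t}"),
        )
        for t in kin.columns
    }
    hits = qtlscan.find_peaks(profile, cross, kin, thresholds, drop=config.lod_drop)
    pct_var = {}
    for t in kin.columns:
        t_hits = [h for h in hits if h.trait == t]
        pct_var[t] = 100.0 * qtlscan.variance_explained(cross, kin[t], t_hits)
    io.write_peaks_csv(hits, out / "peaks.csv", pct_variance=pct_var)
    (out / "thresholds.json").write_text(json.dumps(thresholds, indent=2))

    # --- gravitropism ---------------------------------------------------
    log.info("stage gravitropism: %d experiments", config.n_experiments)
    curve_sets = synthdata.simulate_tip_angle_curves(
        genotypes_true, n_experiments=config.n_experiments,
        seed=substream(seed, "curves"),
    )
    pc_summaries, cca_solutions = [], []
    corr_tables = []
    for e, curves in enumerate(curve_sets, start=1):
        io.write_curve_csv(curves, out / f"curves_exp{e}.csv")
        pcs = gravimetrics.pca_curves(curves, n_components=config.n_pc)
        pc_summaries.append(pcs)
        score_df = pd.DataFrame(
            pcs.scores, index=curves.index,
            columns=[f"PC{i + 1}" for i in range(config.n_pc)],
        )
        score_df.to_csv(out / f"pc_scores_exp{e}.csv", index_label="ril")
        swing = curves.apply(
            lambda row: gravimetrics.max_swing_rate(row.to_numpy(), config.swing_window),
            axis=1,
        )
        block = kin.join(score_df["PC1"]).assign(max_swing_rate=swing)
        corr = gravimetrics.pearson_matrix(block)
        corr.to_csv(out / f"correlations_exp{e}.csv", index_label="variable")
        corr_tables.append(corr)
        sol = gravimetrics.cca(kin[["regr_max", "elongation_rate",
                                    "regr_max_position", "zone_length"]],
                               score_df)
        sol.permutation_threshold = gravimetrics.cca_permutation_threshold(
            kin[["regr_max", "elongation_rate", "regr_max_position", "zone_length"]],
            score_df, n_perm=config.cca_n_perm, quantile=config.cca_quantile,
            seed=substream(seed, f"cca:{e}"),
        )
        cca_solutions.append(sol)
        report = {
            "experiment": e,
            "correlation": sol.correlation,
            "permutation_threshold": sol.permutation_threshold,
            "x_weights": dict(zip(
                ["regr_max", "elongation_rate", "regr_max_position", "zone_length"],
                map(float, sol.x_weights))),
            "y_weights": {f"PC{i + 1}": float(w) for i, w in enumerate(sol.y_weights)},
            "pc1_variance_share": float(pcs.variance_share[0]),
        }
        (out / f"cca_exp{e}.json").write_text(json.dumps(report, indent=2))

    log.info("pipeline complete: %d significant QTL", len(hits))
    return PipelineResult(
        out_dir=out,
        traits=trait_table,
        lod_profile=profile,
        thresholds=thresholds,
        hits=hits,
        pct_variance=pct_var,
        pc_summaries=pc_summaries,
        cca_solutions=cca_solutions,
        correlations=corr_tables[0] if corr_tables else pd.DataFrame(),
    )
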