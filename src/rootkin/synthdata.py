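"""Synthetic RIL population generator for end-to-end pipeline runs.

Emulates the study design the analysis assumes: ~160 recombinant inbred
lines (RILs) on a 5-chromosome genetic map with ~234 markers, 7-10
replicate velocity point clouds per RIL drawn from the flexible logistic
profile with additive noise, QTL effects planted on the profile
parameters, and two gravitropism tip-angle "experiments" (241 samples at
2-min spacing) that share per-RIL genetic values.

All randomness is driven by explicit seeds / generators; a fixed seed
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import velocity_model
from .qtlscan import haldane_r, ril_selfing_R
from .types import GeneticMap, VelocityPointCloud, VelocityProfileParams

# Arabidopsis-like chromosome lengths in cM (5 chromosomes, ~480 cM total)
DEFAULT_CHROM_LENGTHS = (120.0, 72.0, 92.0, 80.0, 120.0)
DEFAULT_N_MARKERS = 234

# Baseline flexible-logistic parameters and population SD scales, chosen so
# simulated trait ranges match typical Arabidopsis primary roots
# (elongation rate ~0.08-0.32 mm/h, max REGR ~30-60 %/h, peak position
# ~0.25-0.57 mm, zone length ~0.25-0.8 mm).
BASELINE_PARAMS = {"vf": 0.20, "x0": 0.40, "k": 9.0, "n": 1.0}
PARAM_SD = {"vf": 0.040, "x0": 0.050, "k": 1.2, "n": 0.15}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class PlantedQTL:
    """A simulated causal locus acting on one profile parameter."""

    chromosome: str
    position: float  # cM
    parameter: str  # one of vf, x0, k, n
    effect: float  # additive effect, trait-SD units

    def __post_init__(self) -> None:
        if self.parameter not in BASELINE_PARAMS:
            raise ValueError(f"unknown target parameter {self.parameter!r}")
        if not np.isfinite(self.effect):
            raise ValueError("effect must be finite")


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic population."""

    n_rils: int = 160
    n_replicates_per_ril: tuple[int, int] = (7, 10)  # inclusive range
    planted_qtl: list[PlantedQTL] = field(default_factory=list)
    heritability: dict[str, float] = field(
        default_factory=lambda: {p: 0.5 for p in BASELINE_PARAMS}
    )
    baseline: dict[str, float] = field(default_factory=lambda: dict(BASELINE_PARAMS))
    trait_sd: dict[str, float] = field(default_factory=lambda: dict(PARAM_SD))
    background_sd: dict[str, float] = field(
        default_factory=lambda: {p: 0.0 for p in BASELINE_PARAMS}
    )
    velocity_noise_sd: float = 0.02  # mm/h
    points_per_cloud: int = 120
    x_range: tuple[float, float] = (0.0, 1.5)  # mm
    missing_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for p, h2 in self.heritability.items():
            if not (0.0 < h2 <= 1.0):
                raise ValueError(f"heritability[{p}] must be in (0, 1]")
        if self.velocity_noise_sd < 0:
            raise ValueError("velocity_noise_sd must be >= 0")
        if self.n_rils < 2:
            raise ValueError("n_rils must be >= 2")


def make_genetic_map(
    chrom_lengths=DEFAULT_CHROM_LENGTHS,
    n_markers: int = DEFAULT_N_MARKERS,
    seed: int | np.random.Generator | None = None,
) -> GeneticMap:
    """A marker map with markers spread proportionally to chromosome length.

    Marker spacing is even, with optional uniform jitter when a seed is
    given; chromosome ends always carry markers.
    """
    lengths = [float(x) for x in chrom_lengths]
    if not lengths or n_markers < 2 * len(lengths):
        raise ValueError("need at least 2 markers per chromosome")
    rng = _rng(seed) if seed is not None else None
    total = sum(lengths)
    counts = [max(2, int(round(n_markers * L / total))) for L in lengths]
    # adjust to hit n_markers exactly
    while sum(counts) > n_markers:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < n_markers:
        counts[int(np.argmin(counts))] += 1
    chroms = [f"chr{i + 1}" for i in range(len(lengths))]
    positions: dict[str, np.ndarray] = {}
    names: dict[str, list[str]] = {}
    for chrom, L, m in zip(chroms, lengths, counts):
        pos = np.linspace(0.0, L, m)
        if rng is not None and m > 2:
            gap = L / (m - 1)
            pos[1:-1] += rng.uniform(-0.3 * gap, 0.3 * gap, size=m - 2)
            pos = np.sort(pos)
        positions[chrom] = pos
        names[chrom] = [f"{chrom}_m{j + 1}" for j in range(m)]
    return GeneticMap(
        chromosomes=chroms,
        lengths=dict(zip(chroms, lengths)),
        positions=positions,
        marker_names=names,
    )


def simulate_ril_genotypes(
    gmap: GeneticMap,
    n_rils: int,
    missing_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate fixed RIL genotypes as AA/BB mosaics along each chromosome.

    Adjacent markers d cM apart recombine with the RIL-by-selfing fraction
    R = 2r/(1+2r), Haldane r = (1 - exp(-2d/100))/2.  Entries are masked
    to NaN at ``missing_rate``.
    """
    if gmap.n_markers == 0:
        raise ValueError("empty genetic map")
    if n_rils < 1:
        raise ValueError("n_rils must be positive")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = _rng(seed)
    cols: list[np.ndarray] = []
    col_names: list[str] = []
    for chrom in gmap.chromosomes:
        pos = gmap.positions[chrom]
        m = pos.size
        if m == 0:
            continue
        R = ril_selfing_R(haldane_r(np.diff(pos)))
        geno = np.empty((n_rils, m), dtype=np.int8)
        geno[:, 0] = rng.integers(0, 2, size=n_rils)
        flips = rng.random((n_rils, m - 1)) < R[None, :]
        for j in range(1, m):
            geno[:, j] = np.where(flips[:, j - 1], 1 - geno[:, j - 1], geno[:, j - 1])
        cols.append(geno)
        col_names.extend(gmap.marker_names[chrom])
    mat = np.hstack(cols)
    rils = [f"RIL{i + 1:03d}" for i in range(n_rils)]
    df = pd.DataFrame(
        np.where(mat == 0, "AA", "BB"), index=pd.Index(rils, name="ril"),
        columns=col_names,
    )
    if missing_rate > 0:
        mask = rng.random(df.shape) < missing_rate
        df = df.mask(mask)
    return df


def _allele_code(genotypes: pd.DataFrame, marker: str) -> np.ndarray:
    """AA -> -1, BB -> +1, missing -> 0 (mean-coded)."""
    col = genotypes[marker]
    code = np.zeros(len(col))
    code[(col == "AA").to_numpy()] = -1.0
    code[(col == "BB").to_numpy()] = 1.0
    return code


def _nearest_marker(gmap: GeneticMap, chrom: str, position: float) -> str:
    if chrom not in gmap.chromosomes:
        raise ValueError(f"QTL on unknown chromosome {chrom!r}")
    pos = gmap.positions[chrom]
    idx = int(np.argmin(np.abs(pos - position)))
    return gmap.marker_names[chrom][idx]


def simulate_kinematic_phenotypes(
    genotypes: pd.DataFrame,
    gmap: GeneticMap,
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-RIL true velocity-profile parameters with planted QTL effects.

    For each parameter p with SD scale s_p, a planted QTL of effect a adds
    a * s_p * c where c is the +-1 allele code at the nearest marker; the
    residual (polygenic plus environmental) noise is scaled so the QTL
    explain the configured heritability share of the variance in
    expectation.  Optional background_sd adds variation to parameters
    without planted QTL.  Parameters are kept strictly positive by
    resampling offending rows.
    """
    rng = _rng(seed if seed is not None else config.seed)
    n = genotypes.shape[0]
    for q in config.planted_qtl:
        if q.chromosome not in gmap.chromosomes:
            raise ValueError(f"QTL on unknown chromosome {q.chromosome!r}")
        if not (0.0 <= q.position <= gmap.lengths[q.chromosome] + 1e-9):
            raise ValueError(f"QTL position {q.position} off chromosome {q.chromosome}")
    out: dict[str, np.ndarray] = {}
    for p in ("vf", "x0", "k", "n"):
        s = config.trait_sd[p]
        base = config.baseline[p]
        qtl_here = [q for q in config.planted_qtl if q.parameter == p]
        genetic = np.zeros(n)
        var_qtl = 0.0
        for q in qtl_here:
            code = _allele_code(genotypes, _nearest_marker(gmap, q.chromosome, q.position))
            genetic += q.effect * s * code
            var_qtl += (q.effect * s) ** 2
        h2 = config.heritability[p]
        noise_sd = np.sqrt(var_qtl * (1.0 - h2) / h2) if var_qtl > 0 else 0.0
        bg_sd = config.background_sd.get(p, 0.0) * s
        total_noise = np.hypot(noise_sd, bg_sd)
        vals = base + genetic + total_noise * rng.standard_normal(n)
        # positivity by resampling (avoids point masses at a clip boundary)
        for _ in range(100):
            bad = vals <= 0
            if not bad.any():
                break
            vals[bad] = base + genetic[bad] + total_noise * rng.standard_normal(bad.sum())
        else:
            raise RuntimeError(f"could not keep parameter {p} positive")
        out[p] = vals
    return pd.DataFrame(out, index=genotypes.index)


def simulate_velocity_cloud(
    params: VelocityProfileParams,
    points: int = 120,
    noise_sd: float = 0.02,
    x_range: tuple[float, float] = (0.0, 1.5),
    seed: int | np.random.Generator = 0,
) -> VelocityPointCloud:
    """One root trial: positions uniform over x_range, velocities from the
    flexible logistic profile plus i.i.d. Gaussian noise.

    Noisy velocities may be negative; profile fitting must tolerate that.
    """
    if points < 10:
        raise ValueError("points must be >= 10")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng(seed)
    x = np.sort(rng.uniform(x_range[0], x_range[1], size=points))
    v = velocity_model(params, x) + noise_sd * rng.standard_normal(points)
    return VelocityPointCloud(x=x, v=v)


def simulate_replicate_clouds(
    true_params: pd.DataFrame,
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
) -> dict[str, list[VelocityPointCloud]]:
    """7-10 replicate clouds per RIL (count drawn uniformly per line)."""
    rng = _rng(seed if seed is not None else config.seed)
    lo, hi = config.n_replicates_per_ril
    out: dict[str, list[VelocityPointCloud]] = {}
    for ril, row in true_params.iterrows():
        p = VelocityProfileParams(row["vf"], row["x0"], row["k"], row["n"])
        n_rep = int(rng.integers(lo, hi + 1))
        clouds = []
        for rep in range(n_rep):
            c = simulate_velocity_cloud(
                p,
                points=config.points_per_cloud,
                noise_sd=config.velocity_noise_sd,
                x_range=config.x_range,
                seed=rng,
            )
            c.root_id = f"{ril}_rep{rep + 1}"
            c.ril_id = str(ril)
            clouds.append(c)
        out[str(ril)] = clouds
    return out


# --- gravitropism tip-angle curves -------------------------------------------

N_TIMEPOINTS = 241  # every 2 min for 8 h
TIME_H = np.arange(N_TIMEPOINTS) * 2.0 / 60.0

# Saturating family theta(t) = A * (1 - exp(-rate * max(t - lag, 0))):
# monotone nondecreasing, 0 at the start, asymptote A.  Population
# variation is dominated by the rate parameter so that PC1 of the centered
# curves carries most of the variance.
CURVE_BASE = {"lag": 0.5, "rate": 0.55, "asym": 85.0}  # h, 1/h, degrees
CURVE_SD = {"lag": 0.06, "rate": 0.16, "asym": 2.5}
CURVE_H2 = 0.7  # genetic share of curve-parameter variance across experiments
CURVE_NOISE_SD = 1.0  # degrees, AR(1) measurement noise
CURVE_NOISE_AR = 0.8


def tip_angle_family(lag: float, rate: float, asym: float, t_h=TIME_H) -> np.ndarray:
    """Noise-free saturating tip-angle trajectory in degrees."""
    return asym * -np.expm1(-rate * np.clip(t_h - lag, 0.0, None))


def _polygenic_score(genotypes: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """Standardized per-RIL score from random marker effects (shared genetics)."""
    codes = np.column_stack([_allele_code(genotypes, m) for m in genotypes.columns])
    w = rng.standard_normal(codes.shape[1])
    score = codes @ w
    sd = score.std()
    return (score - score.mean()) / sd if sd > 0 else np.zeros(len(score))


def simulate_tip_angle_curves(
    genotypes: pd.DataFrame,
    n_experiments: int = 2,
    seed: int | np.random.Generator = 0,
    noise_sd: float = CURVE_NOISE_SD,
    curve_sd: dict[str, float] | None = None,
    heritability: float = CURVE_H2,
) -> list[pd.DataFrame]:
    """Per-RIL tip-angle curves for repeated gravitropism experiments.

    Each RIL has genetic values for (lag, rate, asymptote) derived from
    polygenic scores over its genotypes; the experiments share those
    values and differ by environmental deviations and autocorrelated
    measurement noise.  Returns one RIL x 241 DataFrame per experiment.
    """
    if n_experiments < 1:
        raise ValueError("n_experiments must be >= 1")
    rng = _rng(seed)
    sds = dict(CURVE_SD if curve_sd is None else curve_sd)
    n = genotypes.shape[0]
    genetic = {p: _polygenic_score(genotypes, rng) for p in CURVE_BASE}
    out = []
    for _e in range(n_experiments):
        curves = np.empty((n, N_TIMEPOINTS))
        for p in CURVE_BASE:
            env = rng.standard_normal(n)
            vals = CURVE_BASE[p] + sds[p] * (
                np.sqrt(heritability) * genetic[p] + np.sqrt(1 - heritability) * env
            )
            genetic[f"_{p}_vals"] = np.clip(vals, 1e-3, None)
        for i in range(n):
            curves[i] = tip_angle_family(
                genetic["_lag_vals"][i], genetic["_rate_vals"][i], genetic["_asym_vals"][i]
            )
        if noise_sd > 0:
            eps = noise_sd * np.sqrt(1 - CURVE_NOISE_AR**2) * rng.standard_normal(
                (n, N_TIMEPOINTS)
            )
            noise = np.empty_like(eps)
            noise[:, 0] = noise_sd * rng.standard_normal(n)
            for j in range(1, N_TIMEPOINTS):
                noise[:, j] = CURVE_NOISE_AR * noise[:, j - 1] + eps[:, j]
            curves += noise
        out.append(
            pd.DataFrame(
                curves,
                index=genotypes.index,
                columns=[f"t{2 * j}" for j in range(N_TIMEPOINTS)],
            )
        )
    return out
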