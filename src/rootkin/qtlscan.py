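"""Single-QTL genome scanning for two-class recombinant inbred lines.

The scan follows the standard interval-mapping workflow for a RIL-by-selfing
cross with two homozygous genotype classes (AA, BB):

1. a pseudomarker grid is laid over the genetic map (default 1 cM);
2. conditional genotype probabilities at every grid position are computed
   by a two-state hidden Markov model, with Haldane map distances converted
   to RIL recombination fractions R = 2r/(1+2r) and a symmetric genotyping
   error rate in the emissions;
3. Haley-Knott regression of phenotype on P(BB) yields a LOD score
   LOD = (N/2) * log10(RSS0/RSS1) at each position;
4. genome-wide significance thresholds come from permuting the phenotype
   vector against the genotype rows; peaks at or above the threshold are
   reported with 1.5-LOD support intervals and additive effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GeneticMap, LODProfile, QTLHit

GENO_CODES = {"AA": 0, "BB": 1}


def haldane_r(d_cm) -> np.ndarray | float:
    """Recombination fraction per meiosis for a map distance in cM (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def ril_selfing_R(r) -> np.ndarray | float:
    """Observed recombination fraction between fixed RIL genotypes: 2r/(1+2r)."""
    r = np.asarray(r, dtype=float)
    return 2.0 * r / (1.0 + 2.0 * r)


def insert_pseudomarkers(gmap: GeneticMap, step: float = 1.0) -> GeneticMap:
    """Add evenly spaced pseudomarkers so no inter-position gap exceeds ``step``.

    Each gap of d cM between adjacent markers is split into ceil(d/step)
    equal subintervals.  All true markers are retained; pseudomarkers get
    deterministic names ``<chrom>.loc<position>``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    positions: dict[str, np.ndarray] = {}
    names: dict[str, list[str]] = {}
    for chrom in gmap.chromosomes:
        pos = gmap.positions[chrom]
        nm = list(gmap.marker_names[chrom])
        if pos.size == 0:
            positions[chrom] = pos.copy()
            names[chrom] = []
            continue
        new_pos = [float(pos[0])]
        new_nm = [nm[0]]
        for i in range(1, pos.size):
            gap = pos[i] - pos[i - 1]
            n_sub = int(np.ceil(gap / step - 1e-9))
            for j in range(1, n_sub):
                p = pos[i - 1] + gap * j / n_sub
                new_pos.append(float(p))
                new_nm.append(f"{chrom}.loc{p:.6g}")
            new_pos.append(float(pos[i]))
            new_nm.append(nm[i])
        positions[chrom] = np.array(new_pos)
        names[chrom] = new_nm
    return GeneticMap(
        chromosomes=list(gmap.chromosomes),
        lengths=dict(gmap.lengths),
        positions=positions,
        marker_names=names,
    )


@dataclass
class RILCross:
    """A RIL population ready for scanning.

    grid_map carries pseudomarkers; genotypes holds observed calls at true
    markers only (RIL x marker, values AA/BB or NaN); genoprobs maps each
    chromosome to an array (n_ril, n_grid_positions, 2) of conditional
    P(AA), P(BB).
    """

    grid_map: GeneticMap
    genotypes: pd.DataFrame
    genoprobs: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def ril_ids(self) -> list[str]:
        return list(self.genotypes.index)

    def prob_bb_matrix(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Concatenate P(BB) across chromosomes.

        Returns (pBB matrix of shape n_ril x n_positions, chromosome label
        array, position array).
        """
        mats, chroms, poss = [], [], []
        for chrom in self.grid_map.chromosomes:
            probs = self.genoprobs[chrom]
            mats.append(probs[:, :, 1])
            chroms.append(np.full(probs.shape[1], chrom, dtype=object))
            poss.append(self.grid_map.positions[chrom])
        return np.hstack(mats), np.concatenate(chroms), np.concatenate(poss)


def _encode_observations(
    genotypes: pd.DataFrame, grid_map: GeneticMap, chrom: str
) -> np.ndarray:
    """Observation codes at every grid position: 0=AA, 1=BB, -1=missing."""
    n_ril = genotypes.shape[0]
    names = grid_map.marker_names[chrom]
    obs = np.full((n_ril, len(names)), -1, dtype=np.int8)
    for j, name in enumerate(names):
        if name in genotypes.columns:
            col = genotypes[name]
            for code_str, code in GENO_CODES.items():
                obs[(col == code_str).to_numpy(), j] = code
    return obs


def genotype_probabilities(
    grid_map: GeneticMap,
    genotypes: pd.DataFrame,
    error_rate: float = 0.001,
) -> dict[str, np.ndarray]:
    """Conditional genotype probabilities by forward-backward HMM.

    States are the two homozygous classes; transitions between adjacent
    grid positions d cM apart use the RIL-by-selfing fraction
    R = 2r/(1+2r) with Haldane r; emissions match the observed call with
    probability 1 - error_rate (cross-class error_rate), and missing
    observations are uninformative.  Rows sum to 1 at every position.
    """
    if not (0.0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")
    for chrom in grid_map.chromosomes:
        pos = grid_map.positions[chrom]
        if pos.size > 1 and np.any(np.diff(pos) <= 0):
            raise ValueError(f"{chrom}: map positions must be strictly increasing")

    out: dict[str, np.ndarray] = {}
    # emission likelihood table: emis[obs+1, state]
    e = error_rate
    emis = np.array([[1.0, 1.0], [1.0 - e, e], [e, 1.0 - e]])
    for chrom in grid_map.chromosomes:
        pos = grid_map.positions[chrom]
        m = pos.size
        obs = _encode_observations(genotypes, grid_map, chrom)
        n_ril = obs.shape[0]
        if m == 0:
            out[chrom] = np.zeros((n_ril, 0, 2))
            continue
        R = ril_selfing_R(haldane_r(np.diff(pos)))
        # transition matrices T[i] between position i and i+1
        like = emis[obs + 1]  # (n_ril, m, 2)
        alpha = np.empty((n_ril, m, 2))
        beta = np.empty((n_ril, m, 2))
        scale = np.empty((n_ril, m))
        alpha[:, 0] = 0.5 * like[:, 0]
        scale[:, 0] = alpha[:, 0].sum(axis=1)
        alpha[:, 0] /= scale[:, 0, None]
        for i in range(m - 1):
            stay, move = 1.0 - R[i], R[i]
            pred = np.empty((n_ril, 2))
            pred[:, 0] = alpha[:, i, 0] * stay + alpha[:, i, 1] * move
            pred[:, 1] = alpha[:, i, 0] * move + alpha[:, i, 1] * stay
            a = pred * like[:, i + 1]
            s = a.sum(axis=1)
            alpha[:, i + 1] = a / s[:, None]
            scale[:, i + 1] = s
        beta[:, m - 1] = 1.0
        for i in range(m - 2, -1, -1):
            stay, move = 1.0 - R[i], R[i]
            b = beta[:, i + 1] * like[:, i + 1]
            beta[:, i, 0] = (b[:, 0] * stay + b[:, 1] * move) / scale[:, i + 1]
            beta[:, i, 1] = (b[:, 0] * move + b[:, 1] * stay) / scale[:, i + 1]
        post = alpha * beta
        post /= post.sum(axis=2, keepdims=True)
        out[chrom] = post
    return out


def build_cross(
    gmap: GeneticMap,
    genotypes: pd.DataFrame,
    step: float = 1.0,
    error_rate: float = 0.001,
) -> RILCross:
    """Insert pseudomarkers and compute genotype probabilities in one go."""
    bad = set()
    for col in genotypes.columns:
        vals = genotypes[col].dropna().unique()
        bad.update(v for v in vals if v not in GENO_CODES)
    if bad:
        raise ValueError(f"unknown genotype codes: {sorted(map(str, bad))}")
    grid = insert_pseudomarkers(gmap, step=step)
    probs = genotype_probabilities(grid, genotypes, error_rate=error_rate)
    return RILCross(grid_map=grid, genotypes=genotypes, genoprobs=probs)


def _lod_from_corr(r2: np.ndarray, n: int) -> np.ndarray:
    r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
    return -(n / 2.0) * np.log10(1.0 - r2)


def _scan_one(pbb: np.ndarray, y: np.ndarray) -> np.ndarray:
    """LOD per column of pbb for a complete phenotype vector y.

    With a single regressor, RSS1 = RSS0 * (1 - r^2) where r is the sample
    correlation, so LOD = -(N/2) log10(1 - r^2).
    """
    n = y.size
    yc = y - y.mean()
    ss_y = yc @ yc
    if ss_y <= 0:
        return np.zeros(pbb.shape[1])
    xc = pbb - pbb.mean(axis=0)
    ss_x = np.einsum("ij,ij->j", xc, xc)
    num = yc @ xc
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_x > 0, num**2 / (ss_x * ss_y), 0.0)
    return _lod_from_corr(r2, n)


def hk_scan(
    cross: RILCross,
    phenotypes: pd.DataFrame,
) -> LODProfile:
    """One-dimensional single-QTL Haley-Knott scan for every trait column.

    At each grid position the phenotype is regressed on [1, P(BB)]; RILs
    with a missing phenotype are dropped trait-wise.
    """
    pbb, chroms, poss = cross.prob_bb_matrix()
    ril_index = pd.Index(cross.ril_ids)
    phenotypes = phenotypes.reindex(ril_index)
    lods: dict[str, np.ndarray] = {}
    n_used: dict[str, int] = {}
    for trait in phenotypes.columns:
        y = phenotypes[trait].to_numpy(dtype=float)
        keep = np.isfinite(y)
        n = int(keep.sum())
        if n == 0:
            raise ValueError(f"trait {trait!r}: all phenotypes missing")
        if n < 4:
            raise ValueError(f"trait {trait!r}: need >= 4 non-missing phenotypes")
        if n < 10:
            import warnings

            warnings.warn(
                f"trait {trait!r}: only {n} non-missing phenotypes; "
                "LOD scores will be unstable",
                stacklevel=2,
            )
        lods[trait] = _scan_one(pbb[keep], y[keep])
        n_used[trait] = n
    return LODProfile(chromosome=chroms, position=poss, lod=lods, n_used=n_used)


def permutation_threshold(
    cross: RILCross,
    phenotype: pd.Series | np.ndarray,
    n_perm: int = 1000,
    quantile: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> float:
    """Genome-wide LOD threshold from phenotype permutations.

    The whole phenotype vector is shuffled against the RIL rows n_perm
    times (preserving genotype linkage structure); the empirical
    ``quantile`` of the genome-wide maximum LOD is returned.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    maxima = permutation_max_lods(cross, phenotype, n_perm, seed)
    return float(np.quantile(maxima, quantile))


def permutation_max_lods(
    cross: RILCross,
    phenotype: pd.Series | np.ndarray,
    n_perm: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Genome-wide max LOD for each phenotype permutation (vectorized)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pbb, _, _ = cross.prob_bb_matrix()
    y = np.asarray(
        phenotype.reindex(cross.ril_ids) if isinstance(phenotype, pd.Series) else phenotype,
        dtype=float,
    )
    keep = np.isfinite(y)
    y = y[keep]
    pbb = pbb[keep]
    n = y.size
    yc = y - y.mean()
    ss_y = yc @ yc
    if ss_y <= 0:
        raise ValueError("zero-variance phenotype")
    xc = pbb - pbb.mean(axis=0)
    ss_x = np.einsum("ij,ij->j", xc, xc)
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    Y = yc[perm_idx]  # (n_perm, n), each row a permuted centered phenotype
    num = Y @ xc  # (n_perm, n_pos)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_x > 0, num**2 / (ss_x * ss_y), 0.0)
    lod = _lod_from_corr(r2, n)
    return lod.max(axis=1)


def _support_interval(
    lod: np.ndarray, pos: np.ndarray, peak_idx: int, drop: float
) -> tuple[float, float]:
    """Contiguous region around the peak with LOD >= peak - drop."""
    cutoff = lod[peak_idx] - drop
    lo = peak_idx
    while lo > 0 and lod[lo - 1] >= cutoff:
        lo -= 1
    hi = peak_idx
    while hi < lod.size - 1 and lod[hi + 1] >= cutoff:
        hi += 1
    return float(pos[lo]), float(pos[hi])


def find_peaks(
    profile: LODProfile,
    cross: RILCross,
    phenotypes: pd.DataFrame,
    threshold: float | dict[str, float],
    drop: float = 1.5,
) -> list[QTLHit]:
    """Significant peaks (LOD >= threshold) with 1.5-LOD support intervals.

    One peak per chromosome per trait (the chromosome-wide maximum; ties
    broken leftmost).  The additive effect is half the difference of the
    fitted genotype-class means at the peak, i.e. half the HK slope on
    P(BB).
    """
    pbb, chroms, poss = cross.prob_bb_matrix()
    ril_index = pd.Index(cross.ril_ids)
    phenotypes = phenotypes.reindex(ril_index)
    hits: list[QTLHit] = []
    for trait in profile.trait_names():
        lod_all = profile.lod[trait]
        thr = threshold[trait] if isinstance(threshold, dict) else threshold
        y_full = phenotypes[trait].to_numpy(dtype=float)
        keep = np.isfinite(y_full)
        for chrom in dict.fromkeys(profile.chromosome):
            mask = profile.chromosome == chrom
            lod = lod_all[mask]
            pos = poss[mask]
            if lod.size == 0:
                continue
            peak_idx = int(np.argmax(lod))
            if lod[peak_idx] < thr:
                continue
            ci_lo, ci_hi = _support_interval(lod, pos, peak_idx, drop)
            x = pbb[keep][:, np.nonzero(mask)[0][peak_idx]]
            y = y_full[keep]
            slope = float(np.polyfit(x, y, 1)[0]) if np.ptp(x) > 0 else 0.0
            hits.append(
                QTLHit(
                    trait=trait,
                    chromosome=str(chrom),
                    position=float(pos[peak_idx]),
                    lod=float(lod[peak_idx]),
                    ci_lo=ci_lo,
                    ci_hi=ci_hi,
                    effect=slope / 2.0,
                )
            )
    return hits


def variance_explained(
    cross: RILCross,
    phenotype: pd.Series | np.ndarray,
    hits: list[QTLHit],
) -> float:
    """R-squared of the joint multiple regression on P(BB) at all hit peaks.

    Duplicate peak positions are dropped with a warning; returns a
    fraction (multiply by 100 for percent).
    """
    if not hits:
        return 0.0
    pbb, chroms, poss = cross.prob_bb_matrix()
    y = np.asarray(
        phenotype.reindex(cross.ril_ids) if isinstance(phenotype, pd.Series) else phenotype,
        dtype=float,
    )
    keep = np.isfinite(y)
    y = y[keep]
    cols = []
    seen: set[tuple[str, float]] = set()
    for h in hits:
        key = (h.chromosome, h.position)
        if key in seen:
            import warnings

            warnings.warn(f"duplicate peak {key} dropped", stacklevel=2)
            continue
        seen.add(key)
        idx = np.nonzero((chroms == h.chromosome) & np.isclose(poss, h.position))[0]
        if idx.size == 0:
            raise ValueError(f"peak {key} not on the scan grid")
        cols.append(pbb[keep][:, idx[0]])
    X = np.column_stack([np.ones(y.size)] + cols)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot <= 0:
        return 0.0
    return float(1.0 - resid @ resid / ss_tot)
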