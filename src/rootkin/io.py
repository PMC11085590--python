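"""CSV table formats for the pipeline.

All tables are comma-separated with header rows and NA for missing values,
following the common qtl-cross file convention (genotypes: first column is
the line ID, remaining columns are markers; map: marker, chromosome,
position) so that real RIL files can be dropped in.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import GeneticMap, LODProfile, QTLHit, VelocityPointCloud

VALID_GENO = {"AA", "BB"}


class FormatError(ValueError):
    """A table failed header or content validation."""


def _check_header(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{what}: missing columns {missing}; found {list(df.columns)}"
        )


# --- genetic map --------------------------------------------------------------

def write_map_csv(gmap: GeneticMap, path: str | Path) -> None:
    rows = gmap.all_markers()
    df = pd.DataFrame(rows, columns=["marker", "chromosome", "position_cM"])
    df.to_csv(path, index=False, float_format="%.6g")


def read_map_csv(path: str | Path) -> GeneticMap:
    df = pd.read_csv(path)
    _check_header(df, ["marker", "chromosome", "position_cM"], "map file")
    chroms = list(dict.fromkeys(df["chromosome"].astype(str)))
    positions: dict[str, np.ndarray] = {}
    names: dict[str, list[str]] = {}
    lengths: dict[str, float] = {}
    for chrom in chroms:
        sub = df[df["chromosome"].astype(str) == chrom]
        pos = sub["position_cM"].to_numpy(dtype=float)
        if np.any(np.diff(pos) <= 0):
            raise FormatError(f"map file: positions not strictly increasing on {chrom}")
        positions[chrom] = pos
        names[chrom] = sub["marker"].astype(str).tolist()
        lengths[chrom] = float(pos[-1])
    return GeneticMap(
        chromosomes=chroms, lengths=lengths, positions=positions, marker_names=names
    )


# --- genotypes ----------------------------------------------------------------

def write_genotype_csv(genotypes: pd.DataFrame, path: str | Path) -> None:
    genotypes.to_csv(path, index=True, index_label="ril", na_rep="NA")


def read_genotype_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA"])
    _check_header(df, ["ril"], "genotype file")
    df = df.set_index("ril")
    bad_cells = []
    for col in df.columns:
        vals = df[col].dropna()
        for ril, v in vals[~vals.isin(VALID_GENO)].items():
            bad_cells.append((ril, col, v))
    if bad_cells:
        shown = ", ".join(f"({r},{c})={v!r}" for r, c, v in bad_cells[:10])
        raise FormatError(f"genotype file: invalid genotype codes at {shown}")
    return df


# --- phenotypes / traits ------------------------------------------------------

def write_phenotype_csv(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, index=True, index_label="ril", na_rep="NA")


def read_phenotype_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA"])
    _check_header(df, ["ril"], "phenotype file")
    return df.set_index("ril").astype(float)


# --- velocity point clouds ----------------------------------------------------

def write_cloud_csv(cloud: VelocityPointCloud, path: str | Path) -> None:
    pd.DataFrame({"x_mm": cloud.x, "v_mm_per_h": cloud.v}).to_csv(path, index=False)


def read_cloud_csv(path: str | Path, root_id: str = "", ril_id: str = "") -> VelocityPointCloud:
    df = pd.read_csv(path)
    _check_header(df, ["x_mm", "v_mm_per_h"], "cloud file")
    return VelocityPointCloud(
        x=df["x_mm"].to_numpy(float),
        v=df["v_mm_per_h"].to_numpy(float),
        root_id=root_id,
        ril_id=ril_id,
    )


# --- tip-angle curves ---------------------------------------------------------

def write_curve_csv(curves: pd.DataFrame, path: str | Path) -> None:
    curves.to_csv(path, index=True, index_label="ril", na_rep="NA")


def read_curve_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA"])
    _check_header(df, ["ril"], "curve file")
    return df.set_index("ril").astype(float)


# --- scan outputs -------------------------------------------------------------

def write_lod_csv(profile: LODProfile, path: str | Path) -> None:
    frames = []
    for trait, lod in profile.lod.items():
        frames.append(
            pd.DataFrame(
                {
                    "chromosome": profile.chromosome,
                    "position_cM": profile.position,
                    "trait": trait,
                    "lod": lod,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_lod_csv(path: str | Path) -> LODProfile:
    df = pd.read_csv(path)
    _check_header(df, ["chromosome", "position_cM", "trait", "lod"], "LOD file")
    traits = list(dict.fromkeys(df["trait"]))
    first = df[df["trait"] == traits[0]]
    return LODProfile(
        chromosome=first["chromosome"].to_numpy(object),
        position=first["position_cM"].to_numpy(float),
        lod={t: df[df["trait"] == t]["lod"].to_numpy(float) for t in traits},
        n_used={t: -1 for t in traits},
    )


PEAKS_COLUMNS = [
    "trait", "chromosome", "position_cM", "lod",
    "ci_lo", "ci_hi", "effect", "pct_variance",
]


def write_peaks_csv(
    hits: list[QTLHit],
    path: str | Path,
    pct_variance: dict[str, float] | None = None,
) -> None:
    """Table-style peak report; positions printed to 1 decimal cM."""
    rows = []
    for h in hits:
        rows.append(
            {
                "trait": h.trait,
                "chromosome": h.chromosome,
                "position_cM": round(h.position, 1),
                "lod": round(h.lod, 2),
                "ci_lo": round(h.ci_lo, 1),
                "ci_hi": round(h.ci_hi, 1),
                "effect": h.effect,
                "pct_variance": (pct_variance or {}).get(h.trait, np.nan),
            }
        )
    pd.DataFrame(rows, columns=PEAKS_COLUMNS).to_csv(path, index=False, na_rep="NA")


def read_peaks_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA"])
    _check_header(df, PEAKS_COLUMNS, "peaks file")
    return df
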