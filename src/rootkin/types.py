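"""Core domain containers shared across the pipeline.

Coordinates and units follow the kinematics convention used throughout:
``x`` is distance from the root tip (quiescent center) in millimetres,
increasing shootward; velocities are mm/h; REGR is reported as % per hour;
genetic map positions are centimorgans (cM); tip angles are degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


@dataclass(frozen=True)
class VelocityProfileParams:
    """Parameters of the flexible logistic velocity profile.

    v(x) = vf * [1 + exp(-k (x - x0))]^(-1/n)

    Attributes
    ----------
    vf : float
        Plateau (final) velocity in mm/h; the root elongation rate.
    x0 : float
        Location parameter in mm from the tip.
    k : float
        Steepness in 1/mm.
    n : float
        Asymmetry shape parameter (unitless); n = 1 recovers the
        symmetric logistic.
    """

    vf: float
    x0: float
    k: float
    n: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.vf) and self.vf > 0):
            raise ValueError(f"vf must be finite and > 0, got {self.vf}")
        if not (np.isfinite(self.k) and self.k > 0):
            raise ValueError(f"k must be finite and > 0, got {self.k}")
        if not (np.isfinite(self.n) and self.n > 0):
            raise ValueError(f"n must be finite and > 0, got {self.n}")
        if not np.isfinite(self.x0):
            raise ValueError(f"x0 must be finite, got {self.x0}")

    def as_array(self) -> np.ndarray:
        return np.array([self.vf, self.x0, self.k, self.n])


@dataclass
class VelocityPointCloud:
    """(position, velocity) observations from one root trial."""

    x: np.ndarray  # mm from tip
    v: np.ndarray  # mm/h
    root_id: str = ""
    ril_id: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.x.shape != self.v.shape or self.x.ndim != 1:
            raise ValueError("x and v must be 1-D arrays of equal length")
        if np.any(self.x < 0):
            raise ValueError("positions must be >= 0 (distance from tip)")

    def __len__(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class KinematicTraits:
    """The four elongation-zone traits derived from a velocity profile."""

    elongation_rate: float  # mm/h
    regr_max: float  # % per h
    regr_max_position: float  # mm from tip
    zone_length: float  # mm

    def __post_init__(self) -> None:
        for name in ("elongation_rate", "regr_max", "regr_max_position", "zone_length"):
            val = getattr(self, name)
            if not (np.isfinite(val) and val > 0):
                raise ValueError(f"{name} must be finite and > 0, got {val}")

    def as_dict(self) -> dict[str, float]:
        return {
            "elongation_rate": self.elongation_rate,
            "regr_max": self.regr_max,
            "regr_max_position": self.regr_max_position,
            "zone_length": self.zone_length,
        }


TRAIT_NAMES = ("elongation_rate", "regr_max", "regr_max_position", "zone_length")
PARAM_NAMES = ("vf", "x0", "k", "n")


@dataclass
class GeneticMap:
    """Ordered marker positions on a set of chromosomes.

    ``positions[chrom]`` maps to an increasing float array of cM positions,
    ``marker_names[chrom]`` to the matching marker name list.
    """

    chromosomes: list[str]
    lengths: dict[str, float]  # cM
    positions: dict[str, np.ndarray]
    marker_names: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for chrom in self.chromosomes:
            pos = np.asarray(self.positions[chrom], dtype=float)
            self.positions[chrom] = pos
            names = self.marker_names[chrom]
            if pos.size != len(names):
                raise ValueError(f"{chrom}: positions and names differ in length")
            if pos.size and (np.any(np.diff(pos) <= 0)):
                raise ValueError(f"{chrom}: marker positions must be strictly increasing")
            if pos.size and (pos[0] < 0 or pos[-1] > self.lengths[chrom] + 1e-9):
                raise ValueError(f"{chrom}: marker positions outside [0, length]")
            dup = seen.intersection(names)
            if dup:
                raise ValueError(f"duplicate marker names: {sorted(dup)}")
            seen.update(names)

    @property
    def n_markers(self) -> int:
        return sum(len(v) for v in self.marker_names.values())

    def all_markers(self) -> list[tuple[str, str, float]]:
        """(marker, chromosome, position) triples in map order."""
        out = []
        for chrom in self.chromosomes:
            for name, pos in zip(self.marker_names[chrom], self.positions[chrom]):
                out.append((name, chrom, float(pos)))
        return out


@dataclass
class LODProfile:
    """Genome-scan output: LOD score per grid position per trait."""

    chromosome: np.ndarray  # str array, one entry per grid position
    position: np.ndarray  # cM
    lod: dict[str, np.ndarray]  # trait -> LOD per position
    n_used: dict[str, int]  # trait -> RILs with non-missing phenotype

    def trait_names(self) -> list[str]:
        return list(self.lod)


@dataclass(frozen=True)
class QTLHit:
    """A significant peak from a single-QTL genome scan."""

    trait: str
    chromosome: str
    position: float  # cM
    lod: float
    ci_lo: float  # 1.5-LOD support interval, cM
    ci_hi: float
    effect: float  # additive effect, phenotype units

    def __post_init__(self) -> None:
        if not (self.ci_lo <= self.position <= self.ci_hi):
            raise ValueError("support interval must contain the peak")


@dataclass
class TipAngleCurve:
    """A gravitropism time course: tip angle sampled every 2 min for 8 h."""

    ril_id: str
    angles: np.ndarray  # degrees, length 241

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 1:
            raise ValueError("angles must be 1-D")
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("angles must be finite")


@dataclass
class PCSummary:
    """PCA of a curve matrix: per-RIL scores and variance shares."""

    scores: np.ndarray  # RIL x component
    variance_share: np.ndarray  # per component, fractions summing to 1
    mean_curve: np.ndarray  # the centering vector
    components: np.ndarray  # component x time loading matrix


@dataclass
class CCASolution:
    """First canonical pair between kinematic traits and PC scores."""

    x_weights: np.ndarray
    y_weights: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    correlation: float
    permutation_threshold: float | None = None
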