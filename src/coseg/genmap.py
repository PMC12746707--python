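"""Genetic maps and the Haldane mapping function.

A genetic map anchors physical coordinates (bp) to cumulative genetic
positions (cM) per chromosome; positions between anchors are obtained by
linear interpolation.  The Haldane mapping function converts a genetic
distance ``d`` (cM) into a recombination fraction

    r = (1/2) * (1 - exp(-2 d / 100)),    r in [0, 0.5),

which is the per-meiosis probability of an odd number of crossovers between
two loci under the no-interference (Poisson crossover) model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Locus",
    "GeneticMap",
    "load_genetic_map",
    "interpolate_cm",
    "locus_cm_position",
    "haldane_r",
    "haldane_inverse",
]


@dataclass(frozen=True)
class Locus:
    """A named genomic interval, 1-based inclusive coordinates."""

    name: str
    chromosome: str
    start_bp: int
    end_bp: int
    cm_position: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start_bp < 1:
            raise ValueError(f"locus {self.name}: start_bp must be >= 1")
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"locus {self.name}: start_bp {self.start_bp} > end_bp {self.end_bp}"
            )

    @property
    def midpoint_bp(self) -> int:
        """Representative physical point of the locus (integer midpoint)."""
        return (self.start_bp + self.end_bp) // 2


@dataclass(frozen=True)
class GeneticMap:
    """Per-chromosome bp -> cM anchor tables.

    Invariants enforced on construction: anchors strictly increasing in bp,
    cM non-decreasing in bp, at least two anchors per chromosome.
    """

    anchors: Dict[str, tuple] = field(default_factory=dict)  # chrom -> (bp, cM) arrays

    def __post_init__(self) -> None:
        for chrom, (bp, cm) in self.anchors.items():
            bp = np.asarray(bp, dtype=np.int64)
            cm = np.asarray(cm, dtype=float)
            if bp.size < 2:
                raise ValueError(f"chromosome {chrom}: at least 2 anchors required")
            if bp.size != cm.size:
                raise ValueError(f"chromosome {chrom}: bp/cM length mismatch")
            if np.any(np.diff(bp) <= 0):
                bad = int(np.argmax(np.diff(bp) <= 0))
                raise ValueError(
                    f"chromosome {chrom}: bp anchors not strictly increasing "
                    f"at rows {bad}-{bad + 1} (bp {bp[bad]}, {bp[bad + 1]})"
                )
            if np.any(np.diff(cm) < 0):
                bad = int(np.argmax(np.diff(cm) < 0))
                raise ValueError(
                    f"chromosome {chrom}: cM not non-decreasing at rows "
                    f"{bad}-{bad + 1} (cM {cm[bad]}, {cm[bad + 1]})"
                )
            if np.any(bp < 1) or np.any(cm < 0):
                raise ValueError(f"chromosome {chrom}: bp must be >=1 and cM >=0")
            self.anchors[chrom] = (bp, cm)

    @property
    def chromosomes(self) -> list:
        return list(self.anchors)

    def interpolate(self, chromosome: str, bp: Union[int, float]) -> float:
        return interpolate_cm(self, chromosome, bp)

    def span_cm(self, chromosome: str) -> tuple:
        """(min, max) genetic position covered by the anchors."""
        _, cm = self.anchors[chromosome]
        return float(cm[0]), float(cm[-1])


def load_genetic_map(source: Union[str, pd.DataFrame]) -> GeneticMap:
    """Load a genetic map from a TSV (columns ``chrom  bp  cM``) or DataFrame.

    Rows may be in any order; they are sorted by (chrom, bp) before the
    GeneticMap invariants are checked, so an out-of-order file loads to the
    same map as a pre-sorted one.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t")
    required = {"chrom", "bp", "cM"}
    if not required.issubset(df.columns):
        raise ValueError(f"genetic map needs columns {sorted(required)}, got {list(df.columns)}")
    df = df.sort_values(["chrom", "bp"], kind="stable")
    anchors = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        anchors[str(chrom)] = (
            grp["bp"].to_numpy(dtype=np.int64),
            grp["cM"].to_numpy(dtype=float),
        )
    return GeneticMap(anchors)


def interpolate_cm(genetic_map: GeneticMap, chromosome: str, bp: Union[int, float]) -> float:
    """Genetic position (cM) of ``bp`` by linear interpolation between anchors.

    Positions outside the anchored range are clamped to the terminal anchor's
    cM value (with a logged warning): extrapolating a local recombination
    rate beyond the map routinely produces absurd distances.
    """
    if chromosome not in genetic_map.anchors:
        raise KeyError(f"chromosome {chromosome!r} not in genetic map")
    bp_arr, cm_arr = genetic_map.anchors[chromosome]
    if bp < bp_arr[0] or bp > bp_arr[-1]:
        log.warning(
            "bp %s outside map range [%d, %d] on %s; clamping to terminal anchor",
            bp, bp_arr[0], bp_arr[-1], chromosome,
        )
    return float(np.interp(bp, bp_arr, cm_arr))


def locus_cm_position(genetic_map: GeneticMap, locus: Locus) -> float:
    """cM position of a locus, interpolated at its physical midpoint."""
    return interpolate_cm(genetic_map, locus.chromosome, locus.midpoint_bp)


def haldane_r(d_cm: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """Haldane recombination fraction for a genetic distance in cM."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(d_cm) else r


def haldane_inverse(r: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """Genetic distance (cM) whose Haldane recombination fraction is ``r``.

    Defined for r in [0, 0.5); d = -50 * ln(1 - 2r).
    """
    rr = np.asarray(r, dtype=float)
    if np.any(rr < 0) or np.any(rr >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = -50.0 * np.log1p(-2.0 * rr)
    return float(d) if np.isscalar(r) else d
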