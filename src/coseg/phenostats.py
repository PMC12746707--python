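"""Zebrafish larval phenotype classification, tallies, and group comparisons.

Each injected larva is scored at 5 dpf on a fixed feature panel (swim
bladder inflation, tail curvature, jaw morphology, cardiac edema,
cleft-like facial defects, body-axis integrity) and classified as

* strong  — two or more severe features (cardiac edema, severe
  bidirectional tail malformation, severe jaw malformation, cleft-like
  defect, severe axis defect);
* medium  — at least one moderate abnormality (non-inflated or partially
  inflated swim bladder, mild tail curvature, jaw protrusion or mild
  asymmetry) or exactly one severe feature;
* normal  — otherwise.

Group tallies report counts and half-up percentages to one decimal;
distributions are compared with Pearson's chi-square (no continuity
correction by default) and ceratohyal-angle distributions with the
Kruskal-Wallis rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PhenotypeRecord",
    "PhenotypeTally",
    "ChiSquareResult",
    "KruskalResult",
    "SWIM_BLADDER_LEVELS",
    "TAIL_LEVELS",
    "JAW_LEVELS",
    "CLASSES",
    "classify_larva",
    "tally",
    "compare_tallies",
    "compare_angles",
    "load_records",
    "load_angles",
]

SWIM_BLADDER_LEVELS = ("inflated", "partial", "absent")
TAIL_LEVELS = ("none", "mild_ventral", "mild_dorsal", "severe_bidirectional")
JAW_LEVELS = ("normal", "protrusion_or_mild_asymmetry", "severe_malformation")
CLASSES = ("normal", "medium", "strong")


@dataclass(frozen=True)
class PhenotypeRecord:
    larva_id: str
    group: str
    swim_bladder: str
    tail_curvature: str
    jaw: str
    cardiac_edema: bool
    cleft_like_defect: bool
    severe_axis_defect: bool

    def __post_init__(self) -> None:
        if self.swim_bladder not in SWIM_BLADDER_LEVELS:
            raise ValueError(f"swim_bladder must be one of {SWIM_BLADDER_LEVELS}")
        if self.tail_curvature not in TAIL_LEVELS:
            raise ValueError(f"tail_curvature must be one of {TAIL_LEVELS}")
        if self.jaw not in JAW_LEVELS:
            raise ValueError(f"jaw must be one of {JAW_LEVELS}")


@dataclass(frozen=True)
class PhenotypeTally:
    group: str
    n: int
    counts: Dict[str, int]
    percentages: Dict[str, float]
    total_abnormal_pct: float


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p_value: float
    dof: int
    warning: Optional[str] = None


@dataclass(frozen=True)
class KruskalResult:
    statistic: float
    p_value: float
    n_groups: int


def _round_pct(value: float) -> float:
    """Half-up rounding to one decimal place, matching printed-table style."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def classify_larva(record: PhenotypeRecord) -> str:
    """Deterministic severity class of one larva; see module docstring."""
    n_severe = sum(
        (
            record.cardiac_edema,
            record.tail_curvature == "severe_bidirectional",
            record.jaw == "severe_malformation",
            record.cleft_like_defect,
            record.severe_axis_defect,
        )
    )
    n_moderate = sum(
        (
            record.swim_bladder in ("partial", "absent"),
            record.tail_curvature in ("mild_ventral", "mild_dorsal"),
            record.jaw == "protrusion_or_mild_asymmetry",
        )
    )
    if n_severe >= 2:
        return "strong"
    if n_moderate >= 1 or n_severe == 1:
        return "medium"
    return "normal"


def tally(records: Iterable[PhenotypeRecord], group: str) -> PhenotypeTally:
    """Class counts and percentages for one experimental group."""
    classes = [classify_larva(r) for r in records if r.group == group]
    if not classes:
        raise ValueError(f"no records for group {group!r}")
    n = len(classes)
    counts = {c: classes.count(c) for c in CLASSES}
    percentages = {c: _round_pct(100.0 * counts[c] / n) for c in CLASSES}
    abnormal = counts["medium"] + counts["strong"]
    return PhenotypeTally(
        group=group,
        n=n,
        counts=counts,
        percentages=percentages,
        total_abnormal_pct=_round_pct(100.0 * abnormal / n),
    )


def compare_tallies(
    tally_a: PhenotypeTally,
    tally_b: PhenotypeTally,
    categories: Sequence[str] = CLASSES,
    yates: bool = False,
) -> ChiSquareResult:
    """Pearson chi-square on the two groups' category counts.

    Categories with zero count in both groups are dropped (they contribute
    no information and break the expected-count computation); an expected
    cell below 1 yields a warning annotation, not an error.
    """
    table = np.array(
        [
            [tally_a.counts.get(c, 0) for c in categories],
            [tally_b.counts.get(c, 0) for c in categories],
        ]
    )
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        raise ValueError("need at least two non-empty categories to compare")
    stat, p, dof, expected = sps.chi2_contingency(table, correction=yates)
    warning = "expected cell count < 1" if np.any(expected < 1) else None
    return ChiSquareResult(float(stat), float(p), int(dof), warning)


def compare_angles(groups: Dict[str, Sequence[float]]) -> KruskalResult:
    """Kruskal-Wallis H (tie-corrected) across angle measurement groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = []
    for name, values in groups.items():
        values = np.asarray(list(values), dtype=float)
        if values.size < 2:
            raise ValueError(f"group {name!r} needs at least 2 measurements")
        if np.any((values <= 0) | (values >= 180)):
            raise ValueError(f"group {name!r}: angles must lie in (0, 180) degrees")
        arrays.append(values)
    stat, p = sps.kruskal(*arrays)
    return KruskalResult(float(stat), float(p), len(groups))


def load_records(source) -> List[PhenotypeRecord]:
    """Load larva records from TSV with one row per larva."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    records = []
    for row in df.itertuples():
        records.append(
            PhenotypeRecord(
                larva_id=str(row.larva_id),
                group=str(row.group),
                swim_bladder=str(row.swim_bladder),
                tail_curvature=str(row.tail_curvature),
                jaw=str(row.jaw),
                cardiac_edema=bool(row.cardiac_edema),
                cleft_like_defect=bool(row.cleft_like_defect),
                severe_axis_defect=bool(row.severe_axis_defect),
            )
        )
    return records


def load_angles(source) -> Dict[str, List[float]]:
    """Load `group  angle_deg` TSV into a group -> measurements mapping."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    out: Dict[str, List[float]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.group), []).append(float(row.angle_deg))
    return out
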