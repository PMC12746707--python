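"""Population allele frequencies and ACMG/AMP variant classification.

Frequencies are exact rationals AC/AN reported to three significant
figures; the rarity tiers follow the conventional thresholds (very rare
AF < 1e-4; rare 1e-4..1e-3; common AF > 1e-3).  The classifier combines
pathogenicity-side ACMG/AMP evidence codes (PVS/PS/PM/PP) with the
published Richards-2015 combining rules; anything that does not reach
Likely Pathogenic is a VUS.  Benign-side codes are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "PopulationFrequencyRecord",
    "ACMGEvidence",
    "Classification",
    "allele_frequency",
    "format_af",
    "frequency_tier",
    "acmg_combine",
    "zero_homozygote_flag",
    "load_frequency_table",
]


class Classification(str, Enum):
    PATHOGENIC = "Pathogenic"
    LIKELY_PATHOGENIC = "Likely Pathogenic"
    VUS = "VUS"
    LIKELY_BENIGN = "Likely Benign"
    BENIGN = "Benign"


_STRENGTH_PREFIXES = ("PVS", "PS", "PM", "PP")


@dataclass(frozen=True)
class PopulationFrequencyRecord:
    variant: str
    population: str
    ac: int
    an: int
    n_homozygotes: int = 0

    def __post_init__(self) -> None:
        if self.an <= 0:
            raise ValueError(f"{self.variant}/{self.population}: AN must be > 0")
        if not 0 <= self.ac <= self.an:
            raise ValueError(f"{self.variant}/{self.population}: need 0 <= AC <= AN")
        if not 0 <= self.n_homozygotes <= self.ac // 2:
            raise ValueError(
                f"{self.variant}/{self.population}: homozygotes must be <= floor(AC/2)"
            )

    @property
    def af(self) -> Fraction:
        return allele_frequency(self.ac, self.an)


@dataclass(frozen=True)
class ACMGEvidence:
    """A set of pathogenicity-side criterion codes (e.g. PM1, PP3)."""

    codes: frozenset

    @classmethod
    def from_codes(cls, codes: Union[str, Iterable[str]]) -> "ACMGEvidence":
        if isinstance(codes, str):
            codes = [c for c in codes.split(",") if c.strip()]
        return cls(frozenset(c.strip().upper() for c in codes))

    def strength_counts(self) -> Dict[str, int]:
        counts = {p: 0 for p in _STRENGTH_PREFIXES}
        for code in self.codes:
            for prefix in _STRENGTH_PREFIXES:  # PVS before PS, PM before PP order matters
                if code.startswith(prefix):
                    counts[prefix] += 1
                    break
            else:
                raise ValueError(
                    f"unknown ACMG code {code!r}; expected prefix in {_STRENGTH_PREFIXES}"
                )
        return counts


def allele_frequency(ac: int, an: int) -> Fraction:
    """Exact allele frequency AC/AN as a rational number."""
    if an <= 0:
        raise ValueError("AN must be > 0")
    if not 0 <= ac <= an:
        raise ValueError("need 0 <= AC <= AN")
    return Fraction(ac, an)


def format_af(af: Union[Fraction, float]) -> str:
    """Three-significant-figure scientific notation, e.g. '4.23e-05'."""
    return f"{float(af):.2e}"


def frequency_tier(af: Union[Fraction, float]) -> str:
    """Rarity tier: 'very rare' (<1e-4), 'rare' (1e-4..1e-3, closed), 'common' (>1e-3)."""
    value = float(af)
    if not 0 <= value <= 1:
        raise ValueError("allele frequency must lie in [0, 1]")
    if value < 1e-4:
        return "very rare"
    if value <= 1e-3:
        return "rare"
    return "common"


def acmg_combine(evidence: ACMGEvidence) -> Classification:
    """Combine pathogenicity-side evidence into a final class.

    Pathogenic: 1 PVS + (>=1 PS | >=2 PM | 1 PM + 1 PP | >=2 PP); or >=2 PS;
    or 1 PS + (>=3 PM | 2 PM + >=2 PP | 1 PM + >=4 PP).
    Likely Pathogenic: 1 PVS + 1 PM; 1 PS + 1-2 PM; 1 PS + >=2 PP; >=3 PM;
    2 PM + >=2 PP; 1 PM + >=4 PP.  Anything weaker is a VUS.  All rules are
    implemented with >= thresholds so adding evidence never weakens the call.
    """
    counts = evidence.strength_counts()
    pvs, ps, pm, pp = counts["PVS"], counts["PS"], counts["PM"], counts["PP"]

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps >= 1 and (pm >= 3 or (pm >= 2 and pp >= 2) or (pm >= 1 and pp >= 4)))
    )
    if pathogenic:
        return Classification.PATHOGENIC

    likely = (
        (pvs >= 1 and pm >= 1)
        or (ps >= 1 and pm >= 1)
        or (ps >= 1 and pp >= 2)
        or pm >= 3
        or (pm >= 2 and pp >= 2)
        or (pm >= 1 and pp >= 4)
    )
    if likely:
        return Classification.LIKELY_PATHOGENIC
    return Classification.VUS


def zero_homozygote_flag(records: Sequence[PopulationFrequencyRecord]) -> bool:
    """True iff the homozygote count is zero in every population record."""
    records = list(records)
    if not records:
        raise ValueError("no population records: homozygote summary undefined")
    return all(rec.n_homozygotes == 0 for rec in records)


def load_frequency_table(source: Union[str, pd.DataFrame]) -> List[PopulationFrequencyRecord]:
    """Load `variant  population  AC  AN  nhomalt` records from a TSV or DataFrame."""
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep="\t")
    required = {"variant", "population", "AC", "AN", "nhomalt"}
    if not required.issubset(df.columns):
        raise ValueError(f"frequency table needs columns {sorted(required)}")
    return [
        PopulationFrequencyRecord(
            variant=str(row.variant),
            population=str(row.population),
            ac=int(row.AC),
            an=int(row.AN),
            n_homozygotes=int(row.nhomalt),
        )
        for row in df.itertuples()
    ]
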