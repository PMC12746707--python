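"""Exact probability of a two-locus haplotype segregation pattern.

In a nuclear family with ``n`` children and a designated transmitting
parent, consider two linked loci A and B at genetic distance ``d`` cM and a
labeled bipartition of the children: a subset C expected to carry parental
haplotype 1 at both loci and its complement C' expected to carry haplotype
2.  Each meiosis transmits haplotype 1 or 2 at locus A with probability
1/2; the child's allele at locus B matches locus A unless a recombination
occurred (probability r from the Haldane function).  The probability that a
given child matches its assigned haplotype at both loci is therefore
(1 - r)/2, and, meioses being independent,

    P(pattern) = ((1 - r) / 2) ** n.

The probability depends only on n, not on how the children are split
between C and C' (every child must match its own label).  A Monte-Carlo
meiosis simulator is provided as an independent oracle for the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Optional, Sequence, Tuple

import numpy as np

from .genmap import GeneticMap, Locus, haldane_r, locus_cm_position

__all__ = [
    "SegregationConfig",
    "PatternProbability",
    "MeiosisEstimate",
    "per_child_no_recomb_prob",
    "pattern_probability",
    "simulate_meioses",
]


@dataclass(frozen=True)
class SegregationConfig:
    """A two-locus segregation pattern in one nuclear family.

    ``children`` are arbitrary labels; ``subset_c`` (size k) is the set of
    children expected to carry haplotype 1 at both loci, the rest haplotype 2.
    """

    d_cm: float
    children: Tuple[str, ...]
    subset_c: FrozenSet[str]
    transmitting_parent: str = "father"

    def __post_init__(self) -> None:
        if len(self.children) < 1:
            raise ValueError("at least one child is required (no meioses to constrain)")
        if len(set(self.children)) != len(self.children):
            raise ValueError("duplicate child labels")
        if not set(self.subset_c) <= set(self.children):
            raise ValueError("subset_c must be a subset of the children")
        if not np.isfinite(self.d_cm) or self.d_cm < 0:
            raise ValueError("d_cm must be finite and non-negative")

    @property
    def n_children(self) -> int:
        return len(self.children)

    @classmethod
    def from_cm_positions(
        cls,
        cm_a: float,
        cm_b: float,
        n_children: Optional[int] = None,
        subset_c: Optional[Sequence[str]] = None,
        children: Optional[Sequence[str]] = None,
        transmitting_parent: str = "father",
    ) -> "SegregationConfig":
        """Build a config from two precomputed cM positions.

        If ``children`` is omitted, labels child1..childN are generated; if
        ``subset_c`` is omitted, the first half of the children is used (the
        probability does not depend on the choice).
        """
        if children is None:
            if n_children is None:
                raise ValueError("give either children labels or n_children")
            children = tuple(f"child{i + 1}" for i in range(n_children))
        children = tuple(children)
        if subset_c is None:
            subset_c = children[: len(children) // 2]
        return cls(
            d_cm=abs(float(cm_b) - float(cm_a)),
            children=children,
            subset_c=frozenset(subset_c),
            transmitting_parent=transmitting_parent,
        )

    @classmethod
    def from_loci(
        cls,
        genetic_map: GeneticMap,
        locus_a: Locus,
        locus_b: Locus,
        **kwargs,
    ) -> "SegregationConfig":
        """Build a config from physical loci via a genetic map (midpoints)."""
        cm_a = locus_cm_position(genetic_map, locus_a)
        cm_b = locus_cm_position(genetic_map, locus_b)
        return cls.from_cm_positions(cm_a, cm_b, **kwargs)


@dataclass(frozen=True)
class PatternProbability:
    r: float
    per_child_prob: float
    total_prob: float
    n_children: int

    @property
    def percent(self) -> float:
        return 100.0 * self.total_prob


@dataclass(frozen=True)
class MeiosisEstimate:
    estimate: float
    se: float
    n_sim: int
    n_matches: int


def per_child_no_recomb_prob(r: float) -> float:
    """Probability that one child matches its assigned haplotype at both loci.

    (1 - r)/2: a coin flip on which parental haplotype is transmitted at
    locus A, times the no-recombination probability 1 - r between A and B.
    Symmetric in the expected haplotype (1 or 2).
    """
    if not 0 <= r < 0.5:
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    return (1.0 - r) / 2.0


def pattern_probability(config: SegregationConfig) -> PatternProbability:
    """Exact probability of the labeled segregation pattern."""
    r = haldane_r(config.d_cm)
    p_child = per_child_no_recomb_prob(r)
    return PatternProbability(
        r=r,
        per_child_prob=p_child,
        total_prob=p_child ** config.n_children,
        n_children=config.n_children,
    )


def simulate_meioses(config: SegregationConfig, n_sim: int, seed: int) -> MeiosisEstimate:
    """Monte-Carlo estimate of the pattern probability.

    For each simulated family, every child's transmitted haplotype at locus
    A is drawn uniformly from {1, 2}; the haplotype at locus B equals the
    one at A unless a crossover occurred (Bernoulli(r), no interference).
    The estimate is the fraction of families in which every child matches
    its assigned haplotype at both loci; the standard error is binomial.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    r = haldane_r(config.d_cm)
    rng = np.random.default_rng(seed)
    n = config.n_children
    expected = np.array(
        [1 if c in config.subset_c else 2 for c in config.children], dtype=np.int8
    )
    hap_a = rng.integers(1, 3, size=(n_sim, n), dtype=np.int8)
    crossover = rng.random(size=(n_sim, n)) < r
    hap_b = np.where(crossover, 3 - hap_a, hap_a)
    match = np.all((hap_a == expected) & (hap_b == expected), axis=1)
    n_matches = int(match.sum())
    p_hat = n_matches / n_sim
    se = float(np.sqrt(p_hat * (1.0 - p_hat) / n_sim))
    return MeiosisEstimate(estimate=p_hat, se=se, n_sim=n_sim, n_matches=n_matches)
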