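"""Pairwise identity-by-descent segment detection from a family multi-sample VCF.

The detector works on biallelic SNVs that survive stringent per-sample
filters (read depth > 14, genotype quality > 30, Mendelian consistency,
heterozygous allelic balance within bounds).  For a pair of full siblings it
resolves, where the four genotypes allow it, which allele each sibling
inherited from each heterozygous parent, and calls a per-site IBD state:

* both parental transmissions resolved  -> IBD0 / IBD1 / IBD2 ("definite")
* one resolved and shared               -> IBD1 (at least one allele shared)
* one resolved and not shared           -> ambiguous (the other parent is
  unobservable at that site, so the site neither supports nor breaks)

IBD regions — intervals where at least one allele is inherited identically
by descent — are maximal runs of IBD1/IBD2 sites, broken by IBD0 evidence
or by physical gaps; short runs are discarded.  The run state is labeled
IBD2 only when the definite sites inside it say so (majority vote).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, TextIO, Tuple, Union

log = logging.getLogger(__name__)

Genotype = Tuple[int, int]

__all__ = [
    "Individual",
    "Pedigree",
    "VariantSite",
    "SiteIBDState",
    "IBDSegment",
    "VcfReadStats",
    "FilterResult",
    "read_multisample_vcf",
    "site_passes_filters",
    "informative_sites",
    "pairwise_ibd_states",
    "segments_from_states",
    "detect_ibd_segments",
    "write_segments_bed",
    "mendelian_consistent",
]


# ---------------------------------------------------------------------------
# Pedigree


@dataclass(frozen=True)
class Individual:
    iid: str
    father: Optional[str] = None
    mother: Optional[str] = None
    sex: Optional[int] = None
    affected: bool = False


class Pedigree:
    """A validated set of individuals with optional parent links."""

    def __init__(self, individuals: Iterable[Individual]):
        self._members: Dict[str, Individual] = {}
        for ind in individuals:
            if ind.iid in self._members:
                raise ValueError(f"duplicate individual {ind.iid!r}")
            self._members[ind.iid] = ind
        for ind in self._members.values():
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in self._members:
                    raise ValueError(
                        f"{ind.iid!r} links to parent {parent!r} not in pedigree"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        for start in self._members:
            seen = set()
            stack = [start]
            while stack:
                iid = stack.pop()
                ind = self._members[iid]
                for parent in (ind.father, ind.mother):
                    if parent is None:
                        continue
                    if parent == start:
                        raise ValueError(f"{start!r} is its own ancestor")
                    if parent not in seen:
                        seen.add(parent)
                        stack.append(parent)

    @classmethod
    def from_ped(cls, path: str) -> "Pedigree":
        """Read a 6-column PED file (FID IID PAT MAT SEX PHENO); '0' = absent."""
        individuals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < 6:
                    raise ValueError(f"PED line has {len(fields)} fields, need 6: {line!r}")
                _, iid, pat, mat, sex, pheno = fields[:6]
                individuals.append(
                    Individual(
                        iid=iid,
                        father=None if pat == "0" else pat,
                        mother=None if mat == "0" else mat,
                        sex=None if sex == "0" else int(sex),
                        affected=(pheno == "2"),
                    )
                )
        return cls(individuals)

    @property
    def members(self) -> List[Individual]:
        return list(self._members.values())

    @property
    def ids(self) -> List[str]:
        return list(self._members)

    def __contains__(self, iid: str) -> bool:
        return iid in self._members

    def __getitem__(self, iid: str) -> Individual:
        return self._members[iid]

    def parents_of(self, iid: str) -> Tuple[Optional[str], Optional[str]]:
        ind = self._members[iid]
        return ind.father, ind.mother

    def are_full_sibs(self, a: str, b: str) -> bool:
        fa, ma = self.parents_of(a)
        fb, mb = self.parents_of(b)
        return fa is not None and ma is not None and (fa, ma) == (fb, mb)


# ---------------------------------------------------------------------------
# Sites


@dataclass
class VariantSite:
    """One biallelic SNV record with per-sample calls."""

    chromosome: str
    position: int
    ref: str
    alt: str
    genotypes: Dict[str, Optional[Genotype]]
    depth: Dict[str, int]
    quality: Dict[str, float]
    allele_depths: Dict[str, Tuple[int, int]]  # (ref_count, alt_count)


@dataclass
class VcfReadStats:
    n_sites: int = 0
    skipped_multiallelic: int = 0
    skipped_non_snv: int = 0
    skipped_missing_format: int = 0


def read_multisample_vcf(
    path: str, sample_ids: Sequence[str]
) -> Tuple[List[VariantSite], VcfReadStats]:
    """Read biallelic SNVs for the requested samples from a VCF 4.x file.

    Multiallelic and non-SNV records are skipped and counted, as are records
    lacking a usable GT/DP/GQ/AD FORMAT value for any requested sample with
    a called genotype.  A requested sample absent from the header is fatal.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    absent = [s for s in sample_ids if s not in vcf.samples]
    if absent:
        raise ValueError(f"samples {absent} not present in {path}")
    idx = {s: vcf.samples.index(s) for s in sample_ids}

    stats = VcfReadStats()
    sites: List[VariantSite] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            stats.skipped_multiallelic += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            stats.skipped_non_snv += 1
            continue
        ad = rec.format("AD")
        dp = rec.format("DP")
        gq = rec.format("GQ")
        if ad is None or dp is None or gq is None:
            stats.skipped_missing_format += 1
            continue
        genotypes: Dict[str, Optional[Genotype]] = {}
        depth: Dict[str, int] = {}
        quality: Dict[str, float] = {}
        allele_depths: Dict[str, Tuple[int, int]] = {}
        usable = True
        for s in sample_ids:
            i = idx[s]
            a0, a1 = rec.genotypes[i][0], rec.genotypes[i][1]
            if a0 < 0 or a1 < 0:
                genotypes[s] = None
                depth[s] = 0
                quality[s] = 0.0
                allele_depths[s] = (0, 0)
                continue
            if dp[i][0] < 0 or gq[i][0] < 0 or ad[i][0] < 0 or ad[i][1] < 0:
                usable = False
                break
            genotypes[s] = (int(min(a0, a1)), int(max(a0, a1)))
            depth[s] = int(dp[i][0])
            quality[s] = float(gq[i][0])
            allele_depths[s] = (int(ad[i][0]), int(ad[i][1]))
        if not usable:
            stats.skipped_missing_format += 1
            continue
        stats.n_sites += 1
        sites.append(
            VariantSite(
                chromosome=rec.CHROM,
                position=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                genotypes=genotypes,
                depth=depth,
                quality=quality,
                allele_depths=allele_depths,
            )
        )
    if stats.skipped_multiallelic or stats.skipped_non_snv or stats.skipped_missing_format:
        log.info(
            "VCF read: kept %d sites; skipped %d multiallelic, %d non-SNV, %d missing-FORMAT",
            stats.n_sites,
            stats.skipped_multiallelic,
            stats.skipped_non_snv,
            stats.skipped_missing_format,
        )
    return sites, stats


# ---------------------------------------------------------------------------
# Filters


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reason: Optional[str] = None

    def __bool__(self) -> bool:
        return self.passed


def mendelian_consistent(
    child: Genotype, father: Optional[Genotype], mother: Optional[Genotype]
) -> bool:
    """True if the child genotype can arise from the parental genotypes.

    With both parents: some (paternal, maternal) allele assignment must
    reproduce the child's genotype.  With one parent the check degrades to
    allele sharing; with none it is vacuously true.
    """
    if father is not None and mother is not None:
        child_sorted = tuple(sorted(child))
        return any(
            tuple(sorted((a, b))) == child_sorted for a in set(father) for b in set(mother)
        )
    for parent in (father, mother):
        if parent is not None and not set(child) & set(parent):
            return False
    return True


def site_passes_filters(
    site: VariantSite,
    pedigree: Pedigree,
    *,
    min_dp: int = 15,
    min_gq: int = 31,
    het_ab_range: Tuple[float, float] = (0.25, 0.75),
) -> FilterResult:
    """Apply the per-sample site filters; returns pass/fail with a reason.

    Every pedigree member must have a called genotype with DP >= ``min_dp``
    (the default 15 encodes the strict "depth > 14") and GQ >= ``min_gq``
    (">30"); every trio must be Mendelian-consistent; every heterozygote's
    alt-allele fraction must lie within ``het_ab_range``.
    """
    for ind in pedigree.members:
        if site.genotypes.get(ind.iid) is None:
            return FilterResult(False, "missing")
    for ind in pedigree.members:
        if site.depth.get(ind.iid, 0) < min_dp:
            return FilterResult(False, "depth")
    for ind in pedigree.members:
        if site.quality.get(ind.iid, 0) < min_gq:
            return FilterResult(False, "quality")
    for ind in pedigree.members:
        if ind.father is None and ind.mother is None:
            continue
        father_gt = site.genotypes.get(ind.father) if ind.father else None
        mother_gt = site.genotypes.get(ind.mother) if ind.mother else None
        if not mendelian_consistent(site.genotypes[ind.iid], father_gt, mother_gt):
            return FilterResult(False, "mendelian")
    for ind in pedigree.members:
        gt = site.genotypes[ind.iid]
        if gt[0] != gt[1]:
            ref_n, alt_n = site.allele_depths.get(ind.iid, (0, 0))
            total = ref_n + alt_n
            if total == 0:
                return FilterResult(False, "allelic_balance")
            frac = alt_n / total
            if not het_ab_range[0] <= frac <= het_ab_range[1]:
                return FilterResult(False, "allelic_balance")
    return FilterResult(True, None)


# ---------------------------------------------------------------------------
# Transmission resolution and per-site IBD states


def _transmission_assignments(
    child: Genotype, father: Genotype, mother: Genotype
) -> Set[Tuple[int, int]]:
    """All (paternal, maternal) allele assignments consistent with the trio."""
    child_sorted = tuple(sorted(child))
    return {
        (a, b)
        for a in set(father)
        for b in set(mother)
        if tuple(sorted((a, b))) == child_sorted
    }


def _resolve_transmitted(
    child: Genotype, father: Genotype, mother: Genotype
) -> Tuple[Optional[int], Optional[int]]:
    """Uniquely resolved (paternal, maternal) transmitted alleles, else None."""
    assignments = _transmission_assignments(child, father, mother)
    if not assignments:
        return None, None
    pats = {a for a, _ in assignments}
    mats = {b for _, b in assignments}
    return (
        pats.pop() if len(pats) == 1 else None,
        mats.pop() if len(mats) == 1 else None,
    )


def _pair_parent_sharing(
    site: VariantSite, pair: Tuple[str, str], pedigree: Pedigree
) -> Tuple[Optional[bool], Optional[bool]]:
    """(paternal_shared, maternal_shared) for a full-sib pair; None = unresolved.

    A parent contributes only when heterozygous and both siblings' alleles
    from that parent are uniquely resolvable from the four genotypes.
    """
    s1, s2 = pair
    father, mother = pedigree.parents_of(s1)
    f_gt = site.genotypes.get(father)
    m_gt = site.genotypes.get(mother)
    g1 = site.genotypes.get(s1)
    g2 = site.genotypes.get(s2)
    if f_gt is None or m_gt is None or g1 is None or g2 is None:
        return None, None
    p1, m1 = _resolve_transmitted(g1, f_gt, m_gt)
    p2, m2 = _resolve_transmitted(g2, f_gt, m_gt)
    pat = (p1 == p2) if (f_gt[0] != f_gt[1] and p1 is not None and p2 is not None) else None
    mat = (m1 == m2) if (m_gt[0] != m_gt[1] and m1 is not None and m2 is not None) else None
    return pat, mat


def _check_sib_pair(pair: Tuple[str, str], pedigree: Pedigree) -> None:
    a, b = pair
    for iid in pair:
        if iid not in pedigree:
            raise ValueError(f"individual {iid!r} not in pedigree")
    if not pedigree.are_full_sibs(a, b):
        raise ValueError(
            f"pair ({a}, {b}) are not full siblings with both parents in the "
            "pedigree; segment detection is defined for full-sib pairs"
        )


def informative_sites(
    sites: Iterable[VariantSite],
    pair: Tuple[str, str],
    pedigree: Pedigree,
    *,
    ad_tiebreak: bool = False,
) -> List[VariantSite]:
    """Sites at which parental transmission to the pair is discriminating.

    Retains sites where at least one parent is heterozygous and both
    siblings' transmitted alleles from that parent are uniquely resolvable.
    With ``ad_tiebreak`` the double-heterozygous configurations (both
    parents and both sibs het, transmission ambiguous) are also retained so
    the allele-depth heuristic can weigh in downstream.
    """
    _check_sib_pair(pair, pedigree)
    kept = []
    for site in sites:
        pat, mat = _pair_parent_sharing(site, pair, pedigree)
        if pat is not None or mat is not None:
            kept.append(site)
        elif ad_tiebreak and _is_double_het_ambiguous(site, pair, pedigree):
            kept.append(site)
    return kept


def _is_double_het_ambiguous(
    site: VariantSite, pair: Tuple[str, str], pedigree: Pedigree
) -> bool:
    father, mother = pedigree.parents_of(pair[0])
    gts = [site.genotypes.get(i) for i in (father, mother, *pair)]
    return all(g is not None and g[0] != g[1] for g in gts)


@dataclass(frozen=True)
class SiteIBDState:
    chromosome: str
    position: int
    state: str  # 'IBD0' | 'IBD1' | 'IBD2' | 'ambiguous'
    definite: bool  # True when both parental transmissions were resolved


def pairwise_ibd_states(
    sites: Iterable[VariantSite],
    pair: Tuple[str, str],
    pedigree: Pedigree,
    *,
    ad_tiebreak: bool = False,
    ad_tolerance: float = 0.1,
) -> List[SiteIBDState]:
    """Per-site IBD state for a full-sib pair (sites should be pre-filtered).

    The optional allele-depth tie-break (off by default, heuristic): at
    fully ambiguous double-het sites, two het siblings with similar
    alt-allele fractions (|difference| <= ``ad_tolerance``) are taken as
    weak evidence of sharing (non-definite IBD1).
    """
    _check_sib_pair(pair, pedigree)
    states: List[SiteIBDState] = []
    for site in sites:
        pat, mat = _pair_parent_sharing(site, pair, pedigree)
        known = [v for v in (pat, mat) if v is not None]
        if len(known) == 2:
            state = f"IBD{int(pat) + int(mat)}"
            definite = True
        elif len(known) == 1:
            state = "IBD1" if known[0] else "ambiguous"
            definite = False
        else:
            state = "ambiguous"
            definite = False
            if ad_tiebreak and _is_double_het_ambiguous(site, pair, pedigree):
                fracs = []
                for s in pair:
                    ref_n, alt_n = site.allele_depths.get(s, (0, 0))
                    total = ref_n + alt_n
                    if total == 0:
                        break
                    fracs.append(alt_n / total)
                if len(fracs) == 2 and abs(fracs[0] - fracs[1]) <= ad_tolerance:
                    state = "IBD1"
        states.append(
            SiteIBDState(site.chromosome, site.position, state, definite)
        )
    return states


# ---------------------------------------------------------------------------
# Segments


@dataclass(frozen=True)
class IBDSegment:
    pair: Tuple[str, str]
    chromosome: str
    start_bp: int  # 1-based inclusive
    end_bp: int
    state: str  # 'IBD1' | 'IBD2'
    n_supporting_sites: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("segment start_bp > end_bp")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def segments_from_states(
    per_site_states: Sequence[SiteIBDState],
    min_sites: int = 5,
    max_gap_bp: int = 1_000_000,
    pair: Tuple[str, str] = ("A", "B"),
) -> List[IBDSegment]:
    """Collapse per-site states into IBD segments.

    Maximal runs of supporting sites (state IBD1 or IBD2) are closed by IBD0
    evidence, a chromosome change, or a gap between consecutive supporting
    sites larger than ``max_gap_bp``; ambiguous sites are transparent (they
    neither support nor break).  Runs with fewer than ``min_sites``
    supporting sites are discarded.  Segment coordinates span the first to
    last supporting site; the segment state is IBD2 when the definite sites
    in the run are majority-IBD2, else IBD1.
    """
    segments: List[IBDSegment] = []
    run: List[SiteIBDState] = []

    def flush() -> None:
        if len(run) >= min_sites:
            definite = [s.state for s in run if s.definite]
            n_ibd2 = sum(1 for s in definite if s == "IBD2")
            state = "IBD2" if definite and n_ibd2 * 2 > len(definite) else "IBD1"
            segments.append(
                IBDSegment(
                    pair=pair,
                    chromosome=run[0].chromosome,
                    start_bp=run[0].position,
                    end_bp=run[-1].position,
                    state=state,
                    n_supporting_sites=len(run),
                )
            )
        run.clear()

    for st in per_site_states:
        if st.state == "ambiguous":
            continue
        if st.state == "IBD0":
            flush()
            continue
        if run and (
            st.chromosome != run[-1].chromosome
            or st.position - run[-1].position > max_gap_bp
        ):
            flush()
        run.append(st)
    flush()
    return segments


def detect_ibd_segments(
    sites: Iterable[VariantSite],
    pair: Tuple[str, str],
    pedigree: Pedigree,
    *,
    min_dp: int = 15,
    min_gq: int = 31,
    het_ab_range: Tuple[float, float] = (0.25, 0.75),
    min_sites: int = 5,
    max_gap_bp: int = 1_000_000,
    ad_tiebreak: bool = False,
) -> List[IBDSegment]:
    """Full pipeline: filter sites, keep informative ones, call states, segment."""
    passed = [
        s
        for s in sites
        if site_passes_filters(
            s, pedigree, min_dp=min_dp, min_gq=min_gq, het_ab_range=het_ab_range
        )
    ]
    informative = informative_sites(passed, pair, pedigree, ad_tiebreak=ad_tiebreak)
    states = pairwise_ibd_states(informative, pair, pedigree, ad_tiebreak=ad_tiebreak)
    return segments_from_states(
        states, min_sites=min_sites, max_gap_bp=max_gap_bp, pair=pair
    )


def write_segments_bed(segments: Iterable[IBDSegment], dest: Union[str, TextIO]) -> None:
    """Write segments as BED-like TSV (0-based half-open in the file)."""
    own = isinstance(dest, str)
    fh = open(dest, "w") if own else dest
    try:
        fh.write("chrom\tstart0\tend\tpair\tstate\tn_sites\n")
        for seg in segments:
            fh.write(
                f"{seg.chromosome}\t{seg.start_bp - 1}\t{seg.end_bp}\t"
                f"{seg.pair[0]},{seg.pair[1]}\t{seg.state}\t{seg.n_supporting_sites}\n"
            )
    finally:
        if own:
            fh.close()
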