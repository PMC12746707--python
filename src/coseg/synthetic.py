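"""Synthetic inputs with the statistical structure the analyses assume.

Generators (all pure functions of their configuration and an integer seed):

* a nuclear-family meiosis simulator with Poisson crossovers on the cM
  scale (no interference, Haldane-consistent), phased haplotypes, and a
  read-depth / genotype-quality / allele-depth noise model feeding the IBD
  detector — including a VCF 4.2 writer;
* weighted background networks with a planted functionally proximal module
  containing a pair of seed genes, feeding the randomization null;
* per-larva phenotype feature tables with group-specific class
  probabilities (defaults are the integer count tables consistent with the
  published injection-experiment percentages), feeding the tally
  statistics; feature combinations are rejection-sampled against the
  classifier, keeping the generator and the classifier decoupled;
* per-group ceratohyal-angle distributions (Gaussian truncated to
  (0, 180) degrees), n = 20 larvae per group across seven conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .ibd import Individual, Pedigree, VariantSite
from .phenostats import (
    JAW_LEVELS,
    PhenotypeRecord,
    SWIM_BLADDER_LEVELS,
    TAIL_LEVELS,
    classify_larva,
)

log = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulatedFamily",
    "nuclear_pedigree",
    "simulate_family",
    "draw_meioses",
    "true_ibd_states",
    "family_variant_sites",
    "write_family_vcf",
    "write_ped",
    "simulate_network",
    "simulate_phenotype_records",
    "simulate_angles",
    "DEFAULT_GROUP_COUNTS",
    "DEFAULT_ANGLE_PARAMS",
]


# ---------------------------------------------------------------------------
# Family / meiosis simulator


@dataclass(frozen=True)
class SimulationConfig:
    """Site grid, founder frequencies, and the sequencing noise model.

    The default grid is one 100-Mbp chromosome at a uniform 1 cM/Mb with
    5000 evenly spaced biallelic sites and founder alternate-allele
    frequency 0.5 (maximally informative markers).  Depth is Poisson with
    ``mean_depth``; heterozygous allele depths are binomial around balance
    0.5; GQ is a monotone function of depth (and of allelic balance for
    heterozygotes).  ``noiseless`` fixes DP=60, GQ=99 and exact allele
    depths — the regime in which genotypes are error-free and no site fails
    the depth/quality filters.
    """

    n_sites: int = 5000
    chromosome: str = "chr1"
    start_bp: int = 1_000_000
    end_bp: int = 100_000_000
    cm_per_mb: float = 1.0
    founder_alt_freq: float = 0.5
    mean_depth: float = 30.0
    genotype_error_rate: float = 0.0
    noiseless: bool = False

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("site grid must be non-empty")
        if self.start_bp >= self.end_bp:
            raise ValueError("start_bp must be < end_bp")
        if not 0 < self.founder_alt_freq < 1:
            raise ValueError("founder allele frequency must be in (0, 1)")
        if self.mean_depth <= 0 or self.cm_per_mb < 0:
            raise ValueError("rates must be positive")

    @property
    def positions_bp(self) -> np.ndarray:
        return np.linspace(self.start_bp, self.end_bp, self.n_sites).astype(np.int64)

    @property
    def positions_cm(self) -> np.ndarray:
        return self.positions_bp * self.cm_per_mb / 1e6

    @property
    def length_cm(self) -> float:
        cm = self.positions_cm
        return float(cm[-1] - cm[0])


def nuclear_pedigree(n_children: int = 2, affected: Sequence[str] = ()) -> Pedigree:
    """father + mother + child1..childN, children linked to both parents."""
    individuals = [Individual("father"), Individual("mother")]
    for i in range(n_children):
        iid = f"child{i + 1}"
        individuals.append(
            Individual(iid, father="father", mother="mother", affected=iid in affected)
        )
    return Pedigree(individuals)


@dataclass
class SimulatedFamily:
    """Phased haplotypes and crossover positions for one simulated family.

    ``haplotypes[iid]`` is a (2, n_sites) int8 array; for children row 0 is
    the paternal and row 1 the maternal haplotype.  ``sources[(child,
    role)]`` records which of the parent's two haplotypes each site was
    copied from; ``crossovers[(child, role)]`` the crossover positions (cM).
    """

    config: SimulationConfig
    pedigree: Pedigree
    positions_bp: np.ndarray
    positions_cm: np.ndarray
    haplotypes: Dict[str, np.ndarray]
    sources: Dict[Tuple[str, str], np.ndarray]
    crossovers: Dict[Tuple[str, str], np.ndarray]
    seed: int

    def genotypes(self, iid: str) -> np.ndarray:
        """(2, n_sites) allele array (unphased content, phased storage)."""
        return self.haplotypes[iid]


def _draw_meiosis(
    rng: np.random.Generator, cm: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """One meiosis: crossover count ~ Poisson(map length in Morgans),
    positions uniform on the cM scale, start haplotype fair.  Returns
    (source index per site, crossover positions)."""
    length_morgan = (cm[-1] - cm[0]) / 100.0
    n_x = rng.poisson(length_morgan)
    xpos = np.sort(rng.uniform(cm[0], cm[-1], size=n_x))
    start = int(rng.integers(2))
    source = (start + np.searchsorted(xpos, cm, side="right")) % 2
    return source.astype(np.int8), xpos


def draw_meioses(cm: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """n independent meioses over the cM grid; (n, n_sites) source indices."""
    return np.stack([_draw_meiosis(rng, cm)[0] for _ in range(n)])


def simulate_family(
    config: SimulationConfig, pedigree: Optional[Pedigree] = None, seed: int = 0
) -> SimulatedFamily:
    """Simulate founder haplotypes and meioses through a nuclear pedigree.

    Founder haplotypes are drawn i.i.d. from the founder allele frequency;
    each child haplotype is a crossover mosaic of the corresponding
    parent's two haplotypes.  Deterministic given (config, pedigree, seed).
    """
    if pedigree is None:
        pedigree = nuclear_pedigree(2)
    rng = np.random.default_rng(seed)
    cm = config.positions_cm
    n_sites = config.n_sites

    haplotypes: Dict[str, np.ndarray] = {}
    sources: Dict[Tuple[str, str], np.ndarray] = {}
    crossovers: Dict[Tuple[str, str], np.ndarray] = {}

    founders = [ind for ind in pedigree.members if ind.father is None and ind.mother is None]
    children = [ind for ind in pedigree.members if ind.father or ind.mother]
    for ind in founders:
        haplotypes[ind.iid] = (
            rng.random((2, n_sites)) < config.founder_alt_freq
        ).astype(np.int8)
    for ind in children:
        if ind.father is None or ind.mother is None:
            raise ValueError(f"{ind.iid}: children must have both parents")
        rows = []
        for role, parent in (("paternal", ind.father), ("maternal", ind.mother)):
            if parent not in haplotypes:
                raise ValueError("pedigrees deeper than one nuclear family are not supported")
            source, xpos = _draw_meiosis(rng, cm)
            rows.append(haplotypes[parent][source, np.arange(n_sites)])
            sources[(ind.iid, role)] = source
            crossovers[(ind.iid, role)] = xpos
        haplotypes[ind.iid] = np.stack(rows)

    return SimulatedFamily(
        config=config,
        pedigree=pedigree,
        positions_bp=config.positions_bp,
        positions_cm=cm,
        haplotypes=haplotypes,
        sources=sources,
        crossovers=crossovers,
        seed=seed,
    )


def true_ibd_states(family: SimulatedFamily, pair: Tuple[str, str]) -> np.ndarray:
    """Ground-truth per-site IBD state (0/1/2) for a full-sib pair."""
    s1, s2 = pair
    pat = family.sources[(s1, "paternal")] == family.sources[(s2, "paternal")]
    mat = family.sources[(s1, "maternal")] == family.sources[(s2, "maternal")]
    return pat.astype(np.int8) + mat.astype(np.int8)


def _gq_from_depth(dp: np.ndarray, het: np.ndarray, ab: np.ndarray) -> np.ndarray:
    """Monotone genotype-quality model: grows with depth, shrinks with
    heterozygous allelic imbalance; capped at 99."""
    gq = 3.0 * dp
    gq = np.where(het, gq * (1.0 - 2.0 * np.abs(ab - 0.5)), gq)
    return np.clip(np.rint(gq), 0, 99).astype(np.int64)


def family_variant_sites(
    family: SimulatedFamily, noise_seed: int = 0
) -> List[VariantSite]:
    """Render the family's genotypes as VariantSite records with noise.

    DP ~ Poisson(mean_depth); alt allele depth ~ Binomial(DP, true alt
    fraction); GQ from the monotone model; optional genotype flips at
    ``genotype_error_rate``.  The noiseless preset emits DP=60, GQ=99 and
    exact allele depths.  Deterministic given (family, noise_seed).
    """
    config = family.config
    rng = np.random.default_rng(noise_seed)
    sample_ids = [ind.iid for ind in family.pedigree.members]
    n_sites = config.n_sites

    gt = {s: family.haplotypes[s].copy() for s in sample_ids}
    if config.genotype_error_rate > 0 and not config.noiseless:
        for s in sample_ids:
            flips = rng.random((2, n_sites)) < config.genotype_error_rate
            gt[s] = np.where(flips, 1 - gt[s], gt[s]).astype(np.int8)

    depth: Dict[str, np.ndarray] = {}
    alt_depth: Dict[str, np.ndarray] = {}
    gq: Dict[str, np.ndarray] = {}
    for s in sample_ids:
        alt_frac = gt[s].mean(axis=0)  # 0, 0.5 or 1
        het = gt[s][0] != gt[s][1]
        if config.noiseless:
            dp = np.full(n_sites, 60, dtype=np.int64)
            alt = np.rint(dp * alt_frac).astype(np.int64)
            quality = np.full(n_sites, 99, dtype=np.int64)
        else:
            dp = rng.poisson(config.mean_depth, size=n_sites)
            alt = rng.binomial(dp, alt_frac)
            ab = np.divide(alt, dp, out=np.full(n_sites, 0.5), where=dp > 0)
            quality = _gq_from_depth(dp, het, ab)
        depth[s] = dp
        alt_depth[s] = alt
        gq[s] = quality

    sites: List[VariantSite] = []
    for i in range(n_sites):
        sites.append(
            VariantSite(
                chromosome=config.chromosome,
                position=int(family.positions_bp[i]),
                ref="A",
                alt="G",
                genotypes={
                    s: (int(min(gt[s][:, i])), int(max(gt[s][:, i]))) for s in sample_ids
                },
                depth={s: int(depth[s][i]) for s in sample_ids},
                quality={s: float(gq[s][i]) for s in sample_ids},
                allele_depths={
                    s: (int(depth[s][i] - alt_depth[s][i]), int(alt_depth[s][i]))
                    for s in sample_ids
                },
            )
        )
    return sites


def write_family_vcf(family: SimulatedFamily, path: str, noise_seed: int = 0) -> None:
    """Write the simulated family as a plain-text VCF 4.2 with GT:AD:DP:GQ."""
    sites = family_variant_sites(family, noise_seed=noise_seed)
    sample_ids = [ind.iid for ind in family.pedigree.members]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            f"##contig=<ID={family.config.chromosome},length={family.config.end_bp + 1}>\n"
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for site in sites:
            cols = [
                site.chromosome,
                str(site.position),
                ".",
                site.ref,
                site.alt,
                ".",
                "PASS",
                ".",
                "GT:AD:DP:GQ",
            ]
            for s in sample_ids:
                g = site.genotypes[s]
                ref_n, alt_n = site.allele_depths[s]
                cols.append(
                    f"{g[0]}/{g[1]}:{ref_n},{alt_n}:{site.depth[s]}:{int(site.quality[s])}"
                )
            fh.write("\t".join(cols) + "\n")


def write_ped(pedigree: Pedigree, path: str, family_id: str = "FAM1") -> None:
    """Write a 6-column PED file."""
    with open(path, "w") as fh:
        for ind in pedigree.members:
            fh.write(
                f"{family_id}\t{ind.iid}\t{ind.father or 0}\t{ind.mother or 0}\t"
                f"{ind.sex or 0}\t{2 if ind.affected else 1}\n"
            )


# ---------------------------------------------------------------------------
# Networks


def simulate_network(
    n_nodes: int = 200,
    mean_degree: float = 4.0,
    planted_module_size: int = 8,
    seed_pair_labels: Tuple[str, str] = ("EHHADH", "MASP1"),
    seed: int = 0,
    module_weight: float = 20.0,
    background_weight: float = 1.0,
) -> Tuple[nx.Graph, Dict[str, bool]]:
    """Background random network with a planted functionally proximal module.

    An Erdos-Renyi background (edge weights ~ U(0.5, 1.5) x background
    scale) carries a planted clique of ``planted_module_size`` nodes —
    including both seed genes — whose weights are an order of magnitude
    stronger (~U(0.8, 1.2) x module scale).  Disconnected components are
    tied to the giant component with unit-weight edges (logged).  Returns
    the graph and truth labels marking module membership.
    """
    if planted_module_size < 2:
        raise ValueError("planted module must contain at least the two seed genes")
    if planted_module_size > n_nodes:
        raise ValueError("planted module larger than the network")
    rng = np.random.default_rng(seed)
    p_edge = min(1.0, mean_degree / max(n_nodes - 1, 1))
    graph = nx.gnp_random_graph(n_nodes, p_edge, seed=int(rng.integers(2**31)))
    names = {i: f"G{i:04d}" for i in range(n_nodes)}
    module_nodes = list(rng.choice(n_nodes, size=planted_module_size, replace=False))
    names[module_nodes[0]] = seed_pair_labels[0]
    names[module_nodes[1]] = seed_pair_labels[1]
    graph = nx.relabel_nodes(graph, names)
    module = [names[i] for i in module_nodes]

    for a, b in graph.edges:
        graph[a][b]["weight"] = float(background_weight * rng.uniform(0.5, 1.5))
    for i, a in enumerate(module):
        for b in module[i + 1 :]:
            graph.add_edge(a, b, weight=float(module_weight * rng.uniform(0.8, 1.2)))

    components = sorted(nx.connected_components(graph), key=len, reverse=True)
    if len(components) > 1:
        log.info("connecting %d stray component(s) to the giant component", len(components) - 1)
        anchor = next(iter(components[0]))
        for comp in components[1:]:
            graph.add_edge(anchor, next(iter(comp)), weight=float(background_weight))

    labels = {node: node in set(module) for node in graph.nodes}
    return graph, labels


# ---------------------------------------------------------------------------
# Phenotypes

# Integer class counts (normal, medium, strong) consistent with the printed
# group sizes and percentages of the injection experiments.
DEFAULT_GROUP_COUNTS: Dict[str, Tuple[int, int, int]] = {
    "GFP": (92, 1, 0),
    "EHHADH-WT": (105, 14, 8),
    "EHHADH-MT": (68, 18, 8),
    "MASP1-WT": (104, 20, 11),
    "MASP1-MT": (106, 28, 12),
    "COMBO-WT": (118, 20, 12),
    "COMBO-MT": (100, 39, 13),
}

_MODERATE_CHOICES = {
    "swim_bladder": ("partial", "absent"),
    "tail_curvature": ("mild_ventral", "mild_dorsal"),
    "jaw": ("protrusion_or_mild_asymmetry",),
}


def _normal_features() -> Dict[str, object]:
    return dict(
        swim_bladder="inflated",
        tail_curvature="none",
        jaw="normal",
        cardiac_edema=False,
        cleft_like_defect=False,
        severe_axis_defect=False,
    )


def _propose_features(cls: str, rng: np.random.Generator) -> Dict[str, object]:
    feats = _normal_features()
    if cls == "normal":
        return feats
    if cls == "medium":
        n_abn = int(rng.integers(1, 4))
        fields = list(rng.choice(list(_MODERATE_CHOICES), size=n_abn, replace=False))
        for name in fields:
            feats[name] = str(rng.choice(_MODERATE_CHOICES[name]))
        return feats
    severe_pool = [
        ("cardiac_edema", True),
        ("tail_curvature", "severe_bidirectional"),
        ("jaw", "severe_malformation"),
        ("cleft_like_defect", True),
        ("severe_axis_defect", True),
    ]
    n_severe = int(rng.integers(2, len(severe_pool) + 1))
    chosen = rng.choice(len(severe_pool), size=n_severe, replace=False)
    for k in chosen:
        name, value = severe_pool[k]
        feats[name] = value
    return feats


def simulate_phenotype_records(
    group_class_probs: Optional[Dict[str, Sequence[float]]] = None,
    n_per_group: Optional[Dict[str, int]] = None,
    seed: int = 0,
    max_attempts: int = 1000,
) -> List[PhenotypeRecord]:
    """Per-larva feature tables with group-specific class probabilities.

    Classes (normal/medium/strong) are drawn per larva, then a feature
    combination is rejection-sampled until the phenotype classifier agrees
    with the drawn class; this keeps the generator decoupled from the
    classifier.  Defaults reproduce the published seven-condition design.
    """
    if group_class_probs is None:
        group_class_probs = {
            g: tuple(c / sum(counts) for c in counts)
            for g, counts in DEFAULT_GROUP_COUNTS.items()
        }
    if n_per_group is None:
        n_per_group = {g: sum(c) for g, c in DEFAULT_GROUP_COUNTS.items()}

    rng = np.random.default_rng(seed)
    classes = ("normal", "medium", "strong")
    records: List[PhenotypeRecord] = []
    for group, probs in group_class_probs.items():
        probs = np.asarray(probs, dtype=float)
        if probs.size != 3 or abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
            raise ValueError(f"group {group!r}: class probabilities must sum to 1")
        n = n_per_group.get(group)
        if n is None or n < 1:
            raise ValueError(f"group {group!r}: positive n required")
        for i in range(n):
            target = classes[int(rng.choice(3, p=probs))]
            for _ in range(max_attempts):
                feats = _propose_features(target, rng)
                record = PhenotypeRecord(
                    larva_id=f"{group}-{i + 1}", group=group, **feats
                )
                if classify_larva(record) == target:
                    break
            else:
                raise RuntimeError(
                    f"could not realize class {target!r} within {max_attempts} attempts"
                )
            records.append(record)
    return records


# ---------------------------------------------------------------------------
# Angles

# (mean degrees, sd degrees) per condition; the co-injected mutant group is
# shifted by two standard deviations relative to the injection control.
DEFAULT_ANGLE_PARAMS: Dict[str, Tuple[float, float]] = {
    "GFP": (60.0, 6.0),
    "EHHADH-WT": (63.0, 6.0),
    "EHHADH-MT": (66.0, 6.0),
    "MASP1-WT": (63.0, 6.0),
    "MASP1-MT": (66.0, 6.0),
    "COMBO-WT": (64.0, 6.0),
    "COMBO-MT": (72.0, 6.0),
}


def simulate_angles(
    group_params: Optional[Dict[str, Tuple[float, float]]] = None,
    n_per_group: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-group ceratohyal angles: Gaussian draws truncated to (0, 180).

    Returns a DataFrame with columns ``group`` and ``angle_deg``.
    """
    if group_params is None:
        group_params = DEFAULT_ANGLE_PARAMS
    rng = np.random.default_rng(seed)
    rows = []
    for group, (mean, sd) in group_params.items():
        if sd <= 0:
            raise ValueError(f"group {group!r}: sd must be positive")
        values = np.empty(n_per_group)
        filled = 0
        while filled < n_per_group:
            draw = rng.normal(mean, sd, size=n_per_group - filled)
            keep = draw[(draw > 0) & (draw < 180)]
            values[filled : filled + keep.size] = keep
            filled += keep.size
        rows.extend({"group": group, "angle_deg": float(v)} for v in values)
    return pd.DataFrame(rows)
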