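import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coseg.ibd import (
    IBDSegment,
    Individual,
    Pedigree,
    SiteIBDState,
    VariantSite,
    detect_ibd_segments,
    informative_sites,
    mendelian_consistent,
    pairwise_ibd_states,
    read_multisample_vcf,
    segments_from_states,
    site_passes_filters,
    write_segments_bed,
)
from coseg.synthetic import (
    SimulationConfig,
    family_variant_sites,
    nuclear_pedigree,
    simulate_family,
    true_ibd_states,
    write_ped,
)

PAIR = ("child1", "child2")
SAMPLES = ("father", "mother", "child1", "child2")


def make_site(genotypes, dp=30, gq=99, ad=None, pos=1000):
    """Convenience builder: genotypes as {'father': (0,1), ...}."""
    depth = {s: dp for s in genotypes}
    quality = {s: float(gq) for s in genotypes}
    if ad is None:
        ad = {}
        for s, gt in genotypes.items():
            if gt is None:
                ad[s] = (0, 0)
            elif gt[0] != gt[1]:
                ad[s] = (dp // 2, dp - dp // 2)
            else:
                ad[s] = (dp, 0) if gt[0] == 0 else (0, dp)
    return VariantSite(
        chromosome="chr1",
        position=pos,
        ref="A",
        alt="G",
        genotypes=dict(genotypes),
        depth=depth,
        quality=quality,
        allele_depths=ad,
    )


class TestPedigree:
    def test_ped_roundtrip(self, tmp_path, sib_pedigree):
        path = tmp_path / "fam.ped"
        write_ped(sib_pedigree, str(path))
        loaded = Pedigree.from_ped(str(path))
        assert loaded.ids == sib_pedigree.ids
        assert loaded["child1"].father == "father"
        assert loaded["child1"].affected

    def test_missing_parent_link_rejected(self):
        with pytest.raises(ValueError, match="not in pedigree"):
            Pedigree([Individual("kid", father="ghost")])

    def test_self_ancestry_rejected(self):
        with pytest.raises(ValueError, match="ancestor"):
            Pedigree(
                [
                    Individual("a", father="b"),
                    Individual("b", father="a"),
                ]
            )

    def test_full_sib_detection(self, sib_pedigree):
        assert sib_pedigree.are_full_sibs("child1", "child2")
        assert not sib_pedigree.are_full_sibs("father", "child1")


class TestMendelianCheck:
    def test_brute_force_enumeration(self):
        """Compare against exhaustive gamete enumeration on all trio genotypes."""
        gts = [(0, 0), (0, 1), (1, 1)]
        for child, father, mother in itertools.product(gts, repeat=3):
            possible = {
                tuple(sorted((a, b))) for a in father for b in mother
            }
            assert mendelian_consistent(child, father, mother) == (child in possible)

    def test_single_parent_degrades_to_sharing(self):
        assert mendelian_consistent((0, 0), (0, 1), None)
        assert not mendelian_consistent((1, 1), (0, 0), None)
        assert mendelian_consistent((1, 1), None, None)


class TestSiteFilters:
    def good_site(self):
        return make_site(
            {"father": (0, 1), "mother": (0, 0), "child1": (0, 1), "child2": (0, 0)}
        )

    def test_clean_site_passes(self, sib_pedigree):
        result = site_passes_filters(self.good_site(), sib_pedigree)
        assert result.passed and result.reason is None

    def test_depth_threshold_is_strictly_greater_than_14(self, sib_pedigree):
        site = self.good_site()
        site.depth["child1"] = 14
        assert site_passes_filters(site, sib_pedigree).reason == "depth"
        site.depth["child1"] = 15
        assert site_passes_filters(site, sib_pedigree).passed

    def test_quality_threshold_is_strictly_greater_than_30(self, sib_pedigree):
        site = self.good_site()
        site.quality["mother"] = 30
        assert site_passes_filters(site, sib_pedigree).reason == "quality"

    def test_mendelian_error_detected(self, sib_pedigree):
        site = make_site(
            {"father": (0, 0), "mother": (0, 1), "child1": (1, 1), "child2": (0, 0)}
        )
        assert site_passes_filters(site, sib_pedigree).reason == "mendelian"

    def test_allelic_imbalance_detected(self, sib_pedigree):
        site = self.good_site()
        site.allele_depths["child1"] = (27, 3)  # alt fraction 0.1
        assert site_passes_filters(site, sib_pedigree).reason == "allelic_balance"

    def test_missing_genotype(self, sib_pedigree):
        site = self.good_site()
        site.genotypes["child2"] = None
        assert site_passes_filters(site, sib_pedigree).reason == "missing"

    def test_filtering_is_idempotent(self, sib_pedigree):
        family = simulate_family(SimulationConfig(n_sites=400), nuclear_pedigree(2), seed=9)
        sites = family_variant_sites(family, noise_seed=9)
        once = [s for s in sites if site_passes_filters(s, sib_pedigree)]
        twice = [s for s in once if site_passes_filters(s, sib_pedigree)]
        assert twice == once
        assert len(once) < len(sites)  # the noise model does reject some sites


class TestVcfReading:
    def write_vcf(self, tmp_path, body):
        header = (
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000000>\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="q">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
        )
        path = tmp_path / "toy.vcf"
        path.write_text(header + body)
        return str(path)

    def sample(self, gt="0/1", ad="15,15", dp=30, gq=99):
        return f"{gt}:{ad}:{dp}:{gq}"

    def test_reads_all_clean_records(self, tmp_path):
        rows = "".join(
            f"chr1\t{pos}\t.\tA\tG\t.\tPASS\t.\tGT:AD:DP:GQ\t{self.sample()}\t{self.sample()}\n"
            for pos in (100, 200, 300, 400, 500)
        )
        sites, stats = read_multisample_vcf(self.write_vcf(tmp_path, rows), ["S1", "S2"])
        assert len(sites) == 5 and stats.n_sites == 5
        assert sites[0].genotypes["S1"] == (0, 1)
        assert sites[0].allele_depths["S2"] == (15, 15)

    def test_multiallelic_and_indel_records_are_skipped(self, tmp_path):
        rows = (
            f"chr1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT:AD:DP:GQ\t{self.sample(ad='10,10,10')}\t{self.sample(ad='10,10,10')}\n"
            f"chr1\t200\t.\tAT\tA\t.\tPASS\t.\tGT:AD:DP:GQ\t{self.sample()}\t{self.sample()}\n"
            f"chr1\t300\t.\tA\tG\t.\tPASS\t.\tGT:AD:DP:GQ\t{self.sample()}\t{self.sample()}\n"
        )
        sites, stats = read_multisample_vcf(self.write_vcf(tmp_path, rows), ["S1", "S2"])
        assert len(sites) == 1
        assert stats.skipped_multiallelic == 1
        assert stats.skipped_non_snv == 1

    def test_record_missing_format_is_skipped_and_counted(self, tmp_path):
        rows = (
            f"chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:DP:GQ\t0/1:30:99\t0/1:30:99\n"
            f"chr1\t200\t.\tA\tG\t.\tPASS\t.\tGT:AD:DP:GQ\t{self.sample()}\t{self.sample()}\n"
        )
        sites, stats = read_multisample_vcf(self.write_vcf(tmp_path, rows), ["S1", "S2"])
        assert len(sites) == 1
        assert stats.skipped_missing_format == 1

    def test_absent_sample_is_fatal(self, tmp_path):
        rows = f"chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:AD:DP:GQ\t{self.sample()}\t{self.sample()}\n"
        with pytest.raises(ValueError, match="S9"):
            read_multisample_vcf(self.write_vcf(tmp_path, rows), ["S1", "S9"])

    def test_missing_genotype_is_kept_as_none(self, tmp_path):
        rows = (
            f"chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:AD:DP:GQ\t./.:.:.:.\t{self.sample()}\n"
        )
        sites, _ = read_multisample_vcf(self.write_vcf(tmp_path, rows), ["S1", "S2"])
        assert sites[0].genotypes["S1"] is None


class TestInformativeness:
    def test_double_homozygous_parents_dropped(self, sib_pedigree):
        site = make_site(
            {"father": (0, 0), "mother": (0, 0), "child1": (0, 0), "child2": (0, 0)}
        )
        assert informative_sites([site], PAIR, sib_pedigree) == []

    def test_single_het_parent_retained(self, sib_pedigree):
        site = make_site(
            {"father": (0, 1), "mother": (0, 0), "child1": (0, 1), "child2": (0, 0)}
        )
        assert informative_sites([site], PAIR, sib_pedigree) == [site]

    def test_double_het_with_het_children_is_ambiguous(self, sib_pedigree):
        site = make_site(
            {"father": (0, 1), "mother": (0, 1), "child1": (0, 1), "child2": (0, 1)}
        )
        assert informative_sites([site], PAIR, sib_pedigree) == []
        # ... unless the allele-depth heuristic is allowed to weigh in
        assert informative_sites([site], PAIR, sib_pedigree, ad_tiebreak=True) == [site]

    def test_non_sib_pair_rejected(self, sib_pedigree):
        with pytest.raises(ValueError, match="full sib"):
            informative_sites([], ("father", "child1"), sib_pedigree)


class TestPairwiseStates:
    def test_both_transmissions_shared_is_ibd2(self, sib_pedigree):
        # both parents het, both sibs homozygous alt: each sib received the
        # alt allele from both parents -> definite IBD2
        site = make_site(
            {"father": (0, 1), "mother": (0, 1), "child1": (1, 1), "child2": (1, 1)}
        )
        [state] = pairwise_ibd_states([site], PAIR, sib_pedigree)
        assert state.state == "IBD2" and state.definite

    def test_opposite_homozygotes_are_ibd0(self, sib_pedigree):
        site = make_site(
            {"father": (0, 1), "mother": (0, 1), "child1": (0, 0), "child2": (1, 1)}
        )
        [state] = pairwise_ibd_states([site], PAIR, sib_pedigree)
        assert state.state == "IBD0" and state.definite

    def test_shared_paternal_allele_is_ibd1(self, sib_pedigree):
        # father het and informative; mother homozygous (maternal sharing
        # unobservable): sibs share the paternal alt allele
        site = make_site(
            {"father": (0, 1), "mother": (0, 0), "child1": (0, 1), "child2": (0, 1)}
        )
        [state] = pairwise_ibd_states([site], PAIR, sib_pedigree)
        assert state.state == "IBD1" and not state.definite

    def test_unshared_single_parent_evidence_is_ambiguous(self, sib_pedigree):
        site = make_site(
            {"father": (0, 1), "mother": (0, 0), "child1": (0, 1), "child2": (0, 0)}
        )
        [state] = pairwise_ibd_states([site], PAIR, sib_pedigree)
        assert state.state == "ambiguous"

    def test_ad_tiebreak_calls_weak_sharing(self, sib_pedigree):
        site = make_site(
            {"father": (0, 1), "mother": (0, 1), "child1": (0, 1), "child2": (0, 1)}
        )
        [with_tb] = pairwise_ibd_states([site], PAIR, sib_pedigree, ad_tiebreak=True)
        assert with_tb.state == "IBD1"
        site.allele_depths["child1"] = (27, 3)
        site.allele_depths["child2"] = (3, 27)
        [far_apart] = pairwise_ibd_states([site], PAIR, sib_pedigree, ad_tiebreak=True)
        assert far_apart.state == "ambiguous"

    def test_definite_states_match_simulated_truth(self, sib_pedigree):
        """On noiseless simulated data the definite per-site calls are exact."""
        config = SimulationConfig(noiseless=True)
        family = simulate_family(config, nuclear_pedigree(2), seed=3)
        sites = family_variant_sites(family, noise_seed=3)
        informative = informative_sites(sites, PAIR, sib_pedigree)
        states = pairwise_ibd_states(informative, PAIR, sib_pedigree)
        truth = true_ibd_states(family, PAIR)
        pos_index = {int(p): i for i, p in enumerate(family.positions_bp)}
        definite = [(s, truth[pos_index[s.position]]) for s in states if s.definite]
        assert len(definite) > 100
        agree = sum(1 for s, t in definite if s.state == f"IBD{t}")
        assert agree / len(definite) >= 0.99


def run(states_spec, **kwargs):
    states = [
        SiteIBDState("chr1", pos, state, definite)
        for pos, state, definite in states_spec
    ]
    return segments_from_states(states, **kwargs)


class TestSegments:
    def test_uninterrupted_run_is_one_segment(self):
        spec = [(i * 100, "IBD2", True) for i in range(1, 11)]
        [seg] = run(spec, min_sites=5)
        assert (seg.start_bp, seg.end_bp) == (100, 1000)
        assert seg.state == "IBD2" and seg.n_supporting_sites == 10

    def test_ibd0_site_splits_runs(self):
        spec = (
            [(i * 100, "IBD2", True) for i in range(1, 7)]
            + [(700, "IBD0", True)]
            + [(i * 100, "IBD2", True) for i in range(8, 14)]
        )
        segments = run(spec, min_sites=5)
        assert len(segments) == 2

    def test_ambiguous_sites_are_transparent(self):
        spec = (
            [(i * 100, "IBD2", True) for i in range(1, 6)]
            + [(600, "ambiguous", False)]
            + [(i * 100, "IBD2", True) for i in range(7, 12)]
        )
        [seg] = run(spec, min_sites=5)
        assert seg.n_supporting_sites == 10

    def test_large_gap_splits_runs(self):
        spec = [(i * 100, "IBD1", False) for i in range(1, 7)] + [
            (5_000_000 + i * 100, "IBD1", False) for i in range(1, 7)
        ]
        segments = run(spec, min_sites=5, max_gap_bp=1_000_000)
        assert len(segments) == 2

    def test_short_runs_are_discarded(self):
        spec = [(i * 100, "IBD2", True) for i in range(1, 4)]
        assert run(spec, min_sites=5) == []

    def test_segment_state_by_definite_majority(self):
        spec = [(100, "IBD1", False), (200, "IBD2", True), (300, "IBD1", False)]
        [seg] = run(spec, min_sites=2)
        assert seg.state == "IBD2"
        spec = [(100, "IBD1", False)] * 1  # no definite sites at all
        spec = [(100, "IBD1", False), (200, "IBD1", False)]
        [seg] = run(spec, min_sites=2)
        assert seg.state == "IBD1"

    @given(
        states=st.lists(
            st.sampled_from(["IBD0", "IBD1", "IBD2", "ambiguous"]), min_size=1, max_size=60
        ),
        min_a=st.integers(min_value=1, max_value=6),
        bump=st.integers(min_value=1, max_value=6),
    )
    def test_raising_min_sites_never_adds_segments(self, states, min_a, bump):
        spec = [(100 * (i + 1), s, True) for i, s in enumerate(states)]
        low = run(spec, min_sites=min_a)
        high = run(spec, min_sites=min_a + bump)
        assert len(high) <= len(low)

    def test_bed_writer_converts_to_zero_based_half_open(self, tmp_path):
        seg = IBDSegment(("a", "b"), "chr1", 101, 500, "IBD1", 7)
        out = tmp_path / "segs.bed"
        write_segments_bed([seg], str(out))
        line = out.read_text().splitlines()[1]
        assert line.split("\t")[:3] == ["chr1", "100", "500"]


class TestEndToEnd:
    def test_segments_sorted_nonoverlapping_and_cover_truth(self, sib_pedigree):
        config = SimulationConfig(noiseless=True)
        family = simulate_family(config, nuclear_pedigree(2), seed=17)
        sites = family_variant_sites(family, noise_seed=17)
        segments = detect_ibd_segments(sites, PAIR, sib_pedigree)
        assert segments == sorted(segments, key=lambda s: s.start_bp)
        for a, b in zip(segments, segments[1:]):
            assert a.end_bp < b.start_bp
        truth = true_ibd_states(family, PAIR) >= 1
        pos = family.positions_bp
        truth_len = int(np.sum(np.diff(pos)[truth[:-1] & truth[1:]]))
        covered = 0
        for seg in segments:
            inside = (pos >= seg.start_bp) & (pos <= seg.end_bp)
            covered += int(np.sum(np.diff(pos)[(inside & truth)[:-1] & (inside & truth)[1:]]))
        assert covered / truth_len >= 0.9
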