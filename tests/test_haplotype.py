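"""EM phasing, haplotype dosage/association and the haplotype network."""

import numpy as np
import pytest

from transfinemap import ld_core, synthetic_data as sd
from transfinemap.association import linear_assoc
from transfinemap.errors import InputError
from transfinemap.geno_io import GenotypeMatrix, VariantRecord
from transfinemap.haplotype import (
    Haplotype,
    HaplotypeSet,
    _enumerate_pairs,
    build_phylogeny,
    em_phase,
    haplotype_assoc,
    haplotype_assoc_meta,
    haplotype_dosage,
)

from .conftest import make_pheno


def _panel_from_haplotypes(hap_pairs, n_snps, alleles=("G", "A")):
    """Build an unphased panel from explicit 0/1 haplotype pairs."""
    calls = np.array([[a + b for a, b in zip(h1, h2)] for h1, h2 in hap_pairs])
    variants = [
        VariantRecord(f"snp{j + 1}", "16", 100 + 10 * j, alleles[0], alleles[1], alleles[1])
        for j in range(n_snps)
    ]
    return GenotypeMatrix(
        variants=variants,
        samples=[f"s{i + 1}" for i in range(len(hap_pairs))],
        calls=calls.astype(np.int8),
    )


class TestEnumeratePairs:
    def test_no_heterozygote_single_resolution(self):
        assert _enumerate_pairs((0, 2, 0)) == [((0, 1, 0), (0, 1, 0))]

    def test_double_heterozygote_two_resolutions(self):
        pairs = _enumerate_pairs((1, 1))
        assert sorted(pairs) == [((1, 0), (0, 1)), ((1, 1), (0, 0))]

    def test_count_scales_as_two_to_h_minus_one(self):
        assert len(_enumerate_pairs((1,) * 5)) == 2 ** 4


class TestEmPhase:
    def test_unambiguous_panel_recovered_exactly(self, rng):
        """With no double heterozygotes the frequencies are exact."""
        # haplotypes 111 and 000 only: any genotype is 000, 111+000, or 222
        picks = rng.random((200, 2)) < 0.3
        hap_pairs = [
            (tuple([int(a)] * 3), tuple([int(b)] * 3)) for a, b in picks
        ]
        panel = _panel_from_haplotypes(hap_pairs, 3)
        hs = em_phase(panel)
        truth = np.mean(picks)
        est = {h.label: hs.freqs["all"][h.label] for h in hs.haplotypes}
        assert est.get("AAA", 0.0) == pytest.approx(truth, abs=1e-8)
        assert est.get("GGG", 0.0) == pytest.approx(1 - truth, abs=1e-8)

    def test_two_snp_case_matches_pairwise_em(self, rng):
        ga = rng.binomial(2, 0.4, 300).astype(float)
        gb = np.where(rng.random(300) < 0.2, rng.binomial(2, 0.4, 300), ga).astype(float)
        panel = _panel_from_haplotypes(
            [((0, 0), (0, 0))] * 300, 2
        )
        panel.calls = np.column_stack([ga, gb]).astype(np.int8)
        hs = em_phase(panel)
        h2 = ld_core.em_hapfreq2(ga, gb)
        # map: effect allele "A" = allele 1 at both SNPs
        freqs = {h.label: f for h, f in ((h, hs.freqs["all"][h.label]) for h in hs.haplotypes)}
        assert freqs.get("AA", 0.0) == pytest.approx(h2.f_AB, abs=1e-6)
        assert freqs.get("AG", 0.0) == pytest.approx(h2.f_Ab, abs=1e-6)
        assert freqs.get("GA", 0.0) == pytest.approx(h2.f_aB, abs=1e-6)
        assert freqs.get("GG", 0.0) == pytest.approx(h2.f_ab, abs=1e-6)

    def test_population_frequencies_recovered_within_3se(self):
        """East-Asian-style frequencies are recovered from n=5000 genotypes."""
        freqs = {"H1": 0.15, "H3": 0.77, "H4": 0.05, "H2": 0.03}
        cfg = sd.PopulationConfig(name="asn", n_samples=5000, hap_freqs=freqs, seed=51)
        panel, _, _ = sd.simulate_panel(cfg)
        hs = em_phase(panel, population="asn").relabelled(sd.default_haplotypes())
        for label, truth in freqs.items():
            se = np.sqrt(truth * (1 - truth) / (2 * 5000))
            assert hs.freqs["asn"][label] == pytest.approx(truth, abs=3 * se)

    def test_all_samples_incomplete_raises(self):
        panel = _panel_from_haplotypes([((0, 0), (0, 1))] * 30, 2)
        panel.calls[:, 0] = -1
        with pytest.raises(InputError):
            em_phase(panel)


class TestDosage:
    def test_homozygous_sample_has_dosage_two(self, rng):
        picks = rng.random((100, 2)) < 0.4
        hap_pairs = [(tuple([int(a)] * 2), tuple([int(b)] * 2)) for a, b in picks]
        panel = _panel_from_haplotypes(hap_pairs, 2)
        hs = em_phase(panel)
        d = haplotype_dosage(hs, "AA")
        hom = [i for i, (a, b) in enumerate(picks) if a and b]
        assert np.allclose(d[hom], 2.0)

    def test_dosages_sum_to_two_exactly(self, rng):
        cfg = sd.PopulationConfig(
            name="x", n_samples=300,
            hap_freqs={"H1": 0.2, "H2": 0.3, "H3": 0.4, "H4": 0.1}, seed=53,
        )
        panel, _, _ = sd.simulate_panel(cfg)
        hs = em_phase(panel)
        total = sum(haplotype_dosage(hs, l) for l in hs.labels)
        assert np.allclose(total, 2.0, atol=1e-9)

    def test_hand_computed_posterior_split(self):
        """A 0.6/0.4 phase-ambiguous posterior over pairs carrying 1 vs 0
        copies of the target gives dosage 0.6."""
        snps = [VariantRecord("s1", "1", 1, "G", "A", "A"),
                VariantRecord("s2", "1", 2, "G", "A", "A")]
        haps = [Haplotype("AG", ("A", "G")), Haplotype("GA", ("G", "A")),
                Haplotype("AA", ("A", "A")), Haplotype("GG", ("G", "G"))]
        hs = HaplotypeSet(
            snp_list=snps, haplotypes=haps,
            freqs={"all": {"AG": 0.25, "GA": 0.25, "AA": 0.25, "GG": 0.25}},
            samples=["s1"],
            posterior=[{("AG", "GA"): 0.3, ("GA", "AG"): 0.3,
                        ("AA", "GG"): 0.2, ("GG", "AA"): 0.2}],
        )
        assert haplotype_dosage(hs, "AG")[0] == pytest.approx(0.6)

    def test_unknown_label_raises(self, rng):
        picks = rng.random((50, 2)) < 0.4
        panel = _panel_from_haplotypes(
            [(tuple([int(a)] * 2), tuple([int(b)] * 2)) for a, b in picks], 2
        )
        hs = em_phase(panel)
        with pytest.raises(KeyError):
            haplotype_dosage(hs, "nope")


class TestHaplotypeAssoc:
    def test_planted_haplotype_effect_recovered_within_2se(self):
        cfg = sd.PopulationConfig(
            name="asn", n_samples=15_000,
            hap_freqs={"H1": 0.2, "H3": 0.7, "H4": 0.1}, seed=57,
        )
        eff = sd.EffectConfig(bmi_beta_per_h1=0.064)
        panel, pheno, _ = sd.simulate_panel(cfg, eff)
        hs = em_phase(panel, population="asn").relabelled(sd.default_haplotypes())
        r = haplotype_assoc(hs, "H1", pheno, trait="bmi")
        assert abs(r.beta - 0.064) < 2 * r.se

    def test_reduces_to_single_snp_when_target_tags_one_allele(self, rng):
        """If the target haplotype is exactly the indicator of one SNP
        allele, its dosage beta equals the single-SNP beta."""
        picks = rng.random((400, 2)) < 0.3
        hap_pairs = [((int(a), 0), (int(b), 0)) for a, b in picks]
        panel = _panel_from_haplotypes(hap_pairs, 2)
        bmi = rng.normal(23, 1, 400) + 0.3 * panel.calls[:, 0]
        pheno = make_pheno(panel.samples, bmi=bmi, age=rng.uniform(40, 60, 400))
        hs = em_phase(panel, ["snp1", "snp2"])
        # snp2 is monomorphic, so the "AG" haplotype is exactly the snp1
        # effect-allele indicator
        assert np.allclose(haplotype_dosage(hs, "AG"), panel.genotype("snp1"), atol=1e-6)
        single = linear_assoc("snp1", panel, pheno)
        hap = haplotype_assoc(hs, "AG", pheno, trait="bmi")
        assert hap.beta == pytest.approx(single.beta, abs=1e-6)
        assert hap.se == pytest.approx(single.se, abs=1e-6)

    def test_absent_target_dropped_from_meta_with_warning(self):
        cfg_with = sd.PopulationConfig(
            name="p1", n_samples=800, hap_freqs={"H1": 0.3, "H3": 0.7}, seed=61
        )
        cfg_without = sd.PopulationConfig(
            name="p2", n_samples=800, hap_freqs={"H3": 0.6, "H4": 0.4}, seed=63
        )
        p1, ph1, _ = sd.simulate_panel(cfg_with)
        p2, ph2, _ = sd.simulate_panel(cfg_without)
        target = sd.default_haplotypes().haplotype("H1").alleles
        with pytest.warns(UserWarning, match="absent|degenerate"):
            combined, per_pop = haplotype_assoc_meta(
                {"p1": p1, "p2": p2}, {"p1": ph1, "p2": ph2},
                p1.snp_ids, target, trait="bmi",
            )
        assert list(per_pop) == ["p1"]
        assert combined.k_studies == 1


class TestPhylogeny:
    def test_published_topology_for_principal_haplotypes(self):
        """H2 -> H3 (rs9939609), H3 -> H4 (rs9941349), H2 -> H1 over the six
        first-cluster SNPs."""
        hs = sd.default_haplotypes()
        net = build_phylogeny(hs, "H2", freq_floor=0.05)
        assert set(net.nodes) == {"H1", "H2", "H3", "H4"}
        assert net.edge_to("H3").parent == "H2"
        assert net.edge_to("H3").detail == ("rs9939609",)
        assert net.edge_to("H4").parent == "H3"
        assert net.edge_to("H4").detail == ("rs9941349",)
        e1 = net.edge_to("H1")
        assert e1.parent == "H2" and e1.kind == "mutation"
        assert set(e1.detail) == {
            "rs1421085", "rs3751812", "rs9941349", "rs56137030",
            "rs17817964", "rs12149832",
        }

    def test_constructed_recombinant_detected_with_breakpoint(self):
        hs = sd.default_haplotypes()
        h1 = hs.haplotype("H1").alleles
        h3 = hs.haplotype("H3").alleles
        rec = Haplotype("REC", h1[:3] + h3[3:])
        hs2 = HaplotypeSet(
            snp_list=hs.snp_list,
            haplotypes=[hs.haplotype(l) for l in ("H1", "H2", "H3", "H4")] + [rec],
            freqs={"all": {"H1": 0.3, "H2": 0.1, "H3": 0.4, "H4": 0.1, "REC": 0.1}},
        )
        net = build_phylogeny(hs2, "H2", freq_floor=0.05)
        edge = net.edge_to("REC")
        assert edge.kind == "recombination"
        second_parent, interval = edge.detail
        assert {edge.parent, second_parent} == {"H1", "H3"}
        # crossover must fall where the parents differ around the join
        assert interval == ("rs9939609", "rs9941349")

    def test_root_only_network(self):
        hs = sd.default_haplotypes().subset(["H2"])
        net = build_phylogeny(hs, "H2")
        assert net.nodes == ["H2"] and net.edges == []

    def test_missing_ancestor_raises(self):
        hs = sd.default_haplotypes().subset(["H1", "H3"])
        with pytest.raises(InputError):
            build_phylogeny(hs, "H2")

    def test_events_bounded_by_star_topology(self):
        hs = sd.default_haplotypes()
        net = build_phylogeny(hs, "H2", freq_floor=0.0)
        h2 = hs.haplotype("H2").alleles
        star = sum(
            sum(a != b for a, b in zip(hs.haplotype(l).alleles, h2))
            for l in net.nodes if l != "H2"
        )
        assert net.total_events() <= star

    def test_newick_export_of_principal_tree(self):
        net = build_phylogeny(sd.default_haplotypes(), "H2", freq_floor=0.05)
        assert net.newick() == "(H1,(H4)H3)H2;"
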