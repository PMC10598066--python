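"""Variant funnel: stage predicates, marker estimation, and invariants."""

import numpy as np
import pytest

from catifunnel import (
    Genotype,
    Impact,
    LocusInterval,
    Marker,
    VariantRecord,
    classify_impact,
    cross_assembly_concordance,
    estimate_marker_position,
    filter_homozygous,
    panel_exclusion,
    restrict_to_locus,
    run_variant_funnel,
    select_impact,
)
from catifunnel import datasets
from catifunnel.simulate import DECOY_STAGES
from catifunnel.variants import PanelManifest, most_severe_term


def var(chrom="chr1", pos=100, ref="A", alt="T", gt=Genotype.HOM_ALT,
        gene="g", terms=("missense_variant",), assembly="A"):
    so = frozenset(terms)
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                         genotype=gt, gene=gene, so_terms=so,
                         impact=classify_impact(so), assembly=assembly)


# ---------------------------------------------------------------------------
# Impact classification
# ---------------------------------------------------------------------------

class TestClassifyImpact:
    @pytest.mark.parametrize("terms,expected", [
        ({"missense_variant"}, Impact.MODERATE),
        ({"stop_lost"}, Impact.HIGH),
        ({"disruptive_inframe_deletion"}, Impact.MODERATE),
        ({"conservative_inframe_insertion"}, Impact.MODERATE),
        ({"synonymous_variant"}, Impact.LOW),
        ({"intron_variant"}, Impact.MODIFIER),
        # multi-term alleles take the most severe class
        ({"splice_donor_variant", "splice_region_variant",
          "intron_variant"}, Impact.HIGH),
        ({"splice_donor_variant", "3_prime_UTR_variant",
          "intron_variant"}, Impact.HIGH),
    ])
    def test_reported_term_assignments(self, terms, expected):
        assert classify_impact(terms) is expected

    def test_unknown_terms_classify_unclassified(self):
        assert classify_impact({"made_up_term"}) is Impact.UNCLASSIFIED

    def test_empty_term_set_rejected(self):
        with pytest.raises(ValueError):
            classify_impact(set())

    def test_severity_max_combination_is_idempotent(self):
        terms = {"missense_variant", "synonymous_variant", "intron_variant"}
        once = classify_impact(terms)
        # classifying the union with itself changes nothing
        assert classify_impact(terms | terms) is once
        assert once is Impact.MODERATE

    def test_most_severe_term_deterministic(self):
        terms = {"intron_variant", "splice_donor_variant",
                 "splice_region_variant"}
        assert most_severe_term(terms) == "splice_donor_variant"


# ---------------------------------------------------------------------------
# Stage predicates
# ---------------------------------------------------------------------------

class TestHomozygosityFilter:
    def test_genotype_handling(self):
        variants = [var(pos=1, gt=Genotype.HOM_ALT),
                    var(pos=2, gt=Genotype.HET),
                    var(pos=3, gt=Genotype.MISSING),
                    var(pos=4, gt=Genotype.HOM_REF)]
        kept = filter_homozygous(variants)
        assert [v.pos for v in kept] == [1]


class TestSelectImpact:
    def test_moderate_high_selection(self):
        vs = [var(pos=1, terms=("missense_variant",)),
              var(pos=2, terms=("stop_lost",)),
              var(pos=3, terms=("synonymous_variant",)),
              var(pos=4, terms=("intron_variant",))]
        kept = select_impact(vs, {Impact.MODERATE, Impact.HIGH})
        assert [v.pos for v in kept] == [1, 2]
        assert select_impact(vs, set()) == []

    def test_disjoint_classes_partition_the_selection(self):
        rng = np.random.default_rng(5)
        terms_pool = [("missense_variant",), ("stop_lost",),
                      ("synonymous_variant",), ("intron_variant",)]
        vs = [var(pos=i + 1, terms=terms_pool[rng.integers(4)])
              for i in range(100)]
        both = select_impact(vs, {Impact.MODERATE, Impact.HIGH})
        mod = select_impact(vs, {Impact.MODERATE})
        high = select_impact(vs, {Impact.HIGH})
        assert len(mod) + len(high) == len(both)
        assert {v.site_key for v in mod} | {v.site_key for v in high} \
            == {v.site_key for v in both}


class TestConcordance:
    def test_same_gene_allele_effect_retained(self):
        a = [var(pos=100, gene="gX")]
        b = [var(pos=100 + 5000, gene="gX", assembly="B")]
        assert cross_assembly_concordance(a, b) == a

    def test_variant_absent_from_second_assembly_dropped(self):
        a = [var(pos=100, gene="gX"), var(pos=200, gene="gY", ref="C",
                                          alt="G")]
        b = [var(pos=5100, gene="gX", assembly="B")]
        kept = cross_assembly_concordance(a, b)
        assert [v.gene for v in kept] == ["gX"]

    def test_coordinate_mode_matches_site_atoms(self):
        a = [var(pos=100)]
        b_same = [var(pos=100, assembly="B")]
        b_shift = [var(pos=101, assembly="B")]
        assert cross_assembly_concordance(a, b_same, key="coordinate") == a
        assert cross_assembly_concordance(a, b_shift, key="coordinate") == []

    def test_record_without_gene_excluded_with_warning(self, caplog):
        a = [var(pos=100, gene="")]
        with caplog.at_level("WARNING", logger="catifunnel.variants"):
            assert cross_assembly_concordance(a, a) == []
        assert any("excluded" in r.message for r in caplog.records)


class TestPanelExclusion:
    def test_reported_panel_shared_variant_removed(self):
        # the Fdft1 missense change is carried by a non-affected strain
        panel = datasets.reported_panel()
        kept = panel_exclusion(datasets.CHR15_CANDIDATE_VARIANTS, panel)
        assert "Fdft1" not in {v.gene for v in kept}
        assert len(kept) == 4

    def test_empty_panel_is_identity(self):
        vs = [var(pos=1), var(pos=2)]
        assert panel_exclusion(vs, PanelManifest()) == vs

    def test_single_carrier_among_ten_strains_excludes(self):
        vs = [var(pos=1)]
        panel = PanelManifest()
        for i in range(10):
            panel.add(f"s{i}", [var(pos=1, gt=Genotype.HET)] if i == 7
                      else [])
        assert panel_exclusion(vs, panel) == []
        # homozygous-only mode keeps it: the carrier is heterozygous
        assert panel_exclusion(vs, panel, hom_only=True) == vs

    def test_panel_union_equals_sequential_exclusion(self):
        rng = np.random.default_rng(9)
        vs = [var(pos=int(p)) for p in rng.choice(10_000, 50, replace=False)]
        p1_vs = [var(pos=v.pos) for v in vs[:20]]
        p2_vs = [var(pos=v.pos) for v in vs[15:30]]
        p_union = PanelManifest({"a": p1_vs, "b": p2_vs})
        p1 = PanelManifest({"a": p1_vs})
        p2 = PanelManifest({"b": p2_vs})
        joint = panel_exclusion(vs, p_union)
        sequential = panel_exclusion(panel_exclusion(vs, p1), p2)
        assert joint == sequential


class TestRestrictToLocus:
    def test_reported_window_membership(self):
        apoc3 = datasets.CHR8_SELECTED_VARIANTS[0]
        kept = restrict_to_locus([apoc3], datasets.THY1_CYP1A1_WINDOW)
        assert kept == [apoc3]

    def test_chromosome_mismatch_excludes(self):
        gja8 = datasets.OTHER_REPORTED_VARIANTS[0]
        assert gja8.chrom == "chr2"
        assert restrict_to_locus([gja8], datasets.CATI1) == []

    def test_interval_endpoints_inclusive(self):
        locus = LocusInterval("L", "chr1", 100, 200)
        at_start = var(pos=100)
        at_end = var(pos=200)
        outside = var(pos=99)
        kept = restrict_to_locus([at_start, at_end, outside], locus)
        assert [v.pos for v in kept] == [100, 200]


# ---------------------------------------------------------------------------
# Marker position estimation
# ---------------------------------------------------------------------------

class TestEstimateMarkerPosition:
    def test_marker_coincident_with_anchor(self):
        anchor_src = Marker("A", "src", "chr1", 500)
        anchor_tgt = Marker("A", "tgt", "chr1", 900)
        m = Marker("M", "src", "chr1", 500)
        assert estimate_marker_position(m, anchor_src, anchor_tgt).pos == 900

    def test_uniform_shift_estimates_exact_on_both_sides(self):
        rng = np.random.default_rng(2)
        shift = 123_456
        anchor_src = Marker("A", "src", "chr1", 5_000_000)
        anchor_tgt = Marker("A", "tgt", "chr1", 5_000_000 + shift)
        for pos in rng.integers(1_000_000, 9_000_000, size=20):
            m = Marker("M", "src", "chr1", int(pos))
            est = estimate_marker_position(m, anchor_src, anchor_tgt)
            assert est.pos == int(pos) + shift

    def test_reproduces_reported_interval_start(self):
        # the reported interval end sits at 52,813,021 on the target
        # assembly and the source-assembly inter-marker distance is
        # 20,135,471 bases, so the estimate lands at 32,677,550
        est = estimate_marker_position(
            datasets.D15RAT52_RNOR6_SYNTHETIC,
            datasets.D15RAT20_RNOR6_SYNTHETIC,
            datasets.D15RAT20_MAIN,
        )
        assert est.pos == 32_677_550
        assert est.pos == datasets.CATI2.start

    def test_chromosome_mismatch_errors(self):
        m = Marker("M", "src", "chr2", 100)
        anchor_src = Marker("A", "src", "chr1", 500)
        anchor_tgt = Marker("A", "tgt", "chr1", 900)
        with pytest.raises(ValueError, match="hromosome"):
            estimate_marker_position(m, anchor_src, anchor_tgt)


# ---------------------------------------------------------------------------
# The funnel end to end
# ---------------------------------------------------------------------------

class TestRunVariantFunnel:
    def test_planted_causal_recovered_and_decoys_die_at_their_stage(
            self, variant_bundle):
        spec, case_a, case_b, panel, truth = variant_bundle
        report = run_variant_funnel(case_a, case_b, panel=panel,
                                    loci=[spec.causal_locus])
        assert [v.site_key for v in report.candidates] \
            == [truth.causal_variant.site_key]
        # replay each stage to find where each decoy drops out
        survivors = {"homozygosity": filter_homozygous(case_a)}
        hom_b = filter_homozygous(case_b)
        sel = select_impact(survivors["homozygosity"],
                            {Impact.MODERATE, Impact.HIGH})
        survivors["impact_selection"] = sel
        conc = cross_assembly_concordance(
            sel, select_impact(hom_b, {Impact.MODERATE, Impact.HIGH}))
        survivors["cross_assembly_concordance"] = conc
        excl = panel_exclusion(conc, panel)
        survivors["panel_exclusion"] = excl
        survivors["locus_restriction"] = restrict_to_locus(
            excl, spec.causal_locus)
        order = ["homozygosity", "impact_selection",
                 "cross_assembly_concordance", "panel_exclusion",
                 "locus_restriction"]
        for key, cls in truth.variant_classes.items():
            if cls in ("causal", "background"):
                continue
            die_at = DECOY_STAGES[cls]
            before = order[order.index(die_at) - 1] \
                if order.index(die_at) else None
            present_before = before is None or \
                key in {v.site_key for v in survivors[before]}
            assert present_before, (key, cls)
            assert key not in {v.site_key for v in survivors[die_at]}, \
                (key, cls)

    def test_empty_case_set_gives_zero_counts(self):
        report = run_variant_funnel([], [], panel=PanelManifest())
        assert report.candidates == []
        assert all(s.n_in == 0 and s.n_out == 0 for s in report.stages)

    def test_reported_chr15_variants_yield_four_candidate_genes(self):
        report = run_variant_funnel(
            datasets.CHR15_CANDIDATE_VARIANTS,
            datasets.CHR15_CANDIDATE_VARIANTS,
            panel=datasets.reported_panel(),
            loci=[datasets.CATI2],
        )
        assert sorted(v.gene for v in report.candidates) \
            == ["Nkx2-6", "Phf11b", "Ppk", "Sucla2"]

    def test_funnel_counts_monotone_on_random_sets(self):
        rng = np.random.default_rng(17)
        terms_pool = [("missense_variant",), ("stop_lost",),
                      ("synonymous_variant",), ("intron_variant",)]
        gts = [Genotype.HOM_ALT, Genotype.HET, Genotype.MISSING]
        for _ in range(60):
            n = int(rng.integers(0, 40))
            vs = [var(pos=int(p), gene=f"g{p}",
                      terms=terms_pool[rng.integers(4)],
                      gt=gts[rng.integers(3)])
                  for p in rng.choice(100_000, n, replace=False)]
            vs_b = [v for v in vs if rng.random() < 0.8]
            panel = PanelManifest(
                {"s1": [v for v in vs if rng.random() < 0.3]})
            report = run_variant_funnel(
                vs, vs_b, panel=panel,
                loci=[LocusInterval("L", "chr1", 1, 50_000)])
            for s in report.stages:
                assert s.n_out <= s.n_in

    def test_homozygosity_and_locus_restriction_commute(self):
        rng = np.random.default_rng(23)
        gts = [Genotype.HOM_ALT, Genotype.HET, Genotype.HOM_REF]
        vs = [var(pos=int(p), gt=gts[rng.integers(3)])
              for p in rng.choice(10_000, 200, replace=False)]
        locus = LocusInterval("L", "chr1", 2_000, 7_000)
        one = restrict_to_locus(filter_homozygous(vs), locus)
        other = filter_homozygous(restrict_to_locus(vs, locus))
        assert {v.site_key for v in one} == {v.site_key for v in other}

    def test_stage_count_invariant_rejected(self):
        from catifunnel.variants import FunnelStage
        with pytest.raises(ValueError, match="exceeds"):
            FunnelStage("s", "all", 1, 2)
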