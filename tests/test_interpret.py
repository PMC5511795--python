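"""Annotation joins and the somatic/germline classification rules."""

import pytest
from hypothesis import given, settings, strategies as st

from oncopanel.calling import VariantCall
from oncopanel.interpret import (AnnotatedVariant, DrugRule, KnowledgeBase, KnowledgeBaseError,
                                 annotate_variant, classify_germline,
                                 classify_somatic,
                                 classify_germline_case_table,
                                 consequence_from_hgvs,
                                 dm_controversial_prevalence,
                                 load_germline_case_table,
                                 load_somatic_case_table,
                                 somatic_actionability_yield,
                                 tumor_only_filter)


def call(chrom="chr1", pos=100, ref="A", alt="T", alt_count=40, depth=100):
    return VariantCall(chrom, pos, ref, alt, alt_count, depth)


def annotated(**kw):
    defaults = dict(call=call(), gene="KRAS", consequence="missense",
                    pop_freqs={}, in_cosmic=False, in_icgc=False,
                    hgmd_status="none", lof_cancer_gene=False)
    defaults.update(kw)
    return AnnotatedVariant(**defaults)


class TestAnnotate:
    def test_kb_lookup_population_and_cosmic(self):
        kb = KnowledgeBase(
            pop_freqs={("chr1", 100, "A", "T"): {"ExAC": 0.002}},
            cosmic={("chr1", 100, "A", "T")},
            genes_by_site={("chr1", 100): "KRAS"})
        av = annotate_variant(call(), kb)
        assert av.in_cosmic and not av.in_icgc
        assert av.gene == "KRAS"
        assert av.max_pop_freq == pytest.approx(0.002)

    def test_absent_everywhere_means_zero_frequency(self):
        av = annotate_variant(call(), KnowledgeBase())
        assert av.max_pop_freq == 0.0
        assert not (av.in_cosmic or av.in_icgc)
        assert av.hgmd_status == "none"

    def test_malformed_kb_frequency_raises(self):
        kb = KnowledgeBase(pop_freqs={("chr1", 100, "A", "T"): {"ExAC": 1.5}})
        with pytest.raises(KnowledgeBaseError):
            annotate_variant(call(), kb)


class TestConsequenceInference:
    @pytest.mark.parametrize("hgvs_c,hgvs_p,expected", [
        ("c.35G>T", "p.G12V", "missense"),
        ("c.169G>T", "p.E57*", "nonsense"),
        ("c.157_158insG", "p.D53Gfs*110", "frameshift"),
        ("c.802-2A>T", "", "splice"),
        ("c.290+1G>C", "", "splice"),
        ("c.-54G>C", "", "noncoding"),
        ("c.3348+18A>G", "", "noncoding"),
        ("c.591C>T", "p.C197C", "synonymous"),
        ("c.2237_2254del", "p.E746_S752delinsA", "inframe_indel"),
        ("c.*20_*24del", "", "noncoding"),
    ])
    def test_hgvs_classes(self, hgvs_c, hgvs_p, expected):
        assert consequence_from_hgvs(hgvs_c, hgvs_p) == expected


class TestSomaticClassification:
    kras_rule = DrugRule(gene="KRAS", drug="trametinib", hgvs_c="c.35G>T")
    gene_rule = DrugRule(gene="KRAS", drug="everolimus")

    def test_exact_match_actionable_with_drugs(self):
        av = annotated(in_cosmic=True)
        cls = classify_somatic(av, [self.kras_rule, self.gene_rule],
                               hgvs_c="c.35G>T")
        assert cls.clinical_class == "actionable"
        # most specific tier wins: only the exact-variant rule's drugs
        assert [d.drug for d in cls.drug_associations] == ["trametinib"]
        assert cls.evidence_level == "FDA_EMA"

    def test_resistance_direction_preserved(self):
        rules = [DrugRule(gene="BRAF", drug="cetuximab",
                          direction="resistance", tumor_context="colorectal",
                          hgvs_c="c.1799T>A"),
                 DrugRule(gene="BRAF", drug="vemurafenib",
                          hgvs_c="c.1799T>A")]
        av = annotated(gene="BRAF", in_cosmic=True)
        cls = classify_somatic(av, rules, tumor_type="colorectal",
                               hgvs_c="c.1799T>A")
        directions = {d.drug: d.direction for d in cls.drug_associations}
        assert directions["cetuximab"] == "resistance"

    def test_high_population_frequency_not_reported(self):
        av = annotated(in_cosmic=True, pop_freqs={"ExAC": 0.2})
        cls = classify_somatic(av, [self.gene_rule])
        assert cls.clinical_class == "not_reported"

    def test_eligible_without_kb_match_is_somatic_vus(self):
        av = annotated(gene="NOVEL", consequence="frameshift")
        assert classify_somatic(av, [self.gene_rule]).clinical_class \
            == "somatic_VUS"

    def test_codon_range_pattern_match(self):
        rule = DrugRule(gene="EGFR", drug="gefitinib",
                        consequence="inframe_indel", codon_range=(729, 761))
        av = annotated(gene="EGFR", consequence="inframe_indel",
                       in_cosmic=True)
        cls = classify_somatic(av, [rule], hgvs_p="p.E746_S752delinsA")
        assert cls.clinical_class == "actionable"


class TestGermlineClassification:
    @pytest.mark.parametrize("kw,expected", [
        # solid DM at low frequency: pathogenic
        (dict(hgmd_status="DM_solid", pop_freqs={"ExAC": 0.0}),
         ("pathogenic", "none")),
        # non-DM drastic LoF in a risk gene below 0.01: likely pathogenic
        (dict(consequence="frameshift", lof_cancer_gene=True),
         ("likely_pathogenic", "none")),
        # controversial DM below 0.05: VUS
        (dict(hgmd_status="DM_controversial", pop_freqs={"ExAC": 0.02}),
         ("VUS", "DM_controversial")),
        # likely-pathogenic profile but frequency in the 0.01-0.05 band
        (dict(consequence="nonsense", lof_cancer_gene=True,
              pop_freqs={"ESP": 0.03}), ("VUS", "freq_band")),
        # plain rare missense: VUS (other)
        (dict(consequence="missense", pop_freqs={"dbSNP": 0.001}),
         ("VUS", "other")),
        # common non-DM missense: below no category
        (dict(consequence="missense", pop_freqs={"dbSNP": 0.03}),
         ("not_reported", "none")),
        # DM at too-high frequency: not pathogenic, not VUS either
        (dict(hgmd_status="DM_solid", pop_freqs={"ExAC": 0.1}),
         ("not_reported", "none")),
    ])
    def test_rule_lattice(self, kw, expected):
        cls = classify_germline(annotated(**kw))
        assert (cls.clinical_class, cls.vus_subclass) == expected

    @given(hgmd=st.sampled_from(["none", "DM_solid", "DM_controversial"]),
           consequence=st.sampled_from(["missense", "nonsense", "frameshift",
                                        "splice", "start_loss", "synonymous",
                                        "inframe_indel", "noncoding"]),
           lof=st.booleans(),
           freq=st.floats(min_value=0, max_value=0.5))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_classification_total_and_exclusive(self, hgmd, consequence,
                                                lof, freq):
        """Exactly one category for any annotation combination."""
        av = annotated(hgmd_status=hgmd, consequence=consequence,
                       lof_cancer_gene=lof, pop_freqs={"ExAC": freq})
        first = classify_germline(av)
        second = classify_germline(av)
        assert first.clinical_class == second.clinical_class  # deterministic
        assert first.clinical_class in ("pathogenic", "likely_pathogenic",
                                        "VUS", "not_reported")
        if first.clinical_class == "VUS":
            assert first.vus_subclass in ("DM_controversial", "freq_band",
                                          "other")
        else:
            assert first.vus_subclass == "none"


class TestTumorOnlyFilter:
    def test_common_variant_removed(self):
        kb = KnowledgeBase()
        av = annotated(pop_freqs={"dbSNP": 0.30})
        retained, warnings = tumor_only_filter([av], kb)
        assert retained == [] and warnings == []

    def test_absent_variant_retained(self):
        retained, _ = tumor_only_filter([annotated()], KnowledgeBase())
        assert len(retained) == 1

    def test_hereditary_nonsubclonal_flagged(self):
        key = ("chr1", 100, "A", "T")
        kb = KnowledgeBase(hereditary_variants={key})
        high = annotated(call=call(alt_count=45, depth=100))   # VAF 0.45
        low = annotated(call=call(pos=101, alt_count=10, depth=100))
        kb.hereditary_variants.add(("chr1", 101, "A", "T"))
        retained, warnings = tumor_only_filter([high, low], kb)
        assert len(retained) == 2
        assert [w.call.pos for w in warnings] == [100]  # subclonal excluded


class TestClinicalSeries:
    def test_case_table_reproduces_printed_categories(self, registry):
        expected = {"pathogenic": ("pathogenic", "none"),
                    "likely_pathogenic": ("likely_pathogenic", "none"),
                    "dm_controversial": ("VUS", "DM_controversial"),
                    "other_vus": ("VUS", "other")}
        rows = classify_germline_case_table(registry)
        assert rows
        for variant, cls in rows:
            assert (cls.clinical_class, cls.vus_subclass) \
                == expected[variant.category], variant

    def test_germline_series_composition(self):
        rows = load_germline_case_table()
        assert len({r.case_id for r in rows}) == 36
        by_cat = {}
        for r in rows:
            by_cat.setdefault(r.category, []).append(r)
        assert len(by_cat["pathogenic"]) == 3
        assert len(by_cat["likely_pathogenic"]) == 2

    def test_somatic_series_actionability_yield(self):
        actionable, total, pct = somatic_actionability_yield()
        assert (actionable, total) == (35, 39)
        assert pct == pytest.approx(89.74, abs=0.01)

    def test_dm_controversial_tier1_prevalence(self, registry):
        hits, total, pct = dm_controversial_prevalence(registry)
        assert (hits, total) == (15, 36)
        assert pct == pytest.approx(41.67, abs=0.01)

    def test_somatic_series_covers_39_tumors(self):
        rows = load_somatic_case_table()
        assert len({r.case_id for r in rows}) == 39
        no_finding = {r.case_id for r in rows if r.alteration_type == "none"}
        assert len(no_finding) == 4
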