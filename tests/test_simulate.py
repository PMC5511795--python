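"""Synthetic-data generator: determinism, noise-model calibration, formats."""

import numpy as np
import pytest
from scipy import stats

from oncopanel.simulate import (make_reference, mix_libraries,
                                simulate_site_counts, simulate_sv_reads,
                                write_fasta, write_pileup_tsv, write_sam,
                                read_pileup_tsv)


class TestReference:
    def test_seed_determinism_byte_identical_fasta(self, tmp_path):
        paths = []
        for i in (1, 2):
            ref = make_reference(3, 2, 120, homolog_pair=True, seed=42)
            p = tmp_path / f"ref{i}.fa"
            write_fasta(ref, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_single_gene_single_exon_bed(self):
        ref = make_reference(1, 1, 100, seed=0)
        assert len(ref.regions) == 1
        assert len(ref.regions[0]) == 100

    def test_dead_zone_pair_identical_over_250bp(self, homolog_reference):
        ref = homolog_reference
        (a, b) = [r for r in ref.regions if r.gene.startswith("DEADZONE")]
        seq = ref.contigs[a.chrom]
        assert len(a) >= 250
        assert seq[a.start:a.end] == seq[b.start:b.end]

    def test_low_stringency_pair_differs_at_1_to_5_per_250(self, homolog_reference):
        ref = homolog_reference
        (a, b) = [r for r in ref.regions if r.gene.startswith("HOMOLOG")]
        seq = ref.contigs[a.chrom]
        mm = sum(x != y for x, y in zip(seq[a.start:a.end], seq[b.start:b.end]))
        windows = max(1, len(a) // 250)
        assert 1 <= mm <= 5 * windows

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            make_reference(0, 1, 100)


class TestSiteCounts:
    def test_no_variant_no_error_yields_pure_reference(self, small_reference):
        sites, _ = simulate_site_counts(small_reference, [], depth=50,
                                        error_rate=0.0, seed=1)
        assert all(not s.alt_alleles() for s in sites)

    def test_het_vaf_recovered_within_binomial_error(self, small_reference):
        region = small_reference.regions[0]
        variants = [(region.chrom, p, "A" if
                     small_reference.base_at(region.chrom, p) != "A" else "C",
                     0.5)
                    for p in range(region.start + 1, region.start + 101)]
        sites, _ = simulate_site_counts(small_reference, variants, depth=1000,
                                        error_rate=0.0, seed=5,
                                        regions=[region])
        by_pos = {s.pos: s for s in sites}
        vafs = []
        for chrom, pos, alt, _ in variants:
            s = by_pos[pos]
            vafs.append(s.counts.get(alt, 0) / s.depth)
        # analytic SE of the mean observed VAF over 100 sites at depth 1000
        se = np.sqrt(0.25 / 1000 / len(vafs))
        assert abs(np.mean(vafs) - 0.5) < max(0.02, 4 * se)

    def test_ffpe_mode_inflates_ct_class(self, small_reference):
        sites, _ = simulate_site_counts(small_reference, [], depth=500,
                                        error_rate=1e-3, ffpe_ct_rate=0.01,
                                        seed=9)
        classes = {}
        for s in sites:
            for alt in s.alt_alleles():
                if len(alt) == 1:
                    classes[(s.ref, alt)] = classes.get((s.ref, alt), 0) \
                        + s.counts[alt]
        ct = classes.get(("C", "T"), 0) + classes.get(("G", "A"), 0)
        other = sum(n for k, n in classes.items()
                    if k not in (("C", "T"), ("G", "A")))
        assert ct > other

    def test_variant_outside_reference_rejected(self, small_reference):
        with pytest.raises(ValueError, match="outside"):
            simulate_site_counts(small_reference,
                                 [("chr1", 10**9, "A", 0.5)], depth=10)

    def test_allele_counts_match_stated_model(self, small_reference):
        """Chi-square goodness of fit of alt counts over ≥10,000 sites.

        Under the stated model — depth Poisson(d), alt Binomial(depth, vaf) —
        the marginal alt count is Poisson(d·vaf) by Poisson thinning, which
        gives an exact reference distribution for the pooled counts.
        """
        region = small_reference.regions[0]
        vaf, depth = 0.3, 200
        alt_counts = []
        for seed in range(40):
            variants = [(region.chrom, p,
                         alt_for(small_reference, region.chrom, p), vaf)
                        for p in range(region.start + 1, region.end + 1)]
            sites, _ = simulate_site_counts(small_reference, variants,
                                            depth=depth, error_rate=0.0,
                                            seed=seed, regions=[region])
            for s in sites:
                alts = s.alt_alleles()
                alt_counts.append(s.counts[alts[0]] if alts else 0)
        alt_counts = np.asarray(alt_counts)
        n = len(alt_counts)
        assert n >= 10_000
        lam = depth * vaf
        lo, hi = int(lam - 4 * np.sqrt(lam)), int(lam + 4 * np.sqrt(lam))
        expected = np.array(
            [stats.poisson.cdf(lo, lam)]
            + [stats.poisson.pmf(k, lam) for k in range(lo + 1, hi)]
            + [stats.poisson.sf(hi - 1, lam)]) * n
        observed = np.array(
            [np.sum(alt_counts <= lo)]
            + [np.sum(alt_counts == k) for k in range(lo + 1, hi)]
            + [np.sum(alt_counts >= hi)])
        chi2 = np.sum((observed - expected) ** 2 / expected)
        dof = len(expected) - 1
        p_value = stats.chi2.sf(chi2, dof)
        assert p_value > 0.001


def alt_for(reference, chrom, pos):
    return "A" if reference.base_at(chrom, pos) != "A" else "C"


class TestSvReads:
    def spec(self, reference):
        a = reference.regions[0]
        b = reference.regions[-1]
        return ((a.chrom, a.start + 150), (b.chrom, b.start + 150), "+-")

    def test_full_allele_fraction_all_fused(self, small_reference):
        pairs, _ = simulate_sv_reads(small_reference,
                                     self.spec(small_reference),
                                     allele_fraction=1.0, depth=100, seed=3)
        assert all(p.insert_size == 0 for p in pairs)

    def test_split_read_clip_equals_breakpoint(self, small_reference):
        spec = self.spec(small_reference)
        pairs, _ = simulate_sv_reads(small_reference, spec,
                                     allele_fraction=1.0, depth=300, seed=4)
        splits = [p for p in pairs if p.clip_len]
        assert splits
        assert {p.clip_pos for p in splits} == {spec[0][1]}

    def test_low_fraction_support_near_binomial_expectation(self, small_reference):
        af, depth = 0.045, 2000
        pairs, _ = simulate_sv_reads(small_reference,
                                     self.spec(small_reference),
                                     allele_fraction=af, depth=depth, seed=6)
        fused = sum(1 for p in pairs if p.insert_size == 0)
        se = np.sqrt(af * (1 - af) * len(pairs))
        assert abs(fused - af * len(pairs)) < 4 * se

    def test_close_breakpoints_rejected(self, small_reference):
        chrom = small_reference.regions[0].chrom
        with pytest.raises(ValueError, match="geometry"):
            simulate_sv_reads(small_reference,
                              ((chrom, 1000), (chrom, 1050), "+-"),
                              allele_fraction=0.5, depth=10)


class TestMixing:
    def make_sites(self, reference, vaf, seed):
        region = reference.regions[0]
        variants = [(region.chrom, p, alt_for(reference, region.chrom, p), vaf)
                    for p in range(region.start + 1, region.end + 1)] \
            if vaf else []
        sites, _ = simulate_site_counts(reference, variants, depth=800,
                                        error_rate=0.0, seed=seed,
                                        regions=[region])
        return sites

    @pytest.mark.parametrize("pa,vaf_a,vaf_b,expected", [
        (0.1, 0.5, 0.0, 0.05),
        (0.5, 0.5, 0.0, 0.25),
        (1.0, 0.5, 0.0, 0.50),
    ])
    def test_expected_mixture_vaf(self, small_reference, pa, vaf_a, vaf_b,
                                  expected):
        a = self.make_sites(small_reference, vaf_a, seed=21)
        b = self.make_sites(small_reference, vaf_b, seed=22)
        mixed = mix_libraries(a, b, proportion_a=pa, seed=23)
        vafs = []
        for s in mixed:
            alts = s.alt_alleles()
            vafs.append(s.counts[alts[0]] / s.depth if alts else 0.0)
        assert abs(np.mean(vafs) - expected) < 0.01

    def test_mismatched_sites_rejected(self, small_reference):
        a = self.make_sites(small_reference, 0.5, seed=1)
        with pytest.raises(ValueError, match="identical site"):
            mix_libraries(a, a[:-1], 0.5)


class TestTextFormats:
    def test_pileup_roundtrip(self, small_reference, tmp_path):
        region = small_reference.regions[0]
        sites, _ = simulate_site_counts(small_reference, [], depth=30, seed=2,
                                        regions=[region])
        p = tmp_path / "pileup.tsv"
        write_pileup_tsv(sites, p)
        back = read_pileup_tsv(p)
        assert [(s.chrom, s.pos, s.ref, s.counts) for s in sites] == \
               [(s.chrom, s.pos, s.ref, s.counts) for s in back]

    def test_sam_output_parses_with_pysam(self, small_reference, tmp_path):
        pysam = pytest.importorskip("pysam")
        pairs, _ = simulate_sv_reads(
            small_reference,
            ((small_reference.regions[0].chrom,
              small_reference.regions[0].start + 150),
             (small_reference.regions[-1].chrom,
              small_reference.regions[-1].start + 150), "+-"),
            allele_fraction=0.5, depth=50, seed=8)
        p = tmp_path / "reads.sam"
        write_sam(pairs, small_reference, p)
        with pysam.AlignmentFile(str(p), "r") as sam:
            records = list(sam)
        assert len(records) == 2 * len(pairs)
        assert all(r.is_paired for r in records)
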