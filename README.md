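# oncopanel

A testable re-implementation of a targeted hybrid-capture NGS platform for
somatic and germline precision oncology. It is written for bioinformaticians
and molecular-diagnostics developers who want the platform's decision logic —
not its wet lab — as inspectable, unit-tested code:

* **Panel registry** — three subpanels of one capture design (97 somatic
  SNV/indel/CNV genes + 17 rearrangement genes; 148 germline genes on a
  Tier-1a/1b/2 system; 64 research-only genes) with tier-aware
  reportability rules.
* **Sample & coverage QC** — Q/N-ratio sample qualification, per-base
  callability at DP10–DP500, target-sequence gaps (<20 passing reads), and
  the callability-driven probe-density redesign heuristic.
* **Small-variant calling** — germline (depth ≥6, alt ≥3, VAF ≥0.1) and
  paired tumor–normal (VAF ≥0.025) calling on quality-passing allele
  counts, with hotspot rescue of below-threshold database variants, a
  recurrent-artifact blacklist, and a locus-restricted mode for homology
  dead zones.
* **SV & CNV calling** — breakpoint detection from discordant pairs and
  split reads at single-base resolution; per-gene log2 depth ratios
  against a background pool corroborated by allelic imbalance.
* **Classification & reporting** — the somatic actionability and germline
  pathogenicity rule engines, the tumor-only population-frequency filter,
  and the five report modalities driven by request aim, sample
  availability and consent scope.
* **Synthetic data & validation** — seeded generators for references,
  pileups, fusion read pairs and library mixtures, plus confusion-matrix
  and frequency-concordance harnesses.

## Worked example

A paired tumor–normal run on simulated data, end to end:

```python
import oncopanel as op

ref = op.make_reference(n_genes=2, exons_per_gene=2, exon_len=250, seed=1)
chrom, pos = ref.regions[0].chrom, ref.regions[0].start + 40
alt = "A" if ref.base_at(chrom, pos) != "A" else "C"

tumor, truth = op.simulate_site_counts(ref, [(chrom, pos, alt, 0.06)],
                                       depth=950, error_rate=1e-3, seed=2)
normal, _ = op.simulate_site_counts(ref, [], depth=950, error_rate=1e-3,
                                    seed=3)
calls = op.call_somatic_paired(tumor, normal)
for c in calls:
    print(c.chrom, c.pos, c.ref, ">", c.alt,
          f"VAF={c.vaf:.3f}", c.origin, c.status)
```

prints (seed-reproducible):

```
chr1 540 C > A VAF=0.074 somatic pass
```

a low-frequency tumor-private variant called somatic because the matched normal
shows no germline-level support at that site. The same objects flow into
`compute_callability`, `classify_somatic`/`classify_germline` and
`build_report`.

The bundled clinical tables reproduce the platform's published figures:

```python
op.somatic_actionability_yield()        # (35, 39, 89.74…)
reg = op.load_default_panel()
op.dm_controversial_prevalence(reg)     # (15, 36, 41.67…)
op.frequency_correlation(op.load_emqn_pairs([1, 2, 3])).r   # 0.9952…
```

— 35 of 39 tumors with ≥1 drug-associated alteration, 15 of 36 germline
cases with a Tier-1 DM-Controversial variant, and Pearson concordance of
0.9952 between NGS and ddPCR allele frequencies over the
quality-assessment samples.

A thin CLI mirrors the common entry points, e.g. `oncopanel panel summary`,
`oncopanel simulate reference`, `oncopanel emqn`, `oncopanel report`.

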