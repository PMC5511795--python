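"""Variant annotation and clinical classification rules.

Somatic actionability: a tumor variant is eligible for reporting when its
population frequency is below 0.05 in all four population databases (dbSNP,
1000 Genomes, ESP, ExAC; absent counts as 0) and it is either recorded as a
somatic mutation in COSMIC/ICGC or predicted to alter the protein sequence.
An eligible variant matched in the drug-association knowledge base becomes
*actionable*, carrying its drugs (with sensitivity/resistance direction)
and the evidence level of the association; an eligible variant without a
match is a somatic VUS; an ineligible variant is not reported.

Germline pathogenicity, three categories:

* *pathogenic* — an HGMD disease-causing mutation (DM) whose literature
  support was judged solid on expert review, at population frequency <0.05
  in all four databases;
* *likely pathogenic* — not DM, protein-drastic (nonsense, start loss,
  splice disruption or frameshift), in a gene whose germline loss of
  function raises cancer risk, at frequency <0.01;
* *VUS* — everything else below frequency 0.01 (subclass ``other``); DM
  entries with controversial support below 0.05 (subclass
  ``DM_controversial``); and would-be likely-pathogenic variants whose
  frequency falls in [0.01, 0.05) (subclass ``freq_band``).

Variants matching none of these (e.g. a non-DM missense at frequency
0.01–0.05) are not reported.  The solid-vs-controversial judgement on DM
entries is an expert-curated input flag in the knowledge base; the engine
consumes it and never infers it.

Without a matched normal, the tumor-only filter removes putative germline
polymorphisms (frequency ≥0.05 in any database) and raises a hereditary-
cancer warning for retained, non-subclonal (VAF ≥0.3) calls whose variant
is a known hereditary-cancer mutation.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from .calling import VariantCall, VariantKey
from .panel import PanelRegistry, normalize_symbol

POPULATION_DATABASES = ("dbSNP", "1000G", "ESP", "ExAC")
SOMATIC_MAX_POP_FREQ = 0.05
GERMLINE_DM_MAX_FREQ = 0.05
GERMLINE_LP_MAX_FREQ = 0.01
SUBCLONAL_VAF = 0.3

PROTEIN_IMPACTING = frozenset({
    "missense", "nonsense", "frameshift", "splice", "start_loss",
    "inframe_indel"})
DRASTIC_CONSEQUENCES = frozenset({
    "nonsense", "start_loss", "splice", "frameshift"})

EVIDENCE_LEVELS = ("FDA_EMA", "NCCN_CAP", "advanced_trial",
                   "preliminary_trial", "clinical_case", "preclinical")


@dataclass
class AnnotatedVariant:
    call: VariantCall
    gene: str = ""
    tier: str = "none"
    consequence: str = "noncoding"
    pop_freqs: dict[str, float] = field(default_factory=dict)
    in_cosmic: bool = False
    in_icgc: bool = False
    hgmd_status: str = "none"  # none | DM_solid | DM_controversial
    lof_cancer_gene: bool = False
    predictor_scores: dict[str, float] = field(default_factory=dict)
    isoform_note: str = ""

    @property
    def max_pop_freq(self) -> float:
        """Maximum frequency over the four databases; absent counts as 0."""
        return max((self.pop_freqs.get(db, 0.0) for db in POPULATION_DATABASES),
                   default=0.0)


@dataclass
class DrugAssociation:
    drug: str
    direction: str          # sensitivity | resistance
    evidence_level: str = "FDA_EMA"
    tumor_context: str = ""


@dataclass
class ClassifiedVariant:
    annotated: AnnotatedVariant
    clinical_class: str     # actionable | somatic_VUS | not_reported |
                            # pathogenic | likely_pathogenic | VUS
    vus_subclass: str = "none"   # none | DM_controversial | freq_band | other
    evidence_level: str = ""
    drug_associations: list[DrugAssociation] = field(default_factory=list)

    @property
    def gene(self) -> str:
        return self.annotated.gene


class KnowledgeBaseError(ValueError):
    pass


@dataclass
class KnowledgeBase:
    """Mock annotation tables standing in for the external databases.

    ``pop_freqs`` maps variant keys to per-database germline frequencies;
    ``cosmic``/``icgc`` are sets of somatic variant keys; ``hgmd`` maps keys
    to a status carrying the expert curation ("DM_solid"/"DM_controversial");
    ``lof_cancer_genes`` lists genes whose germline loss of function is
    cancer-predisposing; ``hereditary_variants`` keys known hereditary-cancer
    mutations for tumor-only warnings; ``consequences`` optionally overrides
    the HGVS-derived consequence per variant key.
    """

    pop_freqs: dict[VariantKey, dict[str, float]] = field(default_factory=dict)
    cosmic: set[VariantKey] = field(default_factory=set)
    icgc: set[VariantKey] = field(default_factory=set)
    hgmd: dict[VariantKey, str] = field(default_factory=dict)
    lof_cancer_genes: set[str] = field(default_factory=set)
    hereditary_variants: set[VariantKey] = field(default_factory=set)
    consequences: dict[VariantKey, str] = field(default_factory=dict)
    genes_by_site: dict[tuple[str, int], str] = field(default_factory=dict)
    predictor_scores: dict[VariantKey, dict[str, float]] = field(default_factory=dict)


def consequence_from_hgvs(hgvs_c: str, hgvs_p: str = "") -> str:
    """Infer a coarse consequence class from HGVS notation.

    Recognizes frameshift (``fs``), stop gains (``*`` / ``Ter``), start
    loss (``p.M1``), synonymous (identical flanking residues / ``=``),
    in-frame indels, canonical ±1/2 splice-site positions and UTR/intronic
    noncoding changes; anything else coding defaults to missense.
    """
    p = (hgvs_p or "").replace("p.", "")
    c = hgvs_c or ""
    if "fs" in p:
        return "frameshift"
    if p.endswith("*") or "Ter" in p or re.search(r"\*\d*$", p):
        return "nonsense"
    if re.match(r"^M1[^0-9]", p) or p == "M1?":
        return "start_loss"
    if re.search(r"[+-][12](?![0-9])[ACGT]?>", c.replace(" ", "")):
        return "splice"
    if c.startswith(("c.-", "c.*")) or re.match(r"^c\.[-*]", c):
        return "noncoding"
    if re.search(r"c\.\d+[+-]\d+", c):
        return "noncoding"  # deeper intronic
    if re.match(r"^([A-Z])(\d+)\1$", p):
        return "synonymous"
    if ("del" in p or "ins" in p or "dup" in p) and "fs" not in p:
        return "inframe_indel"
    if re.match(r"^[A-Z]\d+[A-Z]$", p):
        return "missense"
    if ("del" in c or "ins" in c or "dup" in c) and not p:
        return "noncoding"
    return "missense" if p else "noncoding"


def annotate_variant(call: VariantCall, kb: KnowledgeBase,
                     registry: PanelRegistry | None = None,
                     gene: str = "") -> AnnotatedVariant:
    """Join a call with every knowledge-base table.

    Missing rows are explicit absences: flags false, frequencies absent
    (treated as 0 by the frequency rules).
    """
    key = call.key
    symbol = gene or kb.genes_by_site.get((call.chrom, call.pos), "")
    symbol, note = normalize_symbol(symbol) if symbol else ("", "")
    tier = registry.germline_tier(symbol) if (registry and symbol) else "none"
    freqs = kb.pop_freqs.get(key, {})
    for db, f in freqs.items():
        if db not in POPULATION_DATABASES:
            raise KnowledgeBaseError(f"unknown population database {db!r} "
                                     f"for {key}")
        if not 0 <= f <= 1:
            raise KnowledgeBaseError(f"frequency {f} out of range for {key}")
    hgmd = kb.hgmd.get(key, "none")
    if hgmd not in ("none", "DM_solid", "DM_controversial"):
        raise KnowledgeBaseError(f"bad HGMD status {hgmd!r} for {key}")
    return AnnotatedVariant(
        call=call, gene=symbol, tier=tier,
        consequence=kb.consequences.get(key, "noncoding"),
        pop_freqs=dict(freqs),
        in_cosmic=key in kb.cosmic, in_icgc=key in kb.icgc,
        hgmd_status=hgmd,
        lof_cancer_gene=symbol in kb.lof_cancer_genes,
        predictor_scores=dict(kb.predictor_scores.get(key, {})),
        isoform_note=note)


# ---------------------------------------------------------------------------
# somatic classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugRule:
    """One drug-association KB row, at one of three match granularities:
    exact variant, variant-class pattern, or gene level."""

    gene: str
    drug: str
    direction: str = "sensitivity"
    evidence_level: str = "FDA_EMA"
    tumor_context: str = ""
    hgvs_c: str = ""            # exact-variant match when set
    consequence: str = ""       # pattern match: gene + consequence
    codon_range: tuple[int, int] | None = None

    @property
    def specificity(self) -> int:
        if self.hgvs_c:
            return 2
        if self.consequence or self.codon_range:
            return 1
        return 0

    def matches(self, gene: str, hgvs_c: str, consequence: str,
                codon: int | None, tumor_type: str) -> bool:
        if self.gene != gene:
            return False
        if self.tumor_context and self.tumor_context != tumor_type:
            return False
        if self.hgvs_c:
            return self.hgvs_c == hgvs_c
        if self.consequence and self.consequence != consequence:
            return False
        if self.codon_range is not None:
            if codon is None:
                return False
            lo, hi = self.codon_range
            if not lo <= codon <= hi:
                return False
        return True


def _codon_of(hgvs_p: str) -> int | None:
    m = re.search(r"[A-Z](\d+)", (hgvs_p or "").replace("p.", ""))
    return int(m.group(1)) if m else None


def classify_somatic(av: AnnotatedVariant, drug_kb: Sequence[DrugRule],
                     tumor_type: str = "", hgvs_c: str = "",
                     hgvs_p: str = "") -> ClassifiedVariant:
    """Somatic actionability classification of an annotated tumor variant.

    Eligibility requires frequency <0.05 in all four population databases
    and (COSMIC or ICGC membership, or a protein-impacting consequence).
    The most specific drug-KB match wins: exact variant, then variant-class
    pattern (gene + consequence and/or codon range), then gene level; all
    rules at the winning specificity contribute their drugs.
    """
    eligible = (av.max_pop_freq < SOMATIC_MAX_POP_FREQ
                and (av.in_cosmic or av.in_icgc
                     or av.consequence in PROTEIN_IMPACTING))
    if not eligible:
        return ClassifiedVariant(av, "not_reported")
    codon = _codon_of(hgvs_p)
    matches = [r for r in drug_kb
               if r.matches(av.gene, hgvs_c, av.consequence, codon, tumor_type)]
    if not matches:
        return ClassifiedVariant(av, "somatic_VUS")
    best = max(r.specificity for r in matches)
    winning = [r for r in matches if r.specificity == best]
    drugs = [DrugAssociation(r.drug, r.direction, r.evidence_level,
                             r.tumor_context) for r in winning]
    level = min((d.evidence_level for d in drugs),
                key=lambda lv: EVIDENCE_LEVELS.index(lv))
    return ClassifiedVariant(av, "actionable", evidence_level=level,
                             drug_associations=drugs)


# ---------------------------------------------------------------------------
# germline classification
# ---------------------------------------------------------------------------

def classify_germline(av: AnnotatedVariant) -> ClassifiedVariant:
    """Three-category germline pathogenicity classification.

    Total and deterministic in the annotation fields; the three categories
    (plus not_reported) are mutually exclusive.  Frequency comparisons are
    strict ``<`` and an absent frequency counts as 0.
    """
    freq = av.max_pop_freq
    if av.hgmd_status == "DM_solid" and freq < GERMLINE_DM_MAX_FREQ:
        return ClassifiedVariant(av, "pathogenic")
    drastic_lof = (av.hgmd_status == "none"
                   and av.consequence in DRASTIC_CONSEQUENCES
                   and av.lof_cancer_gene)
    if drastic_lof and freq < GERMLINE_LP_MAX_FREQ:
        return ClassifiedVariant(av, "likely_pathogenic")
    if av.hgmd_status == "DM_controversial" and freq < GERMLINE_DM_MAX_FREQ:
        return ClassifiedVariant(av, "VUS", vus_subclass="DM_controversial")
    if drastic_lof and GERMLINE_LP_MAX_FREQ <= freq < GERMLINE_DM_MAX_FREQ:
        return ClassifiedVariant(av, "VUS", vus_subclass="freq_band")
    if freq < GERMLINE_LP_MAX_FREQ:
        return ClassifiedVariant(av, "VUS", vus_subclass="other")
    return ClassifiedVariant(av, "not_reported")


# ---------------------------------------------------------------------------
# tumor-only mode
# ---------------------------------------------------------------------------

def tumor_only_filter(annotated: Iterable[AnnotatedVariant],
                      kb: KnowledgeBase,
                      subclonal_vaf: float = SUBCLONAL_VAF
                      ) -> tuple[list[AnnotatedVariant], list[AnnotatedVariant]]:
    """Population-frequency germline filter for unmatched tumors.

    Removes calls with frequency ≥0.05 in at least one of the four
    population databases (putative common germline alleles).  Among the
    retained calls, those that are non-subclonal (VAF ≥ ``subclonal_vaf``)
    and known hereditary-cancer mutations are returned separately so the
    report can carry a germline-testing warning.
    """
    retained: list[AnnotatedVariant] = []
    warnings: list[AnnotatedVariant] = []
    for av in annotated:
        if any(av.pop_freqs.get(db, 0.0) >= SOMATIC_MAX_POP_FREQ
               for db in POPULATION_DATABASES):
            continue
        retained.append(av)
        if (av.call.vaf >= subclonal_vaf
                and av.call.key in kb.hereditary_variants):
            warnings.append(av)
    return retained, warnings


# ---------------------------------------------------------------------------
# bundled clinical case tables
# ---------------------------------------------------------------------------

@dataclass
class SomaticCaseAlteration:
    case_id: str
    tumor_type: str
    gene: str
    alteration_type: str    # snv | amplification | deletion | structural | none
    hgvs_c: str
    hgvs_p: str
    drugs: list[DrugAssociation]


@dataclass
class GermlineCaseVariant:
    case_id: str
    gene: str
    hgvs_c: str
    hgvs_p: str
    zygosity: str
    category: str   # pathogenic | likely_pathogenic | dm_controversial |
                    # other_vus | none (variant-free case)
    isoform_note: str = ""


def _data_file(name: str):
    return resources.files("oncopanel.data") / name


def load_somatic_case_table(path=None) -> list[SomaticCaseAlteration]:
    """The 39-tumor clinical series with its drug associations."""
    path = path or _data_file("somatic_cases.tsv")
    rows: list[SomaticCaseAlteration] = []
    with path.open() if hasattr(path, "open") else open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            drugs = []
            for token in filter(None, row["drugs"].split(";")):
                token = token.strip()
                direction = "sensitivity"
                for marker in ("(no response)", "(resistance)"):
                    if marker in token:
                        token = token.replace(marker, "").strip()
                        direction = "resistance"
                drugs.append(DrugAssociation(token, direction))
            rows.append(SomaticCaseAlteration(
                row["case_id"], row["tumor_type"], row["gene"],
                row["alteration_type"], row["hgvs_c"], row["hgvs_p"], drugs))
    return rows


def load_germline_case_table(path=None) -> list[GermlineCaseVariant]:
    """The 36-sample germline clinical series with printed categories."""
    path = path or _data_file("germline_cases.tsv")
    rows: list[GermlineCaseVariant] = []
    with path.open() if hasattr(path, "open") else open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            symbol, note = (normalize_symbol(row["gene"]) if row["gene"]
                            else ("", ""))
            rows.append(GermlineCaseVariant(
                row["case_id"], symbol, row["hgvs_c"], row["hgvs_p"],
                row["zygosity"], row["category"], isoform_note=note))
    return rows


def _case_variant_to_annotated(v: GermlineCaseVariant,
                               registry: PanelRegistry | None
                               ) -> AnnotatedVariant:
    """Reconstruct the annotation a case-table variant carried.

    The HGMD status and curation flag follow from the printed category
    (the curation is an expert input, encoded in the fixture); frequencies
    use the reporting-band midpoints: effectively absent (0) for
    pathogenic/likely-pathogenic calls, <0.01 for plain VUS, <0.05 for
    DM entries.
    """
    consequence = consequence_from_hgvs(v.hgvs_c, v.hgvs_p)
    hgmd = {"pathogenic": "DM_solid",
            "dm_controversial": "DM_controversial"}.get(v.category, "none")
    freq = 0.0 if v.category in ("pathogenic", "likely_pathogenic") else 0.001
    call = VariantCall(chrom="panel", pos=0, ref="N", alt="N",
                       alt_count=50, depth=100)
    tier = registry.germline_tier(v.gene) if registry else "none"
    return AnnotatedVariant(
        call=call, gene=v.gene, tier=tier, consequence=consequence,
        pop_freqs={db: freq for db in POPULATION_DATABASES},
        hgmd_status=hgmd, lof_cancer_gene=True, isoform_note=v.isoform_note)


def classify_germline_case_table(registry: PanelRegistry | None = None,
                                 path=None) -> list[tuple[GermlineCaseVariant,
                                                          ClassifiedVariant]]:
    """Run the germline rule engine over the bundled clinical series."""
    out = []
    for v in load_germline_case_table(path):
        if v.category == "none":
            continue
        out.append((v, classify_germline(_case_variant_to_annotated(v,
                                                                    registry))))
    return out


def somatic_actionability_yield(path=None) -> tuple[int, int, float]:
    """(actionable cases, total cases, percent) over the clinical series.

    A case counts as actionable when the rule engine labels at least one of
    its alterations actionable, with the drug KB built from the series'
    own association table.
    """
    rows = load_somatic_case_table(path)
    drug_kb: list[DrugRule] = []
    for r in rows:
        key_c = r.hgvs_c if r.alteration_type == "snv" else r.alteration_type
        for d in r.drugs:
            drug_kb.append(DrugRule(gene=r.gene, drug=d.drug,
                                    direction=d.direction, hgvs_c=key_c))
    cases: dict[str, bool] = {}
    for r in rows:
        cases.setdefault(r.case_id, False)
        if r.alteration_type == "none":
            continue
        av = AnnotatedVariant(
            call=VariantCall(chrom="panel", pos=0, ref="N", alt="N",
                             alt_count=30, depth=100),
            gene=r.gene,
            consequence=(consequence_from_hgvs(r.hgvs_c, r.hgvs_p)
                         if r.alteration_type == "snv" else "noncoding"),
            in_cosmic=True)
        key_c = r.hgvs_c if r.alteration_type == "snv" else r.alteration_type
        cls = classify_somatic(av, drug_kb, hgvs_c=key_c, hgvs_p=r.hgvs_p)
        if cls.clinical_class == "actionable" and cls.drug_associations:
            cases[r.case_id] = True
    n_actionable = sum(cases.values())
    n_total = len(cases)
    return n_actionable, n_total, 100.0 * n_actionable / n_total


def dm_controversial_prevalence(registry: PanelRegistry, path=None
                                ) -> tuple[int, int, float]:
    """(cases with a Tier-1-gene DM-Controversial variant, total, percent).

    Counts clinical-series cases carrying at least one variant that the
    rule engine classifies as VUS of subclass DM_controversial in a Tier-1
    germline gene.
    """
    variants = load_germline_case_table(path)
    cases = {v.case_id for v in variants}
    hit_cases = set()
    for v, cls in classify_germline_case_table(registry, path):
        if (cls.clinical_class == "VUS"
                and cls.vus_subclass == "DM_controversial"
                and registry.germline_tier(v.gene) in ("1a", "1b")):
            hit_cases.add(v.case_id)
    return len(hit_cases), len(cases), 100.0 * len(hit_cases) / len(cases)
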