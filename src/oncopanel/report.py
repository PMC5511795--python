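"""Report-modality selection and structured report assembly.

Five request situations, defined by the aim of the request, the available
samples and the scope of the germline informed consent, determine which
subpanels are analyzed, how tumor-specific variants are filtered and what
may be disclosed:

1. therapeutic aim, tumor only — somatic subpanel with the population-
   frequency germline filter; hereditary findings surface only as warnings;
2. therapeutic aim, tumor + germline, no consent — paired tumor–normal
   subtraction plus a parallel germline search for therapeutically relevant
   variants; hereditary findings reported "as present in the tumor" with a
   warning, never as explicit germline results;
3. as 2 with consent — hereditary germline findings disclosed explicitly;
4. therapeutic + counseling aims, tumor + germline, consent — somatic and
   full germline subpanels, two-section *Complete* report;
5. counseling aim, germline only, consent — germline report, optionally
   restricted to Tier-1a genes.

Counseling without consent, or a request without samples, is rejected.
The parallel germline search of modalities 2–4 exists so that paired
subtraction can never hide a drug-relevant variant present in both tumor
and germline: such variants are re-injected into the therapeutic section.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

from .interpret import ClassifiedVariant
from .qc import CallabilityReport, SampleQC

AIMS = ("therapeutic", "counseling", "both")


class ContextError(ValueError):
    """An invalid or unsupported request-context combination."""


@dataclass(frozen=True)
class RequestContext:
    aim: str
    tumor_sample: bool = False
    germline_sample: bool = False
    germline_consent: bool = False
    syndromic: bool = False
    tier1a_only: bool = False

    def validate(self) -> None:
        if self.aim not in AIMS:
            raise ContextError(f"unknown aim {self.aim!r}")
        if not (self.tumor_sample or self.germline_sample):
            raise ContextError("no sample available")
        if self.aim in ("counseling", "both") and not self.germline_sample:
            raise ContextError("counseling aim requires a germline sample")
        if self.aim in ("counseling", "both") and not self.germline_consent:
            raise ContextError("consent required for germline reporting")


@dataclass
class ModalityConfig:
    modality: int                 # 1-5
    report_type: str              # somatic | germline | complete
    panels: tuple[str, ...]       # subpanels analyzed
    tumor_filter: str             # population_frequency | paired_subtraction | none
    germline_comment_mode: str    # warning_only | explicit | full_report | none
    parallel_germline_search: bool = False
    tier1a_only: bool = False
    syndromic: bool = False


def select_modality(ctx: RequestContext) -> ModalityConfig:
    """Map a request context onto one of the five pipeline configurations.

    Total over the five supported situations; every other combination is
    rejected with a :class:`ContextError`.
    """
    ctx.validate()
    if ctx.aim == "therapeutic":
        if ctx.tumor_sample and not ctx.germline_sample:
            return ModalityConfig(1, "somatic", ("somatic",),
                                  "population_frequency", "warning_only")
        if ctx.tumor_sample and ctx.germline_sample:
            if not ctx.germline_consent:
                return ModalityConfig(2, "somatic", ("somatic",),
                                      "paired_subtraction", "warning_only",
                                      parallel_germline_search=True)
            return ModalityConfig(3, "somatic", ("somatic",),
                                  "paired_subtraction", "explicit",
                                  parallel_germline_search=True)
        raise ContextError("therapeutic aim requires a tumor sample")
    if ctx.aim == "both":
        if not ctx.tumor_sample:
            raise ContextError("combined aims require a tumor sample")
        return ModalityConfig(4, "complete", ("somatic", "germline"),
                              "paired_subtraction", "full_report",
                              parallel_germline_search=True,
                              tier1a_only=ctx.tier1a_only,
                              syndromic=ctx.syndromic)
    # counseling
    if ctx.tumor_sample:
        raise ContextError("counseling-only requests take a germline sample "
                           "only")
    return ModalityConfig(5, "germline", ("germline",), "none", "full_report",
                          tier1a_only=ctx.tier1a_only, syndromic=ctx.syndromic)


@dataclass
class ReportBundle:
    modality: int
    report_type: str
    actionable: list[dict] = field(default_factory=list)
    germline_findings: dict[str, list[dict]] = field(default_factory=dict)
    vus: list[dict] = field(default_factory=list)
    additional_comments: list[str] = field(default_factory=list)
    technical: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    def render_text(self) -> str:
        lines = [f"=== Report (modality {self.modality}, "
                 f"{self.report_type}) ==="]
        if self.report_type in ("somatic", "complete"):
            lines.append("-- Therapeutically relevant alterations --")
            if not self.actionable:
                lines.append("  none identified")
            for a in self.actionable:
                drugs = ", ".join(
                    d["drug"] + (" (resistance)" if d["direction"] ==
                                 "resistance" else "")
                    for d in a["drugs"])
                lines.append(f"  {a['gene']} {a['variant']}"
                             f" [{a['evidence_level']}]: {drugs}")
        if self.report_type in ("germline", "complete"):
            lines.append("-- Germline findings --")
            for cat in ("pathogenic", "likely_pathogenic", "VUS"):
                for v in self.germline_findings.get(cat, []):
                    lines.append(f"  [{cat}] {v['gene']} {v['variant']}")
        if self.vus:
            lines.append("-- Variants of uncertain significance --")
            for v in self.vus:
                lines.append(f"  {v['gene']} {v['variant']}")
        lines.append("-- Additional comments --")
        for c in self.additional_comments or ["none"]:
            lines.append(f"  {c}")
        lines.append("-- Technical performance --")
        for k, v in self.technical.items():
            lines.append(f"  {k}: {v}")
        return "\n".join(lines)


def _variant_label(cv: ClassifiedVariant) -> str:
    call = cv.annotated.call
    if call.pos:
        return f"{call.chrom}:{call.pos} {call.ref}>{call.alt}"
    return "(panel variant)"


def _actionable_entry(cv: ClassifiedVariant, note: str = "") -> dict:
    return {
        "gene": cv.gene,
        "variant": _variant_label(cv),
        "evidence_level": cv.evidence_level,
        "drugs": [asdict(d) for d in cv.drug_associations],
        "origin": cv.annotated.call.origin,
        "note": note,
    }


def build_report(somatic_variants: Sequence[ClassifiedVariant],
                 germline_variants: Sequence[ClassifiedVariant],
                 qc: tuple[SampleQC | None, CallabilityReport | None],
                 config: ModalityConfig,
                 hereditary_warnings: Sequence[ClassifiedVariant] = (),
                 pertinent_negatives: Sequence[str] = ()) -> ReportBundle:
    """Assemble the structured report for a modality configuration.

    ``somatic_variants`` are the classified tumor findings after the
    modality's tumor filter; ``germline_variants`` are classified germline
    findings (for modalities 2–3 these are the parallel-search results and
    feed the therapeutic section rather than a germline section).
    """
    if config.report_type == "germline" and somatic_variants:
        raise ContextError("germline-only report cannot carry somatic "
                           "variants")
    if config.report_type == "somatic" and config.modality == 1 \
            and germline_variants:
        raise ContextError("tumor-only modality has no germline variant set")

    bundle = ReportBundle(config.modality, config.report_type)
    sample_qc, callability = qc

    seen: set = set()
    for cv in somatic_variants:
        if cv.clinical_class == "actionable":
            bundle.actionable.append(_actionable_entry(cv))
            seen.add((cv.gene, _variant_label(cv)))
        elif cv.clinical_class == "somatic_VUS":
            bundle.vus.append({"gene": cv.gene, "variant": _variant_label(cv)})

    # anti-subtraction re-injection: drug-relevant germline findings of the
    # parallel search always reach the therapeutic section (reported "as
    # present in the tumor")
    if config.parallel_germline_search:
        for cv in germline_variants:
            if cv.clinical_class == "actionable" \
                    and (cv.gene, _variant_label(cv)) not in seen:
                bundle.actionable.append(_actionable_entry(
                    cv, note="identified in the germline sample; reported as "
                             "present in the tumor"))

    if config.germline_comment_mode == "full_report":
        for cv in germline_variants:
            if cv.clinical_class in ("pathogenic", "likely_pathogenic", "VUS"):
                entry = {"gene": cv.gene, "variant": _variant_label(cv),
                         "vus_subclass": cv.vus_subclass}
                bundle.germline_findings.setdefault(
                    cv.clinical_class, []).append(entry)
    elif config.germline_comment_mode == "explicit":
        for cv in germline_variants:
            if cv.clinical_class == "pathogenic":
                bundle.additional_comments.append(
                    f"Germline pathogenic variant disclosed per consent: "
                    f"{cv.gene} {_variant_label(cv)}")

    for cv in hereditary_warnings:
        bundle.additional_comments.append(
            f"Warning: {cv.gene} {_variant_label(cv)} is a known hereditary-"
            f"cancer mutation when germline; genetic counseling and targeted "
            f"germline testing are advised")
    for neg in pertinent_negatives:
        bundle.additional_comments.append(f"Pertinent negative: {neg}")

    if sample_qc is not None:
        bundle.technical["sample_qc"] = sample_qc.to_dict()
    if callability is not None:
        bundle.technical["callability_dp100"] = callability.total_fraction(100)
        bundle.technical["gaps"] = [list(g) for g in callability.gaps]
    return bundle
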