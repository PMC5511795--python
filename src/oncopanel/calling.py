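"""Germline and paired tumor–normal SNV/indel calling.

The callers operate on quality-passing allele counts (reads with base
quality ≥20 and mapping quality ≥30; VAF is computed on that passing depth).
Threshold contract:

* germline: total depth ≥6, mutated allele count ≥3, VAF ≥0.1;
* somatic (tumor sample): depth ≥6, alt count ≥3, VAF ≥0.025, with the
  somatic/germline origin of each tumor call decided by interrogating the
  matched normal — a tumor variant whose site independently passes the
  germline caller in the normal is of germline origin, a site covered in the
  normal without germline-level support is somatic, and a site without
  normal coverage stays undetermined.

Two salvage layers complete the caller: a *rescue* layer that routes
below-threshold candidates present in a hotspot database (COSMIC-like for
somatic, HGMD-like for germline) to a separate output instead of silently
dropping them, and a recurrent-error filter driven by a blacklist of
site/substitution artifacts learned from previously evaluated samples.

Homology dead zones (≥250 bp of perfect identity with another locus) get a
dedicated mode: whole-genome alignment leaves them uncallable (all reads at
mapping quality 0), while realignment against a single-locus reference
restores sensitivity at the cost of specificity, so every dead-zone call is
flagged as requiring orthogonal confirmation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .panel import TargetRegion
from .simulate import SiteCounts

GERMLINE_MIN_DEPTH = 6
GERMLINE_MIN_ALT = 3
GERMLINE_MIN_VAF = 0.1
SOMATIC_MIN_VAF = 0.025

VariantKey = tuple[str, int, str, str]  # chrom, pos, ref, alt


@dataclass
class VariantCall:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    alt_count: int
    depth: int
    origin: str = "undetermined"  # germline | somatic | undetermined
    status: str = "pass"          # pass | rescued | filtered
    filter_reasons: list[str] = field(default_factory=list)
    needs_orthogonal_confirmation: bool = False

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


def passes_thresholds(depth: int, alt_count: int, min_depth: int,
                      min_alt: int, min_vaf: float) -> bool:
    """The caller's threshold predicate, shared by all entry points."""
    if depth < min_depth or alt_count < min_alt:
        return False
    return alt_count / depth >= min_vaf


def _candidates(site: SiteCounts) -> Iterable[tuple[str, int]]:
    for alt in site.alt_alleles():
        yield alt, site.counts[alt]


def call_germline(sites: Iterable[SiteCounts],
                  min_depth: int = GERMLINE_MIN_DEPTH,
                  min_alt: int = GERMLINE_MIN_ALT,
                  min_vaf: float = GERMLINE_MIN_VAF) -> list[VariantCall]:
    """Emit passing germline calls (depth ≥6, alt ≥3, VAF ≥0.1).

    Multi-allelic sites yield one record per alternate allele.  Candidates
    failing the thresholds are absent from the output; route them through
    :func:`apply_rescue` to recover database-listed hotspots.
    """
    calls = []
    for site in sites:
        depth = site.depth
        for alt, n in _candidates(site):
            if passes_thresholds(depth, n, min_depth, min_alt, min_vaf):
                calls.append(VariantCall(site.chrom, site.pos, site.ref, alt,
                                         n, depth, origin="germline"))
    return calls


def call_somatic_paired(tumor_sites: Sequence[SiteCounts],
                        normal_sites: Sequence[SiteCounts],
                        min_depth: int = GERMLINE_MIN_DEPTH,
                        min_alt: int = GERMLINE_MIN_ALT,
                        min_vaf: float = SOMATIC_MIN_VAF) -> list[VariantCall]:
    """Paired tumor–normal calling with per-variant origin assignment.

    Tumor candidates pass at depth ≥6, alt ≥3, VAF ≥0.025; each passing
    variant is then interrogated in the normal.  Low-level support in the
    normal below the germline thresholds does not block a somatic label
    (no contamination margin is applied).
    """
    normal_at: dict[tuple[str, int], SiteCounts] = {
        (s.chrom, s.pos): s for s in normal_sites}
    calls = []
    for site in tumor_sites:
        depth = site.depth
        for alt, n in _candidates(site):
            if not passes_thresholds(depth, n, min_depth, min_alt, min_vaf):
                continue
            call = VariantCall(site.chrom, site.pos, site.ref, alt, n, depth)
            normal = normal_at.get((site.chrom, site.pos))
            if normal is None or normal.depth == 0:
                call.origin = "undetermined"
                call.filter_reasons.append("no_normal_coverage")
            elif passes_thresholds(normal.depth, normal.counts.get(alt, 0),
                                   GERMLINE_MIN_DEPTH, GERMLINE_MIN_ALT,
                                   GERMLINE_MIN_VAF):
                call.origin = "germline"
            else:
                call.origin = "somatic"
            calls.append(call)
    return calls


def apply_rescue(sites: Iterable[SiteCounts],
                 hotspot_db: Iterable[VariantKey] | Mapping,
                 min_depth: int = GERMLINE_MIN_DEPTH,
                 min_alt: int = GERMLINE_MIN_ALT,
                 min_vaf: float = SOMATIC_MIN_VAF) -> list[VariantCall]:
    """Recover database-listed variants that fail the calling thresholds.

    Any observed alternate allele keyed in ``hotspot_db`` (by chrom, pos,
    ref, alt) that fails the thresholds — including the minimum VAF — is
    emitted with ``status='rescued'`` into this separate output rather than
    being discarded.  Candidates that pass the thresholds belong to the
    normal caller output and are not duplicated here; non-listed failing
    candidates are dropped.
    """
    db = set(hotspot_db)
    rescued = []
    for site in sites:
        depth = site.depth
        for alt, n in _candidates(site):
            key = (site.chrom, site.pos, site.ref, alt)
            if key not in db:
                continue
            if passes_thresholds(depth, n, min_depth, min_alt, min_vaf):
                continue
            rescued.append(VariantCall(site.chrom, site.pos, site.ref, alt,
                                       n, depth, status="rescued"))
    return rescued


@dataclass(frozen=True)
class BlacklistEntry:
    """A recurrent sequencing artifact: an exact site/alt, or a
    substitution-class signature (ref>alt anywhere)."""

    chrom: str | None = None
    pos: int | None = None
    ref: str | None = None
    alt: str | None = None

    def matches(self, call: VariantCall) -> bool:
        if self.chrom is not None and (self.chrom != call.chrom
                                       or self.pos != call.pos):
            return False
        if self.ref is not None and self.ref != call.ref:
            return False
        if self.alt is not None and self.alt != call.alt:
            return False
        return True


def filter_recurrent_errors(calls: Iterable[VariantCall],
                            blacklist: Sequence[BlacklistEntry]
                            ) -> list[VariantCall]:
    """Mark calls matching the artifact blacklist as filtered."""
    out = []
    for call in calls:
        if any(b.matches(call) for b in blacklist):
            call.status = "filtered"
            if "recurrent_error" not in call.filter_reasons:
                call.filter_reasons.append("recurrent_error")
        out.append(call)
    return out


def call_dead_zone(sites: Iterable[SiteCounts], mode: str,
                   dead_zone_regions: Sequence[TargetRegion] | None = None,
                   **thresholds) -> list[VariantCall]:
    """Call variants in homology dead zones under two alignment modes.

    ``whole_genome_alignment`` uses the quality-passing counts as they stand:
    reads inside a dead zone map ambiguously with MQ 0, so such variants are
    missed.  ``locus_restricted`` substitutes, inside the configured
    dead-zone regions, the counts obtained by realigning against the target
    locus alone (``SiteCounts.restricted_counts``), recovering sensitivity;
    every call emitted from a dead zone in this mode is flagged
    ``needs_orthogonal_confirmation`` because reads from the homologous
    partner locus are indistinguishable.
    """
    if mode not in ("whole_genome_alignment", "locus_restricted"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "locus_restricted" and not dead_zone_regions:
        raise ValueError("locus_restricted mode requires configured "
                         "dead-zone regions")
    zones = [(r.chrom, r.start, r.end) for r in (dead_zone_regions or ())]

    def in_zone(chrom: str, pos: int) -> bool:
        return any(c == chrom and s < pos <= e for c, s, e in zones)

    effective = []
    flagged: set[tuple[str, int]] = set()
    for site in sites:
        if (mode == "locus_restricted" and site.restricted_counts is not None
                and in_zone(site.chrom, site.pos)):
            site = SiteCounts(site.chrom, site.pos, site.ref,
                              dict(site.restricted_counts),
                              raw_depth=site.raw_depth)
            flagged.add((site.chrom, site.pos))
        effective.append(site)
    calls = call_germline(effective, **thresholds)
    for call in calls:
        if (call.chrom, call.pos) in flagged:
            call.needs_orthogonal_confirmation = True
    return calls


def write_vcf(calls: Iterable[VariantCall], path,
              contigs: Mapping[str, int] | None = None) -> None:
    """Write calls as VCF 4.2 text with ORIGIN/STATUS/NOC INFO fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=ORIGIN,Number=1,Type=String,'
                 'Description="Variant origin">\n')
        fh.write('##INFO=<ID=STATUS,Number=1,Type=String,'
                 'Description="Calling status">\n')
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,'
                 'Description="Variant allele frequency">\n')
        fh.write('##INFO=<ID=NOC,Number=0,Type=Flag,'
                 'Description="Needs orthogonal confirmation">\n')
        fh.write('##FILTER=<ID=recurrent_error,'
                 'Description="Recurrent sequencing artifact">\n')
        fh.write('##FILTER=<ID=no_normal_coverage,'
                 'Description="No matched-normal coverage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda v: (v.chrom, v.pos, v.alt)):
            filt = ";".join(c.filter_reasons) if c.filter_reasons else "PASS"
            info = f"ORIGIN={c.origin};STATUS={c.status};VAF={c.vaf:.4f}"
            if c.needs_orthogonal_confirmation:
                info += ";NOC"
            fh.write(f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\t{filt}\t"
                     f"{info}\n")
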