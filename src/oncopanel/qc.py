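"""Sample qualification, callability/gap computation and probe redesign.

FFPE DNA quality is screened with two quantifications of the same extract:
total absorbance (NanoDrop, N) and dsDNA-specific fluorimetry (Qubit, Q).
The Q/N ratio is a degradation proxy: ≥100 ng of DNA with Q/N > 0.29 and a
nucleated tumor-cell content ≥20% predicts successful library preparation,
while Q/N < 0.1 predicts failure.  The 20% tumor-content floor is the purity
at which a clonal heterozygous variant reaches the validated VAF ≥ 0.1
operating point (VAF = purity/2).

Callability is the fraction of target bases covered by at least k
quality-passing reads (base quality ≥10, mapping quality ≥20 for coverage
accounting); a target-sequence *gap* is a maximal interval of bases with
fewer than 20 passing reads.  Probe densities are retuned per region from
callability: regions short of 100% at 100× get denser tiling (10×), regions
already complete at 500× get sparser tiling (3×).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .panel import TargetRegion
from .simulate import SiteCounts

DEPTH_THRESHOLDS = (10, 20, 50, 100, 500)
GAP_MIN_READS = 20


@dataclass
class SampleQC:
    nanodrop_ng: float
    qubit_ng: float
    qn_ratio: float
    tumor_content: float
    decision: str  # accept | attempt_with_warning | enrich_recommended | predicted_failure

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class CallabilityReport:
    """Per-region callable fractions by depth threshold, plus gap intervals."""

    callable_fraction: dict[str, dict[int, float]]  # region name -> {k: frac}
    gaps: list[tuple[str, int, int]] = field(default_factory=list)  # 0-based half-open
    region_names: list[str] = field(default_factory=list)

    def total_fraction(self, threshold: int) -> float:
        fracs = [v[threshold] for v in self.callable_fraction.values()]
        return sum(fracs) / len(fracs) if fracs else 0.0

    def to_dict(self) -> dict:
        return {
            "callable_fraction": {r: {str(k): v for k, v in d.items()}
                                  for r, d in self.callable_fraction.items()},
            "gaps": [list(g) for g in self.gaps],
        }

    def gaps_as_bed(self, path) -> None:
        """Emit the list of insufficiently covered positions as BED."""
        with open(path, "w") as fh:
            for chrom, start, end in self.gaps:
                fh.write(f"{chrom}\t{start}\t{end}\tgap\n")


def qualify_sample(nanodrop_conc: float, qubit_conc: float, mass_ng: float,
                   tumor_content: float) -> SampleQC:
    """Apply the minimum-sample-requirement decision rules.

    Concentrations must share units (the ratio is what matters).  The
    decision lattice, strongest rule first: Q/N < 0.1 predicts library
    failure; tumor content < 20% calls for macro/microdissection enrichment;
    ≥100 ng with Q/N > 0.29 and adequate tumor content is accepted; anything
    else may be attempted with a warning.
    """
    if nanodrop_conc <= 0 or qubit_conc <= 0:
        raise ValueError("concentrations must be positive")
    if mass_ng < 0 or not 0 <= tumor_content <= 1:
        raise ValueError("mass must be >=0 and tumor content in [0, 1]")
    qn = qubit_conc / nanodrop_conc
    if qn < 0.1:
        decision = "predicted_failure"
    elif tumor_content < 0.20:
        decision = "enrich_recommended"
    elif mass_ng >= 100 and qn > 0.29:
        decision = "accept"
    else:
        decision = "attempt_with_warning"
    # mass_ng is the fluorimetric (dsDNA) mass; the spectrophotometric mass
    # of the same volume follows from the concentration ratio
    return SampleQC(nanodrop_ng=mass_ng / qn, qubit_ng=mass_ng, qn_ratio=qn,
                    tumor_content=tumor_content, decision=decision)


def minimum_tumor_content(vaf_threshold: float = 0.1) -> float:
    """Smallest tumor-cell fraction at which a clonal heterozygous variant
    reaches ``vaf_threshold``.

    A heterozygous variant present in all tumor cells of a sample with
    tumor-cell fraction p has expected VAF p/2 (diploid, no copy change),
    so the minimum usable purity is ``2 * vaf_threshold``.
    """
    if not 0 < vaf_threshold <= 0.5:
        raise ValueError("threshold must be in (0, 0.5]")
    return 2.0 * vaf_threshold


def compute_callability(sites: Iterable[SiteCounts],
                        regions: Sequence[TargetRegion],
                        depth_thresholds: Sequence[int] = DEPTH_THRESHOLDS,
                        gap_min_reads: int = GAP_MIN_READS
                        ) -> CallabilityReport:
    """Count callable bases per region and enumerate coverage gaps.

    A base is callable at DPk iff it has ≥k quality-passing reads; bases
    with no pileup record count as zero coverage.  Gaps are maximal runs of
    bases with fewer than ``gap_min_reads`` passing reads, reported as
    0-based half-open intervals.
    """
    if not regions:
        raise ValueError("empty region set")
    depth_at: dict[tuple[str, int], int] = {}
    for s in sites:
        depth_at[(s.chrom, s.pos)] = s.depth

    fractions: dict[str, dict[int, float]] = {}
    gaps: list[tuple[str, int, int]] = []
    names: list[str] = []
    for region in regions:
        name = region.gene
        names.append(name)
        n = len(region)
        counts = [depth_at.get((region.chrom, pos), 0)
                  for pos in range(region.start + 1, region.end + 1)]
        fractions[name] = {
            k: sum(1 for d in counts if d >= k) / n for k in depth_thresholds}
        gap_start = None
        for i, d in enumerate(counts):
            if d < gap_min_reads:
                if gap_start is None:
                    gap_start = region.start + i
            elif gap_start is not None:
                gaps.append((region.chrom, gap_start, region.start + i))
                gap_start = None
        if gap_start is not None:
            gaps.append((region.chrom, gap_start, region.end))
    return CallabilityReport(fractions, gaps, names)


def redesign_probe_densities(dp100: Mapping[str, float],
                             dp500: Mapping[str, float],
                             densities: Mapping[str, int]) -> dict[str, int]:
    """Retile probe densities from per-region callability.

    A region below 100% callability at 100× is boosted to 10× tiling
    (sensitivity priority — this rule wins when both apply); a region at
    100% callability at 500× has excess depth and is relaxed to 3×; all
    others keep their current density.  Completeness comparisons are exact:
    the fractions derive from integer base counts.
    """
    out: dict[str, int] = {}
    for region, density in densities.items():
        if density not in (3, 5, 10):
            raise ValueError(f"unsupported probe density {density}")
        if dp100.get(region, 1.0) < 1.0:
            out[region] = 10
        elif dp500.get(region, 0.0) == 1.0:
            out[region] = 3
        else:
            out[region] = density
    return out
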