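"""Copy-number assessment from read-depth ratios and allelic imbalance.

Per-region read depths are compared against a background pool of samples
captured with the same protocol: each sample is first normalized by its own
total depth (capture yield varies between libraries), the per-region ratio
against the pool median is log2-transformed, and regions beyond the gain /
loss thresholds are called amplified / deleted.  Heterozygous-SNP allele
fractions provide corroborating evidence: any copy change pushes het VAFs
away from 0.5 (e.g. one extra copy gives 1/3 vs 2/3), summarized as the
mean |VAF - 0.5| per region.  With a paired normal the same computation on
the normal decides the somatic/germline origin of each call.

Default thresholds: gain at log2 ratio ≥ +0.4, loss at ≤ -0.8.  Both sit
about 0.2 inside the single-copy-change expectations (log2(3/2) ≈ +0.58 and
log2(1/2) = -1.0), so a single-copy gain or loss at high purity clears its
threshold with a detection margin of several standard errors of the depth
ratio instead of straddling it.  Imbalance above 0.1 marks a call
corroborated.
Calls are per gene region — the capture is a sparse exon panel, so no
multi-region segmentation is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

GAIN_LOG2 = 0.4
LOSS_LOG2 = -0.8
IMBALANCE_CORROBORATION = 0.1


@dataclass
class CnvSegment:
    region: str
    log2_ratio: float
    imbalance: float | None
    call: str               # amplification | deletion | neutral | uncallable
    origin: str = "undetermined"   # somatic | germline | undetermined
    corroborated: bool = False


def estimate_copy_ratios(sample_depths: Mapping[str, float],
                         background_pool: Sequence[Mapping[str, float]]
                         ) -> dict[str, float]:
    """Per-region log2 depth ratios versus the pooled background.

    Each sample (the test sample and every pool sample) is normalized by its
    total depth over the shared regions; the per-region reference level is
    the median of the normalized pool values.  Regions whose pool median is
    zero are flagged uncallable (NaN).  Ratios are invariant to any global
    depth scale factor by construction.
    """
    if len(background_pool) < 3:
        raise ValueError("background pool needs at least 3 samples")
    regions = list(sample_depths)
    for pool_sample in background_pool:
        if set(pool_sample) != set(regions):
            raise ValueError("pool regions must match sample regions")

    def normalize(depths: Mapping[str, float]) -> dict[str, float]:
        total = sum(depths.values())
        if total <= 0:
            raise ValueError("sample with zero total depth")
        return {r: depths[r] / total for r in regions}

    sample_norm = normalize(sample_depths)
    pool_norm = [normalize(p) for p in background_pool]
    ratios: dict[str, float] = {}
    for r in regions:
        values = sorted(p[r] for p in pool_norm)
        n = len(values)
        med = (values[n // 2] if n % 2
               else 0.5 * (values[n // 2 - 1] + values[n // 2]))
        if med == 0:
            ratios[r] = math.nan  # uncallable: no background signal
        elif sample_norm[r] == 0:
            ratios[r] = -math.inf
        else:
            ratios[r] = math.log2(sample_norm[r] / med)
    return ratios


def compute_allelic_imbalance(het_vafs: Mapping[str, Sequence[float]]
                              ) -> dict[str, float]:
    """Mean |VAF - 0.5| of region heterozygous SNPs; absent without hets."""
    scores: dict[str, float] = {}
    for region, vafs in het_vafs.items():
        if len(vafs) == 0:
            continue
        scores[region] = sum(abs(v - 0.5) for v in vafs) / len(vafs)
    return scores


def _call_from_ratio(log2_ratio: float, gain: float, loss: float) -> str:
    if math.isnan(log2_ratio):
        return "uncallable"
    if log2_ratio >= gain:
        return "amplification"
    if log2_ratio <= loss:
        return "deletion"
    return "neutral"


def call_cnvs(ratios: Mapping[str, float],
              imbalance: Mapping[str, float] | None = None,
              paired_normal_ratios: Mapping[str, float] | None = None,
              gain: float = GAIN_LOG2, loss: float = LOSS_LOG2,
              imbalance_threshold: float = IMBALANCE_CORROBORATION
              ) -> list[CnvSegment]:
    """Call per-region copy state, with optional paired-normal origin.

    A call is corroborated when the region's allelic imbalance exceeds
    ``imbalance_threshold``.  With a paired normal: a non-neutral tumor call
    over a neutral normal region is somatic; the same call in both is
    germline; otherwise the origin stays undetermined.
    """
    imbalance = imbalance or {}
    segments: list[CnvSegment] = []
    for region, ratio in ratios.items():
        call = _call_from_ratio(ratio, gain, loss)
        imb = imbalance.get(region)
        seg = CnvSegment(region=region, log2_ratio=ratio, imbalance=imb,
                         call=call,
                         corroborated=(imb is not None
                                       and imb > imbalance_threshold
                                       and call != "neutral"))
        if paired_normal_ratios is not None and region in paired_normal_ratios:
            normal_call = _call_from_ratio(paired_normal_ratios[region],
                                           gain, loss)
            if call in ("amplification", "deletion"):
                if normal_call == "neutral":
                    seg.origin = "somatic"
                elif normal_call == call:
                    seg.origin = "germline"
        segments.append(seg)
    return segments


def write_cnv_tsv(segments: Sequence[CnvSegment], path) -> None:
    with open(path, "w") as fh:
        fh.write("region\tlog2_ratio\timbalance\tcall\torigin\tcorroborated\n")
        for s in segments:
            imb = "" if s.imbalance is None else f"{s.imbalance:.4f}"
            fh.write(f"{s.region}\t{s.log2_ratio:.4f}\t{imb}\t{s.call}\t"
                     f"{s.origin}\t{int(s.corroborated)}\n")


def write_cnv_vcf(segments: Sequence[CnvSegment], path,
                  coords: Mapping[str, tuple[str, int, int]] | None = None
                  ) -> None:
    """Symbolic-allele (<DUP>/<DEL>) VCF for non-neutral segments."""
    coords = coords or {}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##ALT=<ID=DUP,Description="Amplification">\n')
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description='
                 '"End of the segment">\n')
        fh.write('##INFO=<ID=LOG2,Number=1,Type=Float,Description='
                 '"Log2 depth ratio">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in segments:
            if s.call not in ("amplification", "deletion"):
                continue
            chrom, start, end = coords.get(s.region, (s.region, 1, 1))
            alt = "<DUP>" if s.call == "amplification" else "<DEL>"
            fh.write(f"{chrom}\t{max(start, 1)}\t{s.region}\tN\t{alt}\t.\t"
                     f"PASS\tEND={end};LOG2={s.log2_ratio:.4f}\n")
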