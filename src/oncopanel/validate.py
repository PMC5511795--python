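"""Validation harness: confusion-matrix metrics and frequency concordance.

Calls are benchmarked against simulated truth sets by exact
(chrom, pos, ref, alt) matching, with sensitivity/specificity/PPV reported
overall and stratified by truth VAF bins (≥0.05, ≥0.10, >0.20; bins closed
on the left).  Rescued calls count as detections — they are emitted, just
into a separate output.  Orthogonal frequency estimates (e.g. ddPCR) are
compared with NGS-derived VAFs by Pearson correlation and ordinary
least-squares regression; the bundled external-quality-assessment table
carries the 32 printed (ddPCR %, NGS %) pairs over four FFPE samples.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .calling import VariantCall, VariantKey
from .simulate import TruthSet

VAF_BINS = (("ge_0.05", 0.05, False), ("ge_0.10", 0.10, False),
            ("gt_0.20", 0.20, True))


@dataclass
class BinMetrics:
    tp: int = 0
    fn: int = 0

    @property
    def sensitivity(self) -> float:
        n = self.tp + self.fn
        return self.tp / n if n else 0.0


@dataclass
class ConfusionReport:
    tp: int
    fp: int
    fn: int
    tn: int
    by_vaf_bin: dict[str, BinMetrics] = field(default_factory=dict)

    @property
    def sensitivity(self) -> float:
        n = self.tp + self.fn
        return self.tp / n if n else 0.0

    @property
    def specificity(self) -> float:
        n = self.tn + self.fp
        return self.tn / n if n else 1.0

    @property
    def ppv(self) -> float:
        n = self.tp + self.fp
        return self.tp / n if n else 0.0


def _truth_keys(truth: TruthSet) -> dict[VariantKey, float]:
    return {(v["chrom"], v["pos"], v["ref"], v["alt"]): v["vaf"]
            for v in truth.snvs}


def confusion_metrics(truth: TruthSet, calls: Iterable[VariantCall],
                      negatives: Sequence[tuple[str, int]]) -> ConfusionReport:
    """Score calls against a truth set and assessed-negative sites.

    ``negatives`` are (chrom, pos) sites known variant-free; they must not
    overlap truth variant sites.  A negative site is a false positive when
    any non-filtered call lands on it.
    """
    truth_vafs = _truth_keys(truth)
    truth_sites = {(c, p) for c, p, _, _ in truth_vafs}
    neg_sites = set(negatives)
    if truth_sites & neg_sites:
        raise ValueError("truth and negative site sets overlap")

    detected: set[VariantKey] = set()
    fp_sites: set[tuple[str, int]] = set()
    for call in calls:
        if call.status == "filtered":
            continue
        if call.key in truth_vafs:
            detected.add(call.key)
        elif (call.chrom, call.pos) in neg_sites:
            fp_sites.add((call.chrom, call.pos))

    tp = len(detected)
    fn = len(truth_vafs) - tp
    fp = len(fp_sites)
    tn = len(neg_sites) - fp

    bins: dict[str, BinMetrics] = {name: BinMetrics()
                                   for name, _, _ in VAF_BINS}
    for key, vaf in truth_vafs.items():
        for name, edge, strict in VAF_BINS:
            if (vaf > edge) if strict else (vaf >= edge):
                if key in detected:
                    bins[name].tp += 1
                else:
                    bins[name].fn += 1
    return ConfusionReport(tp, fp, fn, tn, bins)


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    slope: float
    intercept: float
    n: int


def frequency_correlation(pairs: Sequence[tuple[float, float]]
                          ) -> CorrelationResult:
    """Pearson R, correlation-test p-value and OLS fit for paired
    (reference, measured) frequency estimates."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite frequency value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a frequency column")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return CorrelationResult(r=float(r), p_value=float(p),
                             slope=float(fit.slope),
                             intercept=float(fit.intercept), n=len(pairs))


def calling_performance_simulation(n_variants: int = 2000,
                                   n_negative_sites: int = 10_000,
                                   depth: float = 950.0,
                                   error_rate: float = 1e-3,
                                   vaf_grid: Sequence[float] = tuple(
                                       round(0.10 + 0.05 * i, 2)
                                       for i in range(9)),
                                   seed: int = 0) -> ConfusionReport:
    """End-to-end caller benchmark at the platform's coverage regime.

    Simulates ``n_variants`` SNV sites with true allele fractions drawn from
    ``vaf_grid`` (0.10–0.50 by default) plus ``n_negative_sites``
    variant-free sites, all at Poisson mean ``depth`` with per-base error
    ``error_rate``, runs the paired somatic caller (depth ≥6, alt ≥3,
    VAF ≥0.025; rescue disabled, empty blacklist) against a matched clean
    normal, and scores the calls.
    """
    from . import calling
    from .simulate import make_reference, simulate_site_counts

    rng = np.random.default_rng(seed)
    n_sites = n_variants + n_negative_sites
    exon_len = 500
    n_genes = (n_sites + exon_len - 1) // exon_len + 1
    ref = make_reference(n_genes=n_genes, exons_per_gene=1,
                         exon_len=exon_len, seed=seed, intergenic=100)
    positions = [(r.chrom, p) for r in ref.regions
                 for p in range(r.start + 1, r.end + 1)][:n_sites]
    var_idx = rng.choice(len(positions), size=n_variants, replace=False)
    var_set = {positions[i] for i in var_idx}
    variants = []
    for chrom, pos in sorted(var_set):
        ref_base = ref.base_at(chrom, pos)
        alt = "ACGT".replace(ref_base, "")[rng.integers(3)]
        vaf = float(vaf_grid[rng.integers(len(vaf_grid))])
        variants.append((chrom, pos, alt, vaf))
    assessed = set(positions)
    tumor_sites, truth = simulate_site_counts(
        ref, variants, depth=depth, error_rate=error_rate, seed=seed + 1)
    tumor_sites = [s for s in tumor_sites if (s.chrom, s.pos) in assessed]
    normal_sites, _ = simulate_site_counts(
        ref, [], depth=depth, error_rate=error_rate, seed=seed + 2)
    normal_sites = [s for s in normal_sites if (s.chrom, s.pos) in assessed]
    calls = calling.call_somatic_paired(tumor_sites, normal_sites)
    negatives = [pt for pt in positions if pt not in var_set]
    return confusion_metrics(truth, calls, negatives)


def load_emqn_pairs(samples: Sequence[int] | None = None,
                    path=None) -> list[tuple[float, float]]:
    """The bundled (ddPCR %, NGS %) pairs, optionally restricted to samples.

    Both columns stay on the percent scale as printed; Pearson R is
    scale-invariant so this choice does not affect the correlation.
    """
    path = path or resources.files("oncopanel.data") / "emqn_table5.tsv"
    pairs = []
    with path.open() if hasattr(path, "open") else open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            if samples is not None and int(row["sample"]) not in samples:
                continue
            pairs.append((float(row["ddpcr_pct"]), float(row["ngs_pct"])))
    return pairs
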