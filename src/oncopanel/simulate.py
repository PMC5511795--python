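"""Synthetic reference, pileup and read-pair generation.

Everything the calling and validation modules consume can be produced here
with known truth: a toy reference genome with exon-like target regions, per
site allele-count pileups under a Poisson-depth/binomial-allele model with an
optional FFPE deamination excess, fusion-supporting read pairs, and in-silico
mixtures of two libraries.  All generators take an integer seed and are fully
deterministic for a fixed seed.

The pileup noise model: at each target base the quality-passing depth is
Poisson(mean depth); reads supporting an injected variant are
Binomial(depth, VAF); every remaining read miscalls to each of the three
non-reference bases with probability ``error_rate / 3``; FFPE mode adds an
extra C>T (and G>A) miscall probability at reference C (G) sites, emulating
cytosine-deamination artifacts in formalin-fixed tissue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from .panel import TargetRegion

BASES = "ACGT"


@dataclass
class SiteCounts:
    """Per-position allele counts of quality-passing reads.

    ``counts`` maps allele strings (single bases, or longer strings for
    indel alleles) to read counts; ``depth`` is the passing depth (sum of
    ``counts``); ``raw_depth`` additionally includes reads failing the
    base/mapping-quality cutoffs.  ``restricted_counts`` optionally carries
    the counts obtained when reads are realigned against a single-locus
    reference (used for homology dead zones, where whole-genome mapping
    qualities are zero).
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    counts: dict[str, int]
    raw_depth: int = 0
    restricted_counts: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative allele count")
        if self.raw_depth < self.depth:
            self.raw_depth = self.depth

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    def alt_alleles(self) -> list[str]:
        return [a for a, n in self.counts.items() if a != self.ref and n > 0]


@dataclass
class ReadPairRecord:
    """A paired-end fragment, possibly discordant or split at a breakpoint."""

    pair_id: str
    chrom1: str
    pos1: int  # 1-based leftmost
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    insert_size: int  # 0 for interchromosomal / undefined
    read_len: int = 100
    clip_len: int = 0          # soft-clip length on read 1 (split reads)
    clip_pos: int | None = None  # 1-based coordinate of the clip point
    clip_seq: str = ""

    def __post_init__(self) -> None:
        if self.clip_len >= self.read_len:
            raise ValueError("clip length must be < read length")


@dataclass
class TruthSet:
    """Ground truth of a simulation run (round-trips through JSON)."""

    seed: int
    snvs: list[dict] = field(default_factory=list)
    cnvs: list[dict] = field(default_factory=list)
    breakpoints: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class Reference:
    """A synthetic genome: contig sequences plus target regions."""

    contigs: dict[str, str]
    regions: list[TargetRegion]
    dead_zones: list[TargetRegion] = field(default_factory=list)
    homolog_pairs: list[tuple[str, str]] = field(default_factory=list)

    def base_at(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.contigs[chrom][pos - 1]

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom in self.contigs and 1 <= pos <= len(self.contigs[chrom])


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def make_reference(n_genes: int, exons_per_gene: int, exon_len: int,
                   homolog_pair: bool = False, seed: int = 0,
                   intergenic: int = 500, intron: int = 200) -> Reference:
    """Build a deterministic toy reference with exon-like target regions.

    Genes ``GENE1..GENEn`` are laid out on one contig, each with
    ``exons_per_gene`` exons of ``exon_len`` bp separated by introns.  With
    ``homolog_pair`` four extra regions are appended: an NGS dead zone — two
    segments ≥250 bp with 100% sequence identity, where short-read mapping
    qualities collapse to zero — and a low-stringency homology analogue, two
    segments differing at 1–5 positions per 250 bp, which remain mappable
    with proper quality filters.
    """
    if n_genes <= 0 or exons_per_gene <= 0 or exon_len <= 0:
        raise ValueError("reference dimensions must be positive")
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    seq: list[str] = []
    regions: list[TargetRegion] = []
    cursor = 0
    for gi in range(n_genes):
        cursor += intergenic
        seq.append(_random_seq(rng, intergenic))
        gene = f"GENE{gi + 1}"
        for ei in range(exons_per_gene):
            regions.append(TargetRegion(chrom, cursor, cursor + exon_len, gene))
            seq.append(_random_seq(rng, exon_len))
            cursor += exon_len
            if ei != exons_per_gene - 1:
                seq.append(_random_seq(rng, intron))
                cursor += intron

    dead_zones: list[TargetRegion] = []
    homolog_pairs: list[tuple[str, str]] = []
    if homolog_pair:
        dz_len = max(exon_len, 250)
        dz_seq = _random_seq(rng, dz_len)
        for name in ("DEADZONE_A", "DEADZONE_B"):
            cursor += intergenic
            seq.append(_random_seq(rng, intergenic))
            regions.append(TargetRegion(chrom, cursor, cursor + dz_len, name))
            dead_zones.append(regions[-1])
            seq.append(dz_seq)  # identical copy: a true NGS dead zone
            cursor += dz_len
        homolog_pairs.append(("DEADZONE_A", "DEADZONE_B"))

        hom_seq = list(_random_seq(rng, dz_len))
        n_mm = int(rng.integers(1, 6)) * max(1, dz_len // 250)
        mm_pos = rng.choice(dz_len, size=min(n_mm, dz_len), replace=False)
        for name, mutate in (("HOMOLOG_A", False), ("HOMOLOG_B", True)):
            s = list(hom_seq)
            if mutate:
                for p in mm_pos:
                    s[p] = BASES[(BASES.index(s[p]) + 1) % 4]
            cursor += intergenic
            seq.append(_random_seq(rng, intergenic))
            regions.append(TargetRegion(chrom, cursor, cursor + dz_len, name))
            seq.append("".join(s))
            cursor += dz_len
        homolog_pairs.append(("HOMOLOG_A", "HOMOLOG_B"))

    return Reference({chrom: "".join(seq)}, regions, dead_zones, homolog_pairs)


# ---------------------------------------------------------------------------
# pileup simulation
# ---------------------------------------------------------------------------

def simulate_site_counts(reference: Reference,
                         variants: Sequence[tuple[str, int, str, float]],
                         depth: float, error_rate: float = 1e-3,
                         ffpe_ct_rate: float = 0.0, seed: int = 0,
                         regions: Sequence[TargetRegion] | None = None,
                         quality_fail_rate: float = 0.05,
                         ambiguous_regions: Sequence[TargetRegion] = ()
                         ) -> tuple[list[SiteCounts], TruthSet]:
    """Simulate per-site allele counts over target regions.

    ``variants`` is a sequence of ``(chrom, pos, alt, vaf)``; positions are
    1-based and must fall inside the reference.  Sites inside
    ``ambiguous_regions`` (homology dead zones) get zero quality-passing
    reads — their reads map with MQ 0 — while the locus-restricted realignment
    counts are kept in ``restricted_counts``.
    """
    if not (0 <= error_rate < 1 and 0 <= ffpe_ct_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    truth = TruthSet(seed=seed)
    var_by_site: dict[tuple[str, int], tuple[str, float]] = {}
    for chrom, pos, alt, vaf in variants:
        if not 0 <= vaf <= 1:
            raise ValueError(f"VAF {vaf} outside [0, 1]")
        if not reference.contains(chrom, pos):
            raise ValueError(f"variant site {chrom}:{pos} outside reference")
        var_by_site[(chrom, pos)] = (alt, vaf)
        truth.snvs.append({"chrom": chrom, "pos": pos,
                           "ref": reference.base_at(chrom, pos),
                           "alt": alt, "vaf": vaf})

    if regions is None:
        regions = reference.regions
    ambiguous = [(r.chrom, r.start, r.end) for r in ambiguous_regions]

    def is_ambiguous(chrom: str, pos: int) -> bool:
        return any(c == chrom and s < pos <= e for c, s, e in ambiguous)

    sites: list[SiteCounts] = []
    for region in regions:
        for pos in range(region.start + 1, region.end + 1):
            ref = reference.base_at(region.chrom, pos)
            n = int(rng.poisson(depth))
            counts = {ref: n}
            alt, vaf = var_by_site.get((region.chrom, pos), (None, 0.0))
            if alt is not None and n > 0:
                k = int(rng.binomial(n, vaf))
                counts[ref] -= k
                counts[alt] = counts.get(alt, 0) + k
            # sequencing errors on the remaining reference reads
            n_ref = counts[ref]
            if n_ref > 0 and error_rate > 0:
                errs = rng.binomial(n_ref, error_rate)
                for _ in range(int(errs)):
                    b = BASES[rng.integers(4)]
                    if b == ref:
                        continue
                    counts[ref] -= 1
                    counts[b] = counts.get(b, 0) + 1
            # FFPE deamination: C>T on C sites, G>A on G sites
            if ffpe_ct_rate > 0 and ref in "CG" and counts[ref] > 0:
                dam = int(rng.binomial(counts[ref], ffpe_ct_rate))
                if dam:
                    tgt = "T" if ref == "C" else "A"
                    counts[ref] -= dam
                    counts[tgt] = counts.get(tgt, 0) + dam
            raw = n + int(rng.poisson(quality_fail_rate * depth))
            if is_ambiguous(region.chrom, pos):
                sites.append(SiteCounts(region.chrom, pos, ref, {ref: 0},
                                        raw_depth=raw,
                                        restricted_counts=counts))
            else:
                sites.append(SiteCounts(region.chrom, pos, ref, counts,
                                        raw_depth=raw))
    return sites, truth


# ---------------------------------------------------------------------------
# structural-variant read simulation
# ---------------------------------------------------------------------------

def simulate_sv_reads(reference: Reference,
                      breakpoint_spec: tuple[tuple[str, int], tuple[str, int], str],
                      allele_fraction: float, depth: float,
                      read_len: int = 100, insert_mean: float = 300,
                      insert_sd: float = 30, seed: int = 0
                      ) -> tuple[list[ReadPairRecord], TruthSet]:
    """Simulate read pairs over a breakpoint joining posA to posB.

    A fraction ``allele_fraction`` of the fragments covering posA derive
    from the fused allele.  Fused fragments whose junction falls between the
    two mates become discordant pairs (mate 2 placed at the partner locus);
    fragments whose junction falls inside read 1 become split reads whose
    soft-clip coordinate equals the breakpoint exactly.
    """
    (chrom_a, pos_a), (chrom_b, pos_b), orientation = breakpoint_spec
    for chrom, pos in ((chrom_a, pos_a), (chrom_b, pos_b)):
        if not reference.contains(chrom, pos):
            raise ValueError(f"breakpoint {chrom}:{pos} outside reference")
    if chrom_a == chrom_b and abs(pos_a - pos_b) < read_len:
        raise ValueError("breakpoints closer than the read length have "
                         "undefined pair geometry")
    if not 0 < allele_fraction <= 1:
        raise ValueError("allele fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    truth = TruthSet(seed=seed)
    truth.breakpoints.append({
        "chrom_a": chrom_a, "pos_a": pos_a, "chrom_b": chrom_b,
        "pos_b": pos_b, "orientation": orientation,
        "allele_fraction": allele_fraction})

    strand1, strand2 = (orientation + "+-")[:2]
    n_fragments = int(rng.poisson(depth))
    pairs: list[ReadPairRecord] = []
    seq_b = reference.contigs[chrom_b]
    for i in range(n_fragments):
        insert = max(2 * read_len, int(rng.normal(insert_mean, insert_sd)))
        # fragment start so that the fragment covers posA
        offset = int(rng.integers(0, insert))
        start1 = pos_a - offset
        fused = rng.random() < allele_fraction
        if not fused:
            pairs.append(ReadPairRecord(
                pair_id=f"frag{i}", chrom1=chrom_a, pos1=start1, strand1="+",
                chrom2=chrom_a, pos2=start1 + insert - read_len, strand2="-",
                insert_size=insert, read_len=read_len))
            continue
        junction_in_read1 = (pos_a - start1) < read_len - 1 and pos_a >= start1
        if junction_in_read1 and pos_a > start1:
            aligned = pos_a - start1 + 1   # bases aligned before the clip
            clip_len = read_len - aligned
            clip_seq = seq_b[pos_b - 1: pos_b - 1 + clip_len]
            pairs.append(ReadPairRecord(
                pair_id=f"frag{i}", chrom1=chrom_a, pos1=start1,
                strand1=strand1, chrom2=chrom_b, pos2=pos_b, strand2=strand2,
                insert_size=0, read_len=read_len,
                clip_len=max(clip_len, 1), clip_pos=pos_a, clip_seq=clip_seq))
        else:
            # junction between the mates: plain discordant pair
            dist_into_b = insert - offset - read_len
            pairs.append(ReadPairRecord(
                pair_id=f"frag{i}", chrom1=chrom_a, pos1=start1,
                strand1=strand1, chrom2=chrom_b,
                pos2=pos_b + max(dist_into_b, 0), strand2=strand2,
                insert_size=0, read_len=read_len))
    return pairs, truth


# ---------------------------------------------------------------------------
# library mixing
# ---------------------------------------------------------------------------

def mix_libraries(counts_a: Sequence[SiteCounts], counts_b: Sequence[SiteCounts],
                  proportion_a: float, seed: int = 0) -> list[SiteCounts]:
    """Resample a per-site mixture of two libraries covering the same sites.

    At each site every read is drawn from library A with probability
    ``proportion_a`` (else B), sampling alleles from that library's observed
    allele frequencies, so the expected mixed VAF of a variant is
    ``pA * VAF_A + (1 - pA) * VAF_B``.
    """
    if not 0 <= proportion_a <= 1:
        raise ValueError("proportion must be in [0, 1]")
    key_a = [(s.chrom, s.pos) for s in counts_a]
    key_b = [(s.chrom, s.pos) for s in counts_b]
    if key_a != key_b:
        raise ValueError("mixed libraries must cover identical site sets")
    rng = np.random.default_rng(seed)
    mixed: list[SiteCounts] = []
    for sa, sb in zip(counts_a, counts_b):
        n = int(round((sa.depth + sb.depth) / 2))
        n_from_a = int(rng.binomial(n, proportion_a)) if n else 0
        counts: dict[str, int] = {sa.ref: 0}
        for src, k in ((sa, n_from_a), (sb, n - n_from_a)):
            if k == 0 or src.depth == 0:
                continue
            alleles = list(src.counts)
            probs = np.array([src.counts[a] for a in alleles], dtype=float)
            draw = rng.multinomial(k, probs / probs.sum())
            for allele, cnt in zip(alleles, draw):
                counts[allele] = counts.get(allele, 0) + int(cnt)
        mixed.append(SiteCounts(sa.chrom, sa.pos, sa.ref, counts,
                                raw_depth=max(sa.raw_depth, sb.raw_depth)))
    return mixed


# ---------------------------------------------------------------------------
# writers / readers (plain-text formats)
# ---------------------------------------------------------------------------

def write_fasta(reference: Reference, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_bed(regions: Iterable[TargetRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\t"
                     f"{r.probe_density}\t.\n")


def write_sam(pairs: Iterable[ReadPairRecord], reference: Reference, path) -> None:
    """Emit read pairs as minimal valid SAM text (mapped, paired records)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in reference.contigs.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for p in pairs:
            for which, (chrom, pos, strand, mchrom, mpos, mstrand) in enumerate(
                    ((p.chrom1, p.pos1, p.strand1, p.chrom2, p.pos2, p.strand2),
                     (p.chrom2, p.pos2, p.strand2, p.chrom1, p.pos1, p.strand1))):
                flag = 1 | (64 if which == 0 else 128)
                if strand == "-":
                    flag |= 16
                if mstrand == "-":
                    flag |= 32
                pos = max(pos, 1)
                mpos = max(mpos, 1)
                if which == 0 and p.clip_len:
                    cigar = f"{p.read_len - p.clip_len}M{p.clip_len}S"
                else:
                    cigar = f"{p.read_len}M"
                seq = reference.contigs[chrom][pos - 1: pos - 1 + p.read_len]
                seq = (seq + "N" * p.read_len)[:p.read_len]
                tlen = p.insert_size if which == 0 else -p.insert_size
                rnext = "=" if mchrom == chrom else mchrom
                fh.write(f"{p.pair_id}\t{flag}\t{chrom}\t{pos}\t60\t{cigar}\t"
                         f"{rnext}\t{mpos}\t{tlen}\t{seq}\t*\n")


def write_pileup_tsv(sites: Iterable[SiteCounts], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\traw_depth\tcounts\n")
        for s in sites:
            enc = ",".join(f"{a}:{n}" for a, n in sorted(s.counts.items()))
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.raw_depth}\t{enc}\n")


def read_pileup_tsv(path) -> list[SiteCounts]:
    sites = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("chrom")
        for line in fh:
            chrom, pos, ref, raw, enc = line.rstrip("\n").split("\t")
            counts = {}
            for tok in enc.split(","):
                allele, n = tok.rsplit(":", 1)
                counts[allele] = int(n)
            sites.append(SiteCounts(chrom, int(pos), ref, counts,
                                    raw_depth=int(raw)))
    return sites
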