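"""Rearrangement detection from discordant read pairs and split reads.

A read pair is *discordant* when its mates map to different contigs or to
the same contig at an anomalous distance (|insert| exceeding
``insert_mean + anomaly_k * insert_sd``).  Clusters of at least
``min_support`` discordant fragments seed a breakpoint event; soft-clipped
(split) reads, when present, pin the breakpoint to the exact base — the
clip coordinate — which is how nucleotide resolution is achieved.  The
inferred allele fraction is the ratio of supporting fragments to all
fragments spanning the A-side breakpoint.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .simulate import ReadPairRecord


@dataclass
class BreakpointEvent:
    chrom_a: str
    pos_a: int
    strand_a: str
    chrom_b: str
    pos_b: int
    strand_b: str
    discordant_support: int
    split_support: int
    spanning_fragments: int = 0
    gene_a: str = ""
    gene_b: str = ""

    @property
    def support(self) -> int:
        return self.discordant_support + self.split_support

    @property
    def allele_fraction(self) -> float:
        if not self.spanning_fragments:
            return 0.0
        return self.support / self.spanning_fragments

    @property
    def orientation(self) -> str:
        return self.strand_a + self.strand_b

    def canonical(self) -> "BreakpointEvent":
        """Order breakpoint A before B by (contig, position)."""
        if (self.chrom_b, self.pos_b) < (self.chrom_a, self.pos_a):
            return BreakpointEvent(self.chrom_b, self.pos_b, self.strand_b,
                                   self.chrom_a, self.pos_a, self.strand_a,
                                   self.discordant_support, self.split_support,
                                   self.spanning_fragments,
                                   self.gene_b, self.gene_a)
        return self


def _is_discordant(pair: ReadPairRecord, insert_mean: float,
                   insert_sd: float, anomaly_k: float) -> bool:
    if pair.chrom1 != pair.chrom2:
        return True
    if pair.clip_len > 0:
        return True
    if pair.insert_size == 0:
        return True  # same contig with undefined insert: junction-spanning
    return abs(pair.insert_size) > insert_mean + anomaly_k * insert_sd


def detect_rearrangements(read_pairs: Sequence[ReadPairRecord],
                          insert_mean: float, insert_sd: float,
                          min_support: int = 3, anomaly_k: float = 4.0,
                          registry=None) -> list[BreakpointEvent]:
    """Cluster discordant/split fragments into breakpoint events.

    Discordant fragments are grouped by the contig pair of their mates and
    clustered positionally within a window of ``insert_mean + 3*insert_sd``.
    Clusters reaching ``min_support`` fragments (discordant pairs plus split
    reads) become events.  The breakpoint coordinate is the modal split-read
    clip position when any split read exists (ties broken by highest split
    support, then leftmost); without split evidence it is the rightmost
    A-side read end, i.e. insert-level resolution only.  When a panel
    ``registry`` with target regions is supplied, partner genes are looked
    up from the event coordinates.
    """
    if insert_sd <= 0:
        raise ValueError("insert_sd must be positive")
    window = insert_mean + 3 * insert_sd

    discordant = [p for p in read_pairs
                  if _is_discordant(p, insert_mean, insert_sd, anomaly_k)]
    groups: dict[tuple[str, str, str, str], list[ReadPairRecord]] = defaultdict(list)
    for p in discordant:
        groups[(p.chrom1, p.chrom2, p.strand1, p.strand2)].append(p)

    events: list[BreakpointEvent] = []
    for (chrom_a, chrom_b, strand_a, strand_b), pairs in groups.items():
        pairs.sort(key=lambda p: p.pos1)
        cluster: list[ReadPairRecord] = []
        clusters: list[list[ReadPairRecord]] = []
        for p in pairs:
            if cluster and p.pos1 - cluster[-1].pos1 > window:
                clusters.append(cluster)
                cluster = []
            cluster.append(p)
        if cluster:
            clusters.append(cluster)

        for cl in clusters:
            if len(cl) < min_support:
                continue
            splits = [p for p in cl if p.clip_len > 0 and p.clip_pos]
            if splits:
                clip_votes = Counter(p.clip_pos for p in splits)
                best = max(clip_votes.items(), key=lambda kv: (kv[1], -kv[0]))
                pos_a = best[0]
                pos_b = Counter(p.pos2 for p in splits).most_common(1)[0][0]
            else:
                pos_a = max(p.pos1 + p.read_len - 1 for p in cl)
                pos_b = min(p.pos2 for p in cl)
            event = BreakpointEvent(
                chrom_a, pos_a, strand_a, chrom_b, pos_b, strand_b,
                discordant_support=len(cl) - len(splits),
                split_support=len(splits))
            event.spanning_fragments = _count_spanning(read_pairs, chrom_a, pos_a)
            if registry is not None:
                event.gene_a = _gene_at(registry, chrom_a, pos_a)
                event.gene_b = _gene_at(registry, chrom_b, pos_b)
            events.append(event.canonical())
    events.sort(key=lambda e: (e.chrom_a, e.pos_a, e.chrom_b, e.pos_b))
    return events


def _count_spanning(pairs: Iterable[ReadPairRecord], chrom: str, pos: int) -> int:
    """Fragments whose span covers ``pos``.  Discordant fragments (different
    contigs, or insert undefined) span the breakpoint by construction."""
    n = 0
    for p in pairs:
        if p.chrom1 != chrom or p.pos1 > pos:
            continue
        if p.chrom2 != p.chrom1 or p.insert_size == 0:
            n += 1
        elif p.pos1 + p.insert_size - 1 >= pos:
            n += 1
    return n


def _gene_at(registry, chrom: str, pos: int) -> str:
    for region in getattr(registry, "regions", []):
        if region.chrom == chrom and region.start < pos <= region.end:
            return region.gene
    return ""


def write_bedpe(events: Iterable[BreakpointEvent], path) -> None:
    with open(path, "w") as fh:
        for e in events:
            name = f"{e.gene_a or '.'}--{e.gene_b or '.'}"
            fh.write(f"{e.chrom_a}\t{e.pos_a - 1}\t{e.pos_a}\t"
                     f"{e.chrom_b}\t{e.pos_b - 1}\t{e.pos_b}\t{name}\t"
                     f"{e.support}\t{e.strand_a}\t{e.strand_b}\n")


def write_vcf_bnd(events: Iterable[BreakpointEvent], path) -> None:
    """Breakend (BND) VCF representation of the events."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description='
                 '"SV type">\n')
        fh.write('##INFO=<ID=MATEID,Number=1,Type=String,Description='
                 '"Mate breakend">\n')
        fh.write('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description='
                 '"Discordant+split support">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, e in enumerate(events):
            ida, idb = f"bnd_{i}a", f"bnd_{i}b"
            alt_a = f"N[{e.chrom_b}:{e.pos_b}[" if e.strand_b == "+" \
                else f"N]{e.chrom_b}:{e.pos_b}]"
            alt_b = f"N[{e.chrom_a}:{e.pos_a}[" if e.strand_a == "+" \
                else f"N]{e.chrom_a}:{e.pos_a}]"
            common = f"SVTYPE=BND;SUPPORT={e.support}"
            fh.write(f"{e.chrom_a}\t{e.pos_a}\t{ida}\tN\t{alt_a}\t.\tPASS\t"
                     f"{common};MATEID={idb}\n")
            fh.write(f"{e.chrom_b}\t{e.pos_b}\t{idb}\tN\t{alt_b}\t.\tPASS\t"
                     f"{common};MATEID={ida}\n")
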