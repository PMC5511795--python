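"""Gene-panel registry: subpanel membership, germline tiers and reportability.

The platform targets three subpanels of a single hybrid-capture design:

* a *somatic* subpanel — 97 genes screened for SNVs/indels/CNVs plus 17 genes
  whose selected introns are tiled for rearrangement detection;
* a *germline* subpanel — 148 hereditary-cancer genes on a two-tier system.
  Tier-1 genes are predominantly cancer-predisposing; the Tier-1 subset with
  established management guidelines is Tier-1a.  Tier-2 genes are associated
  with cancer only within overt, mainly non-cancerous syndromes and are
  reportable only for syndromic patients;
* a *research* subpanel — genes captured for translational research only,
  never clinically reported.

Panels are loaded from flat TSV tables with columns
``symbol  subpanel  tier  bold  rearrangement_only`` where ``subpanel`` is one
of ``somatic_snv``, ``somatic_rearrangement``, ``germline``, ``research``,
``tier`` is 1/2 for germline rows and ``bold`` marks Tier-1a membership.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

GERMLINE_TIERS = ("none", "1a", "1b", "2")

# lowercase gene aliases seen in the printed case tables; normalised on load
# and on query, with the isoform retained as a note (e.g. the CDKN2A p14ARF
# transcript reported as "cdkn2ai3").
_SYMBOL_ALIASES = {"cdkn2ai3": ("CDKN2A", "isoform 3 (p14ARF reading frame)")}


class PanelError(ValueError):
    """Raised for malformed or self-contradictory panel tables."""


@dataclass
class GeneEntry:
    symbol: str
    transcripts: list[str] = field(default_factory=list)
    in_somatic_snv: bool = False
    in_somatic_rearrangement: bool = False
    germline_tier: str = "none"
    in_research: bool = False
    rearrangement_only: bool = False
    isoform_note: str = ""

    def __post_init__(self) -> None:
        if self.germline_tier not in GERMLINE_TIERS:
            raise PanelError(f"unknown germline tier {self.germline_tier!r} "
                             f"for {self.symbol}")


@dataclass(frozen=True)
class TargetRegion:
    """A captured target interval (0-based half-open, BED convention)."""

    chrom: str
    start: int
    end: int
    gene: str
    region_class: str = "exon"  # exon | intron | UTR
    probe_density: int = 5

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise PanelError(f"empty region {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


def normalize_symbol(symbol: str) -> tuple[str, str]:
    """Return (canonical symbol, isoform note) for a printed gene label."""
    if symbol in _SYMBOL_ALIASES:
        return _SYMBOL_ALIASES[symbol]
    return symbol, ""


class PanelRegistry:
    """In-memory registry of every panel gene with merged subpanel flags."""

    def __init__(self, genes: Iterable[GeneEntry]):
        self._genes: dict[str, GeneEntry] = {}
        for g in genes:
            if g.symbol in self._genes:
                raise PanelError(f"duplicate gene entry {g.symbol}")
            self._genes[g.symbol] = g

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol)[0] in self._genes

    def __len__(self) -> int:
        return len(self._genes)

    def get(self, symbol: str) -> GeneEntry | None:
        return self._genes.get(normalize_symbol(symbol)[0])

    def __getitem__(self, symbol: str) -> GeneEntry:
        entry = self.get(symbol)
        if entry is None:
            raise KeyError(symbol)
        return entry

    # -- subpanel views -----------------------------------------------------
    @property
    def somatic_snv_genes(self) -> set[str]:
        return {s for s, g in self._genes.items() if g.in_somatic_snv}

    @property
    def rearrangement_genes(self) -> set[str]:
        return {s for s, g in self._genes.items() if g.in_somatic_rearrangement}

    @property
    def germline_genes(self) -> set[str]:
        return {s for s, g in self._genes.items() if g.germline_tier != "none"}

    @property
    def tier1_genes(self) -> set[str]:
        return {s for s, g in self._genes.items() if g.germline_tier in ("1a", "1b")}

    @property
    def tier1a_genes(self) -> set[str]:
        return {s for s, g in self._genes.items() if g.germline_tier == "1a"}

    @property
    def tier2_genes(self) -> set[str]:
        return {s for s, g in self._genes.items() if g.germline_tier == "2"}

    @property
    def research_genes(self) -> set[str]:
        return {s for s, g in self._genes.items() if g.in_research}

    def germline_tier(self, symbol: str) -> str:
        entry = self.get(symbol)
        return entry.germline_tier if entry else "none"

    def subpanel_counts(self) -> dict[str, int]:
        return {
            "somatic_snv": len(self.somatic_snv_genes),
            "somatic_rearrangement": len(self.rearrangement_genes),
            "germline": len(self.germline_genes),
            "germline_tier1": len(self.tier1_genes),
            "germline_tier1a": len(self.tier1a_genes),
            "germline_tier2": len(self.tier2_genes),
            "research": len(self.research_genes),
            "somatic_germline_shared": len(self.somatic_snv_genes
                                           & self.germline_genes),
        }

    # -- reportability ------------------------------------------------------
    def reportable_germline_genes(self, *, syndromic: bool = False,
                                  tier1a_only: bool = False) -> set[str]:
        """Germline genes eligible for clinical reporting under a request.

        Tier-2 genes enter the reportable set only for syndromic patients;
        requestors may additionally restrict to Tier-1a (genes with
        management guidelines).  Research-only genes are never reportable.
        """
        if tier1a_only:
            return self.tier1a_genes
        genes = set(self.tier1_genes)
        if syndromic:
            genes |= self.tier2_genes
        return genes

    def reportable_genes(self, context) -> set[str]:
        """Clinically reportable genes for a request context.

        ``context`` needs ``tumor_sample``, ``germline_sample``, ``syndromic``
        and ``tier1a_only`` attributes (see ``oncopanel.report.RequestContext``).
        The somatic subpanel is in play whenever a tumor sample exists; the
        germline reportable set follows :meth:`reportable_germline_genes`.
        """
        genes: set[str] = set()
        if getattr(context, "tumor_sample", False):
            genes |= self.somatic_snv_genes | self.rearrangement_genes
        if getattr(context, "germline_sample", False):
            genes |= self.reportable_germline_genes(
                syndromic=getattr(context, "syndromic", False),
                tier1a_only=getattr(context, "tier1a_only", False))
        return genes - self.research_genes


def _read_rows(path) -> list[dict[str, str]]:
    # accepts str/os.PathLike and importlib.resources traversables alike
    opener = path.open if hasattr(path, "open") else lambda: open(path)
    with opener() as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def load_panel(somatic_table, germline_table, research_table) -> PanelRegistry:
    """Build a registry from the three subpanel TSV tables.

    A gene may appear in several tables (and in both rows of the somatic
    table); memberships are merged onto a single entry.  A duplicate germline
    row with a conflicting tier, or an unknown tier label, is a hard error.
    """
    genes: dict[str, GeneEntry] = {}

    def entry(symbol: str) -> GeneEntry:
        canonical, note = normalize_symbol(symbol)
        e = genes.setdefault(canonical, GeneEntry(symbol=canonical))
        if note:
            e.isoform_note = note
        return e

    for row in _read_rows(somatic_table):
        e = entry(row["symbol"])
        sub = row["subpanel"]
        if sub == "somatic_snv":
            e.in_somatic_snv = True
        elif sub == "somatic_rearrangement":
            e.in_somatic_rearrangement = True
        else:
            raise PanelError(f"unexpected subpanel {sub!r} in somatic table")

    for row in _read_rows(germline_table):
        e = entry(row["symbol"])
        tier_label = row["tier"].strip()
        if tier_label == "1":
            tier = "1a" if row.get("bold", "0").strip() == "1" else "1b"
        elif tier_label == "2":
            tier = "2"
        else:
            raise PanelError(f"unknown tier label {tier_label!r} "
                             f"for {e.symbol}")
        if e.germline_tier != "none" and e.germline_tier != tier:
            raise PanelError(f"conflicting germline tier for {e.symbol}: "
                             f"{e.germline_tier} vs {tier}")
        e.germline_tier = tier

    for row in _read_rows(research_table):
        e = entry(row["symbol"])
        e.in_research = True
        if row.get("rearrangement_only", "0").strip() == "1":
            e.rearrangement_only = True

    return PanelRegistry(genes.values())


def load_default_panel() -> PanelRegistry:
    """Load the bundled v6 panel tables."""
    data = resources.files("oncopanel.data")
    return load_panel(data / "panel_somatic.tsv",
                      data / "panel_germline.tsv",
                      data / "panel_research.tsv")
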