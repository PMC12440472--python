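"""Domain types and coordinate conventions shared by every pipeline stage.

Conventions
-----------
* Variant panels and array manifests carry 1-based positions, as printed in
  pharmacogene variant tables (Hg19 coordinates throughout).
* Interval types (capture probes, target regions) are 0-based half-open,
  following BED. A variant at 1-based position ``p`` lies inside interval
  ``[start, end)`` iff ``start <= p - 1 < end``.
* Chromosome labels are normalized by stripping a leading ``chr`` prefix, so
  mixed-dialect inputs ("chr7" vs "7") compare equal.
* Strand is ignored: all coordinates are forward-strand positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional

__all__ = [
    "AdmeCovError",
    "ParseError",
    "ValidationError",
    "GenomicPosition",
    "PanelVariant",
    "VariantPanel",
    "PlatformManifest",
    "GenomicInterval",
    "PopMode",
    "LDConfig",
    "parse_chrpos",
    "normalize_chrom",
]


class AdmeCovError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(AdmeCovError, ValueError):
    """Malformed textual input (positions, files, headers)."""


class ValidationError(AdmeCovError, ValueError):
    """Structurally valid input that violates a domain invariant."""


_RSID_RE = re.compile(r"^rs[0-9]+$")


def normalize_chrom(label: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix and surrounding whitespace."""
    label = label.strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label


def _chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    # numeric chromosomes sort numerically, then X/Y/MT/others lexically
    if chrom.isdigit():
        return (0, int(chrom), "")
    return (1, 0, chrom)


@dataclass(frozen=True, slots=True)
class GenomicPosition:
    """A single 1-based genomic coordinate on build Hg19."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if not self.chrom:
            raise ValidationError("chromosome label must be non-empty")
        if self.pos < 1:
            raise ValidationError(
                f"position must be >= 1 (1-based), got {self.pos}"
            )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}"

    def sort_key(self) -> tuple[tuple[int, int, str], int]:
        return (_chrom_sort_key(self.chrom), self.pos)

    def __lt__(self, other: "GenomicPosition") -> bool:
        if not isinstance(other, GenomicPosition):
            return NotImplemented
        return self.sort_key() < other.sort_key()

    def distance_to(self, other: "GenomicPosition") -> int:
        """Absolute base-pair distance; raises if chromosomes differ."""
        if self.chrom != other.chrom:
            raise ValidationError(
                f"distance undefined across chromosomes {self.chrom!r} vs {other.chrom!r}"
            )
        return abs(self.pos - other.pos)


def parse_chrpos(text: str) -> GenomicPosition:
    """Parse a ``chrom:pos`` token such as ``"7:99270539"``.

    Raises :class:`ParseError` naming the offending token on malformed input.
    """
    parts = text.strip().split(":")
    if len(parts) != 2:
        raise ParseError(f"expected 'chrom:pos', got {text!r}")
    chrom, pos_text = parts
    try:
        pos = int(pos_text)
    except ValueError:
        raise ParseError(f"non-integer position in {text!r}") from None
    try:
        return GenomicPosition(chrom, pos)
    except ValidationError as exc:
        raise ParseError(f"invalid position {text!r}: {exc}") from None


@dataclass(frozen=True, slots=True)
class PanelVariant:
    """One target variant: gene symbol, dbSNP identifier and position."""

    gene: str
    rsid: str
    position: GenomicPosition

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValidationError("gene symbol must be non-empty")
        if not _RSID_RE.match(self.rsid):
            raise ValidationError(f"malformed rsID {self.rsid!r}")


@dataclass(frozen=True)
class VariantPanel:
    """An ordered target list of pharmacogene variants (the ADME list)."""

    name: str
    variants: tuple[PanelVariant, ...]

    def __init__(self, name: str, variants: Iterable[PanelVariant]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "variants", tuple(variants))
        if len(self.variants) < 1:
            raise ValidationError("a panel must contain at least one variant")
        rsids = [v.rsid for v in self.variants]
        dup_rs = sorted({r for r in rsids if rsids.count(r) > 1})
        if dup_rs:
            raise ValidationError(f"duplicate rsIDs in panel: {', '.join(dup_rs)}")
        positions = [v.position for v in self.variants]
        if len(set(positions)) != len(positions):
            dups = sorted(
                {str(p) for p in positions if positions.count(p) > 1}
            )
            raise ValidationError(f"duplicate positions in panel: {', '.join(dups)}")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[PanelVariant]:
        return iter(self.variants)

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(v.rsid for v in self.variants)

    @property
    def positions(self) -> tuple[GenomicPosition, ...]:
        return tuple(v.position for v in self.variants)

    def gene_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for v in self.variants:
            counts[v.gene] = counts.get(v.gene, 0) + 1
        return counts


@dataclass(frozen=True)
class PlatformManifest:
    """The set of variant sites one genotyping platform interrogates."""

    name: str
    sites: frozenset[GenomicPosition]
    rsids: Optional[frozenset[str]] = None

    def __init__(
        self,
        name: str,
        sites: Iterable[GenomicPosition],
        rsids: Optional[Iterable[str]] = None,
    ):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "sites", frozenset(sites))
        object.__setattr__(
            self, "rsids", frozenset(rsids) if rsids is not None else None
        )

    def __len__(self) -> int:
        return len(self.sites)

    def assays_position(self, pos: GenomicPosition) -> bool:
        return pos in self.sites

    def assays_rsid(self, rsid: str) -> bool:
        return self.rsids is not None and rsid in self.rsids


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """0-based half-open interval ``[start, end)`` (BED convention)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if not self.chrom:
            raise ValidationError("chromosome label must be non-empty")
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains_position(self, pos: GenomicPosition) -> bool:
        """Bridge from 1-based positions: p in [start, end) iff start <= p-1 < end."""
        return self.chrom == pos.chrom and self.start <= pos.pos - 1 < self.end


class PopMode(str, Enum):
    """How LD tagging aggregates across population haplotype panels."""

    POOLED = "pooled"
    PER_POPULATION_ANY = "per_population_any"
    PER_POPULATION_ALL = "per_population_all"


@dataclass(frozen=True, slots=True)
class LDConfig:
    """Parameters of the tag-SNP search.

    r2_min : squared-correlation threshold for calling a proxy (default 0.8,
        the conventional cutoff for strong linkage in pharmacogenomics).
    window_kb : half-width of the search window around the target, in kb
        (default 250, the tag-search default of standard LD tooling).
    pop_mode : aggregation across population panels; pooled merges all
        haplotypes into one panel before computing r-squared.
    """

    r2_min: float = 0.8
    window_kb: float = 250.0
    pop_mode: PopMode = PopMode.POOLED

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2_min <= 1.0:
            raise ValidationError(f"r2_min must lie in [0, 1], got {self.r2_min}")
        if self.window_kb <= 0:
            raise ValidationError(f"window_kb must be positive, got {self.window_kb}")
        if not isinstance(self.pop_mode, PopMode):
            object.__setattr__(self, "pop_mode", PopMode(self.pop_mode))

    @property
    def window_bp(self) -> int:
        return int(round(self.window_kb * 1000))
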