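"""Coverage statistics for pharmacogene variant panels.

Three flavours of coverage are computed:

* **physical (direct)** — the fraction of panel variants whose exact
  genomic position appears on a genotyping-array manifest, i.e.
  ``%coverage = |manifest ∩ panel| * 100 / |panel|``;
* **LD-adjusted** — a variant also counts as captured when an assayed SNP
  within a genomic window tags it at r2 >= threshold (see :mod:`admecov.ld`);
* **enrichment (base-level)** — for capture/amplicon designs, the fraction
  of each target region's bases covered by the union of probe intervals,
  with a high/low classification at a configurable threshold (>= 90% of
  bases by default, inclusive).

Multi-platform results assemble into a boolean variants-by-(platform, mode)
matrix from which per-column summaries and the list of variants no
platform captures are derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .core import (
    GenomicInterval,
    GenomicPosition,
    LDConfig,
    PlatformManifest,
    ValidationError,
    VariantPanel,
)
from .ld import HaplotypePanel, TagCoverage, ld_tag_coverage

__all__ = [
    "CoverageResult",
    "CoverageMatrix",
    "TargetRegion",
    "ProbeDesign",
    "EnrichmentResult",
    "physical_coverage",
    "ld_adjusted_coverage",
    "build_matrix",
    "summarize_matrix",
    "uncovered_variants",
    "region_base_coverage",
    "enrichment_coverage",
    "regions_from_panel",
    "format_percent",
]

DIRECT = "direct"
LD = "ld"


def format_percent(covered_n: int, total_n: int) -> str:
    """Percentage with 2 decimals, round-half-up (18/34 -> '52.94')."""
    if total_n <= 0:
        raise ValidationError("total_n must be positive")
    pct = Decimal(covered_n * 100) / Decimal(total_n)
    return str(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CoverageResult:
    """Per-variant coverage flags of one platform in one mode."""

    platform: str
    mode: str  # "direct" or "ld"
    per_variant: tuple[bool, ...]

    def __post_init__(self) -> None:
        if self.mode not in (DIRECT, LD):
            raise ValidationError(f"mode must be 'direct' or 'ld', got {self.mode!r}")
        if not self.per_variant:
            raise ValidationError("per_variant flags must be non-empty")

    @property
    def covered_n(self) -> int:
        return sum(self.per_variant)

    @property
    def total_n(self) -> int:
        return len(self.per_variant)

    @property
    def percent(self) -> float:
        return self.covered_n * 100.0 / self.total_n

    @property
    def percent_str(self) -> str:
        return format_percent(self.covered_n, self.total_n)


@dataclass(frozen=True)
class CoverageMatrix:
    """Boolean variants-by-(platform, mode) matrix across platforms."""

    panel: VariantPanel
    columns: tuple[tuple[str, str], ...]  # (platform, mode)
    cells: tuple[tuple[bool, ...], ...]  # row per variant, column per pair

    def __post_init__(self) -> None:
        if not self.columns:
            raise ValidationError("coverage matrix needs at least one column")
        if len(self.cells) != len(self.panel):
            raise ValidationError("matrix row count must equal panel size")
        for row in self.cells:
            if len(row) != len(self.columns):
                raise ValidationError("ragged matrix row")

    def column(self, platform: str, mode: str) -> tuple[bool, ...]:
        idx = self.columns.index((platform, mode))
        return tuple(row[idx] for row in self.cells)

    def to_results(self) -> list[CoverageResult]:
        return [
            CoverageResult(platform=p, mode=m, per_variant=self.column(p, m))
            for p, m in self.columns
        ]


def physical_coverage(
    panel: VariantPanel,
    manifest: PlatformManifest,
    rsid_fallback: bool = False,
) -> CoverageResult:
    """Direct coverage: a variant is covered iff its (chrom, pos) is on the
    manifest. With ``rsid_fallback`` a manifest listing only rsIDs can also
    match by identifier."""
    flags = []
    for v in panel:
        hit = manifest.assays_position(v.position)
        if not hit and rsid_fallback:
            hit = manifest.assays_rsid(v.rsid)
        flags.append(hit)
    return CoverageResult(platform=manifest.name, mode=DIRECT, per_variant=tuple(flags))


def ld_adjusted_coverage(
    panel: VariantPanel,
    manifest: PlatformManifest,
    haplotypes: Sequence[HaplotypePanel],
    config: LDConfig = LDConfig(),
) -> CoverageResult:
    """LD-adjusted coverage; always >= physical coverage variant-wise,
    because a directly assayed variant self-tags at r2 = 1."""
    tag_cov: TagCoverage = ld_tag_coverage(panel, manifest, haplotypes, config)
    return CoverageResult(
        platform=manifest.name, mode=LD, per_variant=tag_cov.covered
    )


def build_matrix(
    panel: VariantPanel, results: Sequence[CoverageResult]
) -> CoverageMatrix:
    """Assemble per-platform results into one matrix (columns kept in the
    order given)."""
    if not results:
        raise ValidationError("cannot build a matrix from zero results")
    for r in results:
        if r.total_n != len(panel):
            raise ValidationError(
                f"result {r.platform}:{r.mode} has {r.total_n} variants, "
                f"panel has {len(panel)}"
            )
    columns = tuple((r.platform, r.mode) for r in results)
    if len(set(columns)) != len(columns):
        raise ValidationError("duplicate (platform, mode) columns")
    cells = tuple(
        tuple(r.per_variant[i] for r in results) for i in range(len(panel))
    )
    return CoverageMatrix(panel=panel, columns=columns, cells=cells)


def summarize_matrix(
    matrix: CoverageMatrix,
) -> list[tuple[str, str, int, int, str]]:
    """Per-column (platform, mode, covered_n, total_n, percent) summaries."""
    out = []
    for r in matrix.to_results():
        out.append((r.platform, r.mode, r.covered_n, r.total_n, r.percent_str))
    return out


def uncovered_variants(matrix: CoverageMatrix):
    """Variants whose row is all-false across every column, in panel order."""
    return [
        v
        for v, row in zip(matrix.panel, matrix.cells)
        if not any(row)
    ]


@dataclass(frozen=True)
class ProbeDesign:
    """An enrichment design: a set of probe/amplicon intervals.

    Overlapping intervals are retained as-is; base counting downstream uses
    the interval union, so overlaps never double-count.
    """

    name: str
    intervals: tuple[GenomicInterval, ...]

    def __init__(self, name: str, intervals: Iterable[GenomicInterval]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "intervals", tuple(intervals))

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True, slots=True)
class TargetRegion:
    """A genomic region an enrichment design must cover."""

    gene: str
    region_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class EnrichmentResult:
    """Base-level enrichment coverage with the high/low classification."""

    design: str
    high_threshold: float
    per_region: tuple[tuple[str, str, float, bool], ...]
    # (region_id, gene, base_fraction, is_high)

    @property
    def per_gene(self) -> list[tuple[str, int, int, int, str]]:
        """(gene, regions_n, high_n, low_n, percent_high) per gene, in
        first-appearance order."""
        order: list[str] = []
        counts: dict[str, list[int]] = {}
        for _rid, gene, _frac, is_high in self.per_region:
            if gene not in counts:
                counts[gene] = [0, 0]
                order.append(gene)
            counts[gene][0] += 1
            counts[gene][1] += int(is_high)
        return [
            (
                g,
                counts[g][0],
                counts[g][1],
                counts[g][0] - counts[g][1],
                format_percent(counts[g][1], counts[g][0]),
            )
            for g in order
        ]

    @property
    def overall(self) -> tuple[int, int, str]:
        total = len(self.per_region)
        high = sum(int(h) for *_rest, h in self.per_region)
        return (high, total, format_percent(high, total))


def region_base_coverage(region: TargetRegion, probes: ProbeDesign) -> float:
    """Fraction of the region's bases under the union of probe intervals.

    Bases are counted once regardless of how many probes overlap them.
    """
    iv = region.interval
    tree = IntervalTree()
    for probe in probes.intervals:
        if probe.chrom != iv.chrom:
            continue
        start = max(probe.start, iv.start)
        end = min(probe.end, iv.end)
        if end > start:
            tree.addi(start, end)
    tree.merge_overlaps(strict=False)  # merge book-ended intervals too
    covered = sum(i.end - i.begin for i in tree)
    return covered / len(iv)


def enrichment_coverage(
    regions: Sequence[TargetRegion],
    probes: ProbeDesign,
    high_threshold: float = 0.90,
) -> EnrichmentResult:
    """Classify each target region as high/low covered at the (inclusive)
    base-fraction threshold and aggregate per gene and overall."""
    if not regions:
        raise ValidationError("at least one target region is required")
    ids = [r.region_id for r in regions]
    dups = sorted({i for i in ids if ids.count(i) > 1})
    if dups:
        raise ValidationError(f"duplicate region_id(s): {', '.join(dups)}")
    per_region = []
    for region in regions:
        frac = region_base_coverage(region, probes)
        per_region.append(
            (region.region_id, region.gene, frac, frac >= high_threshold)
        )
    return EnrichmentResult(
        design=probes.name,
        high_threshold=high_threshold,
        per_region=tuple(per_region),
    )


def regions_from_panel(
    panel: VariantPanel, flank_bp: int = 100
) -> list[TargetRegion]:
    """Convenience builder: one target region per panel variant, the
    variant position +/- a flank (default 100 bp). Region ids are rsIDs."""
    regions = []
    for v in panel:
        start = max(0, v.position.pos - 1 - flank_bp)
        end = v.position.pos - 1 + flank_bp + 1
        regions.append(
            TargetRegion(
                gene=v.gene,
                region_id=v.rsid,
                interval=GenomicInterval(v.position.chrom, start, end),
            )
        )
    return regions
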