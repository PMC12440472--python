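"""Linkage-disequilibrium engine on phased haplotypes.

Implements the standard haplotype-frequency definitions from first
principles: for two biallelic loci with allele-1 frequencies ``p_a``,
``p_b`` and two-locus haplotype frequency ``p_ab``,

    D  = p_ab - p_a * p_b
    r2 = D**2 / (p_a * (1 - p_a) * p_b * (1 - p_b))
    D' = |D| / D_max

with ``D_max = min(p_a*(1-p_b), (1-p_a)*p_b)`` when ``D > 0`` and
``min(p_a*p_b, (1-p_a)*(1-p_b))`` when ``D < 0``. All quantities are
computed by direct counting over phased haplotypes — inputs are phased, so
no EM/composite estimator is needed (unphased input is rejected upstream,
never phased here).

Tag-SNP discovery (:func:`find_tags`) reproduces the contract of the
classic ``--show-tags`` workflow: a candidate assayed site is a tag for a
target variant when it lies within a genomic window of the target and its
pairwise r-squared with the target meets the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import (
    AdmeCovError,
    GenomicPosition,
    LDConfig,
    PlatformManifest,
    PopMode,
    ValidationError,
    VariantPanel,
)

logger = logging.getLogger(__name__)

#: absolute tolerance for r2-vs-threshold comparisons (float rounding only;
#: rationals on realistic panel sizes are never this close to a threshold)
_R2_EPS = 1e-9

__all__ = [
    "HaplotypePanel",
    "LDResult",
    "TagSet",
    "TagCoverage",
    "MonomorphicSiteError",
    "TargetNotAssayedError",
    "merge_panels",
    "allele_frequency",
    "pairwise_r2",
    "find_tags",
    "ld_tag_coverage",
]


class MonomorphicSiteError(AdmeCovError):
    """r-squared is undefined when either site is monomorphic."""


class TargetNotAssayedError(AdmeCovError):
    """The target position is absent from the haplotype panel.

    Distinct from "no tags found" (which is an empty :class:`TagSet`).
    """


@dataclass(frozen=True)
class HaplotypePanel:
    """Phased 0/1 allele matrix: rows are haplotypes, columns are sites."""

    alleles: np.ndarray
    site_positions: tuple[GenomicPosition, ...]
    site_ids: Optional[tuple[str, ...]] = None
    population: Optional[str] = None

    def __init__(
        self,
        alleles: np.ndarray,
        site_positions: Sequence[GenomicPosition],
        site_ids: Optional[Sequence[str]] = None,
        population: Optional[str] = None,
    ):
        alleles = np.asarray(alleles, dtype=np.int8)
        if alleles.ndim != 2:
            raise ValidationError("allele matrix must be 2-D (haplotypes x sites)")
        if alleles.size and not np.isin(alleles, (0, 1)).all():
            raise ValidationError("allele matrix entries must be 0 or 1")
        alleles = alleles.copy()
        alleles.setflags(write=False)
        object.__setattr__(self, "alleles", alleles)
        object.__setattr__(self, "site_positions", tuple(site_positions))
        object.__setattr__(
            self, "site_ids", tuple(site_ids) if site_ids is not None else None
        )
        object.__setattr__(self, "population", population)
        if len(self.site_positions) != alleles.shape[1]:
            raise ValidationError(
                f"{alleles.shape[1]} allele columns but "
                f"{len(self.site_positions)} site positions"
            )
        if self.site_ids is not None and len(self.site_ids) != alleles.shape[1]:
            raise ValidationError("site_ids length must match number of sites")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def site_index(self, pos: GenomicPosition) -> Optional[int]:
        """Column index of a position, or None if unassayed in this panel."""
        try:
            return self._position_index()[pos]
        except KeyError:
            return None

    def _position_index(self) -> dict[GenomicPosition, int]:
        cached = getattr(self, "_pos_index_cache", None)
        if cached is None:
            cached = {p: i for i, p in enumerate(self.site_positions)}
            object.__setattr__(self, "_pos_index_cache", cached)
        return cached

    def is_polymorphic(self, site: int) -> bool:
        col = self.alleles[:, site]
        return bool(col.any() and not col.all())


def merge_panels(panels: Sequence[HaplotypePanel]) -> HaplotypePanel:
    """Pool haplotype panels sharing identical site lists into one panel.

    Used by the pooled population mode: haplotypes are stacked, site
    metadata is taken from the first panel. Panels must agree on site
    positions (same loci in the same order).
    """
    if not panels:
        raise ValidationError("cannot merge an empty list of panels")
    if len(panels) == 1:
        return panels[0]
    first = panels[0]
    for p in panels[1:]:
        if p.site_positions != first.site_positions:
            raise ValidationError(
                "panels to merge must share identical site positions"
            )
    stacked = np.vstack([p.alleles for p in panels])
    return HaplotypePanel(
        stacked, first.site_positions, first.site_ids, population="pooled"
    )


@dataclass(frozen=True, slots=True)
class LDResult:
    """Pairwise LD between two sites of a haplotype panel."""

    site_a: int
    site_b: int
    p_a: float
    p_b: float
    d: float
    d_prime: float
    r2: float


@dataclass(frozen=True)
class TagSet:
    """Assayed proxies for one target variant.

    ``tags`` is ordered deterministically: r-squared descending, then
    position ascending. Every tag satisfies the threshold and window used.
    """

    target: GenomicPosition
    tags: tuple[tuple[int, float], ...]  # (site index, r2)
    threshold_used: float
    window_used_kb: float

    def __len__(self) -> int:
        return len(self.tags)

    def __bool__(self) -> bool:
        return bool(self.tags)

    @property
    def best(self) -> Optional[tuple[int, float]]:
        return self.tags[0] if self.tags else None


def allele_frequency(panel: HaplotypePanel, site: int) -> float:
    """Frequency of allele "1" at a site: count of 1s over haplotypes."""
    if not 0 <= site < panel.n_sites:
        raise IndexError(f"site index {site} out of range [0, {panel.n_sites})")
    if panel.n_haplotypes < 1:
        raise ValidationError("panel has no haplotypes")
    return float(panel.alleles[:, site].mean())


def pairwise_r2(panel: HaplotypePanel, site_a: int, site_b: int) -> LDResult:
    """LD between two polymorphic sites by direct haplotype counting.

    Raises :class:`MonomorphicSiteError` if either site is fixed — LD is
    undefined there and is never silently reported as zero.
    """
    a = panel.alleles[:, site_a].astype(np.float64)
    b = panel.alleles[:, site_b].astype(np.float64)
    p_a = float(a.mean())
    p_b = float(b.mean())
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise MonomorphicSiteError(
            f"LD undefined: site {site_a if p_a in (0.0, 1.0) else site_b} "
            "is monomorphic"
        )
    p_ab = float((a * b).mean())
    d = p_ab - p_a * p_b
    # grouped per site so the result is bit-identical under site swap
    denom = (p_a * (1.0 - p_a)) * (p_b * (1.0 - p_b))
    r2 = (d * d) / denom
    if d > 0:
        d_max = min(p_a * (1.0 - p_b), (1.0 - p_a) * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, (1.0 - p_a) * (1.0 - p_b))
    else:
        d_max = 1.0  # D = 0 gives D' = 0 regardless
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    # clip floating noise at the boundaries
    r2 = min(max(r2, 0.0), 1.0)
    d_prime = min(max(d_prime, 0.0), 1.0)
    return LDResult(site_a, site_b, p_a, p_b, d, d_prime, r2)


def find_tags(
    panel: HaplotypePanel,
    target_pos: GenomicPosition,
    candidate_sites: Iterable[int],
    config: LDConfig = LDConfig(),
) -> TagSet:
    """All candidate sites within the window whose r2 with the target meets
    the threshold.

    Candidates monomorphic in the panel are excluded (their r-squared is
    undefined). The target itself, if among the candidates, self-tags at
    r-squared exactly 1. Output ordering is deterministic: r2 descending,
    then position ascending.

    Raises :class:`TargetNotAssayedError` when the target position is not a
    site of the panel — distinguishing "we cannot assess this variant" from
    "assessed, no tags found" (an empty TagSet).
    """
    target_idx = panel.site_index(target_pos)
    if target_idx is None:
        raise TargetNotAssayedError(
            f"target {target_pos} is not a site of the haplotype panel"
        )
    if not panel.is_polymorphic(target_idx):
        raise MonomorphicSiteError(
            f"target {target_pos} is monomorphic in the panel; LD undefined"
        )
    window_bp = config.window_bp
    hits: list[tuple[float, GenomicPosition, int]] = []
    for cand in set(candidate_sites):
        if not 0 <= cand < panel.n_sites:
            raise IndexError(f"candidate site index {cand} out of range")
        cand_pos = panel.site_positions[cand]
        if cand_pos.chrom != target_pos.chrom:
            continue
        if cand_pos.distance_to(target_pos) > window_bp:
            continue
        if cand == target_idx:
            hits.append((1.0, cand_pos, cand))
            continue
        if not panel.is_polymorphic(cand):
            continue
        r2 = pairwise_r2(panel, target_idx, cand).r2
        # tolerance absorbs float rounding of r2 values that are exactly the
        # threshold as rationals (counts on small panels)
        if r2 >= config.r2_min - _R2_EPS:
            hits.append((r2, cand_pos, cand))
    hits.sort(key=lambda h: (-h[0], h[1].sort_key()))
    return TagSet(
        target=target_pos,
        tags=tuple((idx, r2) for r2, _pos, idx in hits),
        threshold_used=config.r2_min,
        window_used_kb=config.window_kb,
    )


@dataclass(frozen=True, slots=True)
class TagCoverage:
    """Per-variant outcome of LD-aware coverage against one manifest.

    covered       : variant is on the manifest or has at least one tag.
    unassessable  : variant absent from every haplotype panel (and not
                    directly on the manifest) — distinct from uncovered.
    best_tag      : (tag position, r2) of the strongest proxy found, or
                    None; the variant's own position when directly assayed.
    """

    covered: tuple[bool, ...]
    unassessable: tuple[bool, ...]
    best_tag: tuple[Optional[tuple[GenomicPosition, float]], ...]
    n_warnings: int


def _tags_in_one_panel(
    panel: HaplotypePanel,
    target_pos: GenomicPosition,
    manifest: PlatformManifest,
    config: LDConfig,
) -> Optional[TagSet]:
    """TagSet for one population panel, or None when unassessable there."""
    target_idx = panel.site_index(target_pos)
    if target_idx is None:
        return None
    candidates = [
        idx
        for idx, pos in enumerate(panel.site_positions)
        if pos in manifest.sites
    ]
    try:
        return find_tags(panel, target_pos, candidates, config)
    except MonomorphicSiteError:
        # monomorphic target: fall back to direct presence only
        logger.warning(
            "target %s monomorphic in panel %s; LD coverage falls back to "
            "direct presence",
            target_pos,
            panel.population or "<unnamed>",
        )
        return TagSet(target_pos, (), config.r2_min, config.window_kb)


def ld_tag_coverage(
    panel_variants: VariantPanel,
    manifest: PlatformManifest,
    haplotypes: Sequence[HaplotypePanel],
    config: LDConfig = LDConfig(),
) -> TagCoverage:
    """LD-adjusted coverage of a variant panel by one platform manifest.

    A variant is covered iff (a) its position is directly on the manifest,
    or (b) tag search over the manifest's assayed sites finds a proxy at
    r2 >= threshold within the window, aggregated across population panels
    according to ``config.pop_mode``:

    * pooled — haplotypes merged into a single panel first;
    * per_population_any — tagged in at least one panel;
    * per_population_all — tagged in every panel that assays the variant.

    Variants absent from all haplotype panels (and not directly assayed)
    are flagged unassessable, with a counted warning.
    """
    if not haplotypes:
        raise ValidationError("at least one haplotype panel is required")
    if config.pop_mode is PopMode.POOLED:
        panels: list[HaplotypePanel] = [merge_panels(list(haplotypes))]
    else:
        panels = list(haplotypes)

    covered: list[bool] = []
    unassessable: list[bool] = []
    best: list[Optional[tuple[GenomicPosition, float]]] = []
    n_warnings = 0
    for variant in panel_variants:
        pos = variant.position
        if manifest.assays_position(pos):
            covered.append(True)
            unassessable.append(False)
            best.append((pos, 1.0))
            continue
        tagsets = [_tags_in_one_panel(p, pos, manifest, config) for p in panels]
        assessed = [t for t in tagsets if t is not None]
        if not assessed:
            logger.warning(
                "variant %s (%s) absent from all haplotype panels: unassessable",
                variant.rsid,
                pos,
            )
            n_warnings += 1
            covered.append(False)
            unassessable.append(True)
            best.append(None)
            continue
        if config.pop_mode is PopMode.PER_POPULATION_ALL:
            is_covered = all(bool(t) for t in assessed)
        else:  # pooled has one panel; any-mode needs one hit
            is_covered = any(bool(t) for t in assessed)
        covered.append(is_covered)
        unassessable.append(False)
        best_hit: Optional[tuple[GenomicPosition, float]] = None
        for t, p in zip(tagsets, panels):
            if t and t.best is not None:
                idx, r2 = t.best
                hit = (p.site_positions[idx], r2)
                if best_hit is None or hit[1] > best_hit[1]:
                    best_hit = hit
        best.append(best_hit)
    return TagCoverage(
        covered=tuple(covered),
        unassessable=tuple(unassessable),
        best_tag=tuple(best),
        n_warnings=n_warnings,
    )
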