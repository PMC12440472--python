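"""Synthetic phased-haplotype panels, manifests and probe tilings with
known ground truth.

The haplotype simulator uses a copy-with-flip block model: sites within a
block are copies of a shared founder column, each copy perturbed by
independent per-haplotype allele flips whose rate is calibrated to a
target within-block r-squared; founder columns of different blocks are
drawn independently, so cross-block LD vanishes in expectation. This gives
exact, controllable LD ground truth for tag discovery — which is what the
coverage pipeline needs for validation — at the deliberate cost of
genealogical realism (no recombination gradients, no allele-frequency
spectrum, no population structure).

All randomness flows from a single integer seed through a named
``numpy.random.Generator``; identical configs produce bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .core import (
    GenomicPosition,
    LDConfig,
    PlatformManifest,
    PanelVariant,
    ValidationError,
    VariantPanel,
)
from .coverage import ProbeDesign, TargetRegion
from .ld import HaplotypePanel, find_tags, pairwise_r2

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimStudy",
    "expected_pair_r2",
    "flip_rate_for_r2",
    "simulate_haplotypes",
    "simulate_manifest",
    "simulate_probes",
    "simulate_study",
]


@dataclass(frozen=True, slots=True)
class SimConfig:
    """Parameters of the block-LD haplotype simulator.

    n_samples       : diploid samples (haplotypes = 2 * n_samples).
    n_sites         : total polymorphic sites.
    block_sizes     : sites per LD block; must sum to n_sites.
    within_block_r  : target pairwise r-squared between sites of a block,
                      in [0, 1]; 1 means exact copies.
    maf_range       : founder minor-allele-frequency range, drawn uniform.
    site_spacing_bp : fixed inter-site spacing; positions are cumulative.
    chrom           : chromosome label for all sites.
    start_pos       : 1-based position of the first site.
    seed            : generator seed.
    """

    n_samples: int = 500
    n_sites: int = 10
    block_sizes: tuple[int, ...] = (5, 5)
    within_block_r: float = 1.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    site_spacing_bp: int = 2000
    chrom: str = "1"
    start_pos: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.n_sites < 2:
            raise ValidationError("n_sites must be >= 2")
        if sum(self.block_sizes) != self.n_sites:
            raise ValidationError("block_sizes must sum to n_sites")
        if any(b < 1 for b in self.block_sizes):
            raise ValidationError("block sizes must be positive")
        if not 0.0 <= self.within_block_r <= 1.0:
            raise ValidationError("within_block_r must lie in [0, 1]")
        low, high = self.maf_range
        if not (0.0 < low <= high <= 0.5):
            raise ValidationError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.site_spacing_bp < 1:
            raise ValidationError("site_spacing_bp must be positive")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth recorded by the simulators.

    block_assignment  : per-site block id (from the haplotype simulator).
    designed_direct   : panel-variant indices placed verbatim on the manifest.
    designed_taggable : panel-variant indices given an in-window proxy at
                        r2 >= threshold (but not placed directly).
    designed_untagged : panel-variant indices left with no proxy.
    """

    block_assignment: tuple[int, ...] = ()
    designed_direct: frozenset[int] = frozenset()
    designed_taggable: frozenset[int] = frozenset()
    designed_untagged: frozenset[int] = frozenset()


def expected_pair_r2(eps: float, maf: float) -> float:
    """Population r-squared between two copies of a Bernoulli(maf) founder,
    each flipped independently per haplotype at rate ``eps``.

    With marginal frequency m = p + eps(1-2p) and
    E[X1*X2] = p(1-eps)^2 + (1-p)eps^2, the correlation is
    cov / (m(1-m)) and r2 is its square.
    """
    p = maf
    m = p + eps * (1.0 - 2.0 * p)
    var = m * (1.0 - m)
    if var == 0.0:
        return 0.0
    e_xy = p * (1.0 - eps) ** 2 + (1.0 - p) * eps**2
    corr = (e_xy - m * m) / var
    return corr * corr


def flip_rate_for_r2(target_r2: float, maf: float) -> float:
    """Flip rate achieving a target expected pairwise r-squared.

    Numerically inverts :func:`expected_pair_r2` over eps in [0, 0.5];
    exact only at the endpoints (eps = 0 gives r2 = 1, eps = 0.5 gives 0).
    """
    if not 0.0 <= target_r2 <= 1.0:
        raise ValidationError("target r2 must lie in [0, 1]")
    if target_r2 >= 1.0:
        return 0.0
    if target_r2 <= 0.0:
        return 0.5
    return float(
        brentq(lambda e: expected_pair_r2(e, maf) - target_r2, 0.0, 0.5)
    )


def _draw_polymorphic_founder(
    rng: np.random.Generator, n_hap: int, maf: float, max_tries: int = 100
) -> np.ndarray:
    """Founder column guaranteed polymorphic (resampled if fixed)."""
    for _ in range(max_tries):
        col = (rng.random(n_hap) < maf).astype(np.int8)
        if col.any() and not col.all():
            return col
    raise ValidationError(
        f"could not draw a polymorphic founder at maf={maf}, n={n_hap}"
    )


def simulate_haplotypes(
    config: SimConfig, population: Optional[str] = None
) -> tuple[HaplotypePanel, SimTruth]:
    """Simulate a phased haplotype panel with block LD structure."""
    rng = np.random.default_rng(config.seed)
    n_hap = 2 * config.n_samples
    columns: list[np.ndarray] = []
    block_assignment: list[int] = []
    for block_id, block_size in enumerate(config.block_sizes):
        maf = float(rng.uniform(*config.maf_range))
        founder = _draw_polymorphic_founder(rng, n_hap, maf)
        eps = flip_rate_for_r2(config.within_block_r, maf)
        for _ in range(block_size):
            if eps == 0.0:
                col = founder.copy()
            else:
                flips = rng.random(n_hap) < eps
                col = np.where(flips, 1 - founder, founder).astype(np.int8)
            columns.append(col)
            block_assignment.append(block_id)
    positions = [
        GenomicPosition(config.chrom, config.start_pos + i * config.site_spacing_bp)
        for i in range(config.n_sites)
    ]
    ids = [f"sim{i}" for i in range(config.n_sites)]
    panel = HaplotypePanel(
        alleles=np.column_stack(columns),
        site_positions=positions,
        site_ids=ids,
        population=population,
    )
    return panel, SimTruth(block_assignment=tuple(block_assignment))


def simulate_manifest(
    panel: VariantPanel,
    haplotypes: HaplotypePanel,
    truth_spec: tuple[int, int, int],
    seed: int = 0,
    ld_config: LDConfig = LDConfig(),
) -> tuple[PlatformManifest, SimTruth]:
    """Build a platform manifest with designed coverage ground truth.

    ``truth_spec = (n_direct, n_taggable, n_untagged)`` partitions panel
    variants (shuffled by ``seed``) into: variants placed verbatim on the
    manifest; variants given an in-window proxy site at r2 >= threshold;
    and variants left without any proxy. Every panel variant must be a
    site of the haplotype panel. Proxies are non-panel sites; a
    :class:`ValidationError` is raised when no qualifying proxy exists for
    a taggable variant, or when counts exceed the panel size.
    """
    n_direct, n_taggable, n_untagged = truth_spec
    if min(truth_spec) < 0 or n_direct + n_taggable + n_untagged > len(panel):
        raise ValidationError(
            f"infeasible truth_spec {truth_spec} for a {len(panel)}-variant panel"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(panel))
    direct_idx = frozenset(int(i) for i in order[:n_direct])
    taggable_idx = frozenset(int(i) for i in order[n_direct : n_direct + n_taggable])
    untagged_idx = frozenset(
        int(i) for i in order[n_direct + n_taggable : n_direct + n_taggable + n_untagged]
    )
    panel_positions = set(panel.positions)
    sites: set[GenomicPosition] = set()
    for i in direct_idx:
        sites.add(panel.variants[i].position)
    for i in taggable_idx:
        target_pos = panel.variants[i].position
        target_site = haplotypes.site_index(target_pos)
        if target_site is None:
            raise ValidationError(
                f"panel variant {panel.variants[i].rsid} ({target_pos}) "
                "is not a site of the haplotype panel"
            )
        candidates = [
            j
            for j, pos in enumerate(haplotypes.site_positions)
            if pos not in panel_positions
            and pos.chrom == target_pos.chrom
            and pos.distance_to(target_pos) <= ld_config.window_bp
            and j != target_site
            and haplotypes.is_polymorphic(j)
        ]
        proxies = [
            j
            for j in candidates
            if pairwise_r2(haplotypes, target_site, j).r2 >= ld_config.r2_min
        ]
        if not proxies:
            raise ValidationError(
                f"no in-window proxy at r2 >= {ld_config.r2_min} exists for "
                f"{panel.variants[i].rsid}; infeasible truth_spec"
            )
        # closest qualifying proxy keeps the design deterministic
        proxies.sort(
            key=lambda j: (
                haplotypes.site_positions[j].distance_to(target_pos),
                haplotypes.site_positions[j].sort_key(),
            )
        )
        sites.add(haplotypes.site_positions[proxies[0]])
    manifest = PlatformManifest(name=f"sim-manifest-{seed}", sites=sites)
    truth = SimTruth(
        block_assignment=(),
        designed_direct=direct_idx,
        designed_taggable=taggable_idx,
        designed_untagged=untagged_idx,
    )
    return manifest, truth


def simulate_probes(
    regions: Sequence[TargetRegion],
    target_fractions: Sequence[float],
    seed: int = 0,
    name: str = "sim-probes",
) -> ProbeDesign:
    """Emit probe tilings whose union covers each region within one base of
    the requested fraction (deterministic from seed)."""
    if len(regions) != len(target_fractions):
        raise ValidationError("one target fraction per region is required")
    rng = np.random.default_rng(seed)
    intervals = []
    for region, frac in zip(regions, target_fractions):
        if not 0.0 <= frac <= 1.0:
            raise ValidationError(f"fraction {frac} outside [0, 1]")
        length = len(region.interval)
        if length == 1 and 0.0 < frac < 1.0:
            raise ValidationError(
                f"region {region.region_id}: fraction {frac} infeasible on a "
                "1-base region"
            )
        k = int(round(frac * length))
        if k == 0:
            continue
        offset = int(rng.integers(0, length - k + 1))
        start = region.interval.start + offset
        end = start + k
        chrom = region.interval.chrom
        if k >= 4:
            # split the covered span into two book-ended probes; union unchanged
            cut = start + int(rng.integers(1, k))
            intervals.append((chrom, start, cut))
            intervals.append((chrom, cut, end))
        else:
            intervals.append((chrom, start, end))
    from .core import GenomicInterval

    return ProbeDesign(
        name=name,
        intervals=[GenomicInterval(c, s, e) for c, s, e in intervals],
    )


@dataclass(frozen=True)
class SimStudy:
    """A complete simulated coverage study: panel, haplotypes, manifest and
    the designed ground truth."""

    panel: VariantPanel
    haplotypes: HaplotypePanel
    manifest: PlatformManifest
    truth: SimTruth
    config: SimConfig


_ADME_GENE_BLOCKS = (("CYP3A5", 5), ("CYP3A4", 4), ("CYP2D6", 20), ("CYP2C8", 5))


def _gene_labels(n_variants: int) -> list[str]:
    if n_variants == 34:
        labels = []
        for gene, count in _ADME_GENE_BLOCKS:
            labels.extend([gene] * count)
        return labels
    return [f"GENE{i + 1}" for i in range(n_variants)]


def simulate_study(
    n_variants: int = 34,
    truth_spec: tuple[int, int, int] = (18, 12, 4),
    n_samples: int = 500,
    sites_per_block: int = 3,
    within_block_r: float = 1.0,
    site_spacing_bp: int = 2000,
    seed: int = 0,
    ld_config: LDConfig = LDConfig(),
) -> SimStudy:
    """End-to-end study builder: one LD block per panel variant (the
    variant plus ``sites_per_block - 1`` potential proxies), then a
    manifest realising a (direct, taggable, untagged) design.

    With ``within_block_r = 1`` the pipeline's physical and LD-adjusted
    coverage recover the designed counts exactly.
    """
    if sites_per_block < 2:
        raise ValidationError("sites_per_block must be >= 2 (variant + proxy)")
    config = SimConfig(
        n_samples=n_samples,
        n_sites=n_variants * sites_per_block,
        block_sizes=tuple([sites_per_block] * n_variants),
        within_block_r=within_block_r,
        site_spacing_bp=site_spacing_bp,
        seed=seed,
    )
    haplotypes, hap_truth = simulate_haplotypes(config)
    genes = _gene_labels(n_variants)
    variants = []
    for v in range(n_variants):
        site = v * sites_per_block  # first site of the block is the variant
        variants.append(
            PanelVariant(
                gene=genes[v],
                rsid=f"rs{9_000_000 + v}",
                position=haplotypes.site_positions[site],
            )
        )
    panel = VariantPanel(name=f"sim-panel-{seed}", variants=variants)
    manifest, design_truth = simulate_manifest(
        panel, haplotypes, truth_spec, seed=seed, ld_config=ld_config
    )
    truth = SimTruth(
        block_assignment=hap_truth.block_assignment,
        designed_direct=design_truth.designed_direct,
        designed_taggable=design_truth.designed_taggable,
        designed_untagged=design_truth.designed_untagged,
    )
    return SimStudy(
        panel=panel,
        haplotypes=haplotypes,
        manifest=manifest,
        truth=truth,
        config=config,
    )
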