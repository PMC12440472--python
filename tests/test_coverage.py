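"""Coverage statistics: physical, LD-adjusted, matrix, enrichment."""

import pytest

from admecov.core import (
    GenomicInterval,
    GenomicPosition,
    PanelVariant,
    PlatformManifest,
    ValidationError,
    VariantPanel,
)
from admecov.coverage import (
    CoverageResult,
    ProbeDesign,
    TargetRegion,
    build_matrix,
    enrichment_coverage,
    format_percent,
    ld_adjusted_coverage,
    physical_coverage,
    region_base_coverage,
    regions_from_panel,
    summarize_matrix,
    uncovered_variants,
)

from conftest import make_panel


class TestFormatPercent:
    @pytest.mark.parametrize(
        "covered,total,expected",
        [(18, 34, "52.94"), (30, 34, "88.24"), (5, 34, "14.71"), (34, 34, "100.00")],
    )
    def test_two_decimals(self, covered, total, expected):
        assert format_percent(covered, total) == expected

    def test_half_up_at_tie(self):
        assert format_percent(1, 800) == "0.13"  # 0.125 rounds up, not to even


class TestPhysicalCoverage:
    def test_axiom_direct_positions(self, adme_panel, platform_matrix):
        """A manifest holding exactly the 18 Axiom-assayed positions gives
        18/34 = 52.94%."""
        flags = platform_matrix.column("Axiom", "direct")
        sites = [
            v.position for v, f in zip(adme_panel, flags) if f
        ]
        assert len(sites) == 18
        result = physical_coverage(adme_panel, PlatformManifest("Axiom", sites))
        assert (result.covered_n, result.percent_str) == (18, "52.94")
        assert result.per_variant == flags

    def test_identity_manifest_is_full(self, adme_panel):
        manifest = PlatformManifest("all", adme_panel.positions)
        assert physical_coverage(adme_panel, manifest).percent_str == "100.00"

    def test_empty_manifest_is_zero(self, adme_panel):
        assert physical_coverage(adme_panel, PlatformManifest("none", [])).covered_n == 0

    def test_rsid_fallback(self):
        v = PanelVariant("CYP3A5", "rs776746", GenomicPosition("7", 99270539))
        panel = VariantPanel("p", [v])
        manifest = PlatformManifest("m", [GenomicPosition("7", 1)], rsids=["rs776746"])
        assert not physical_coverage(panel, manifest).per_variant[0]
        assert physical_coverage(panel, manifest, rsid_fallback=True).per_variant[0]


class TestMatrix:
    def test_fixture_column_sums(self, platform_matrix):
        sums = [r.covered_n for r in platform_matrix.to_results()]
        assert sums == [1, 4, 5, 8, 18, 2, 14, 10, 20, 30]

    def test_summarize_roundtrips_results(self, adme_panel, platform_matrix):
        results = platform_matrix.to_results()
        rebuilt = build_matrix(adme_panel, results)
        assert rebuilt == platform_matrix
        summary = summarize_matrix(rebuilt)
        for row, r in zip(summary, results):
            assert row == (r.platform, r.mode, r.covered_n, r.total_n, r.percent_str)

    def test_mismatched_panel_rejected(self, adme_panel):
        short = CoverageResult("x", "direct", (True, False))
        with pytest.raises(ValidationError):
            build_matrix(adme_panel, [short])

    def test_zero_results_rejected(self, adme_panel):
        with pytest.raises(ValidationError):
            build_matrix(adme_panel, [])

    def test_uncovered_all_false_rows(self, platform_matrix):
        assert [v.rsid for v in uncovered_variants(platform_matrix)] == [
            "rs72549352",
            "rs72549357",
        ]

    def test_uncovered_extremes(self, adme_panel):
        n = len(adme_panel)
        all_true = build_matrix(
            adme_panel, [CoverageResult("x", "direct", (True,) * n)]
        )
        assert uncovered_variants(all_true) == []
        all_false = build_matrix(
            adme_panel, [CoverageResult("x", "direct", (False,) * n)]
        )
        assert uncovered_variants(all_false) == list(adme_panel)


class TestLdAdjustedCoverage:
    def test_never_below_physical(self):
        a = [0, 1, 0, 1, 1, 0]
        hap = make_panel([a, a, [1, 0, 0, 1, 0, 1]], spacing=1000)
        panel = VariantPanel(
            "p",
            [
                PanelVariant("G", "rs1", hap.site_positions[0]),
                PanelVariant("G", "rs2", hap.site_positions[2]),
            ],
        )
        manifest = PlatformManifest("m", [hap.site_positions[1]])
        phys = physical_coverage(panel, manifest)
        ld = ld_adjusted_coverage(panel, manifest, [hap])
        for direct, tagged in zip(phys.per_variant, ld.per_variant):
            assert tagged or not direct
        assert ld.covered_n >= phys.covered_n

    def test_manifest_with_all_variants_matches_physical(self):
        a = [0, 1, 0, 1]
        hap = make_panel([a, [1, 1, 0, 0]], spacing=1000)
        panel = VariantPanel(
            "p",
            [
                PanelVariant("G", "rs1", hap.site_positions[0]),
                PanelVariant("G", "rs2", hap.site_positions[1]),
            ],
        )
        manifest = PlatformManifest("m", panel.positions)
        phys = physical_coverage(panel, manifest)
        ld = ld_adjusted_coverage(panel, manifest, [hap])
        assert phys.per_variant == ld.per_variant == (True, True)


def region(rid, start, end, gene="CYP2D6", chrom="22"):
    return TargetRegion(gene, rid, GenomicInterval(chrom, start, end))


def probes(*spans, chrom="22", name="d"):
    return ProbeDesign(name, [GenomicInterval(chrom, s, e) for s, e in spans])


class TestRegionBaseCoverage:
    def test_full_tiling(self):
        assert region_base_coverage(region("r", 0, 100), probes((0, 100))) == 1.0

    def test_partial_union(self):
        frac = region_base_coverage(region("r", 0, 100), probes((0, 50), (60, 95)))
        assert frac == pytest.approx(0.85)

    def test_overlap_not_double_counted(self):
        frac = region_base_coverage(region("r", 0, 100), probes((0, 50), (10, 50)))
        assert frac == pytest.approx(0.50)

    def test_split_probe_invariance(self):
        whole = region_base_coverage(region("r", 0, 100), probes((20, 80)))
        split = region_base_coverage(region("r", 0, 100), probes((20, 47), (47, 80)))
        assert whole == split

    def test_monotone_as_probes_added(self):
        r = region("r", 0, 100)
        base = probes((0, 30))
        more = probes((0, 30), (50, 70))
        assert region_base_coverage(r, more) >= region_base_coverage(r, base)

    def test_other_chromosome_ignored(self):
        assert region_base_coverage(region("r", 0, 100), probes((0, 100), chrom="7")) == 0.0


class TestEnrichmentCoverage:
    def _pattern(self, gene_regions, high_flags):
        """Regions and probes realizing given high/low flags (fraction 1.0
        for high, 0.5 for low) on 100-base regions."""
        regions, spans = [], []
        i = 0
        for gene, n in gene_regions:
            for _ in range(n):
                start = i * 1000
                regions.append(region(f"{gene}_{i}", start, start + 100, gene=gene))
                frac = 1.0 if high_flags[i] else 0.5
                spans.append((start, start + int(100 * frac)))
                i += 1
        return regions, probes(*spans)

    def test_sure_select_pattern(self):
        """High counts (5, 19, 4, 5) of regions (5, 20, 4, 5): 33/34 overall."""
        genes = [("CYP2C8", 5), ("CYP2D6", 20), ("CYP3A4", 4), ("CYP3A5", 5)]
        flags = [True] * 5 + [True] * 19 + [False] + [True] * 4 + [True] * 5
        regions, design = self._pattern(genes, flags)
        result = enrichment_coverage(regions, design)
        per_gene = {g: (n, hi, pct) for g, n, hi, _lo, pct in result.per_gene}
        assert per_gene["CYP2D6"] == (20, 19, "95.00")
        high, total, _ = result.overall
        assert (high, total) == (33, 34)

    def test_halo_plex_pattern(self):
        genes = [("CYP2C8", 5), ("CYP2D6", 20), ("CYP3A4", 4), ("CYP3A5", 5)]
        flags = (
            [True] * 5 + [True] * 17 + [False] * 3 + [True] * 3 + [False] + [True] * 5
        )
        regions, design = self._pattern(genes, flags)
        per_gene = {g: pct for g, *_rest, pct in enrichment_coverage(regions, design).per_gene}
        assert per_gene == {
            "CYP2C8": "100.00",
            "CYP2D6": "85.00",
            "CYP3A4": "75.00",
            "CYP3A5": "100.00",
        }

    def test_threshold_inclusive_at_exactly_090(self):
        r = region("r", 0, 100)
        exactly = enrichment_coverage([r], probes((0, 90)))
        below = enrichment_coverage([r], probes((0, 89)))
        assert exactly.per_region[0][3] is True
        assert below.per_region[0][3] is False

    def test_duplicate_region_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            enrichment_coverage(
                [region("r", 0, 100), region("r", 200, 300)], probes((0, 100))
            )

    def test_full_tiling_everywhere(self):
        regions = [region(f"r{i}", i * 200, i * 200 + 100) for i in range(4)]
        design = probes(*[(i * 200, i * 200 + 100) for i in range(4)])
        result = enrichment_coverage(regions, design)
        assert result.overall == (4, 4, "100.00")


class TestRegionsFromPanel:
    def test_variant_inside_own_region(self, adme_panel):
        regions = regions_from_panel(adme_panel, flank_bp=100)
        assert len(regions) == len(adme_panel)
        for v, r in zip(adme_panel, regions):
            assert r.region_id == v.rsid
            assert r.interval.contains_position(v.position)
            assert len(r.interval) == 201
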