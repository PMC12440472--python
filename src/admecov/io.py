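"""Readers and writers for the formats the pipeline touches.

Dialects
--------
* variant panel — TSV with header ``gene  rsid  chrom  pos`` (1-based);
* platform manifest — TSV with header containing ``chrom`` and ``pos``
  (optional ``rsid``);
* probe design — BED3 (0-based half-open);
* target regions — TSV with header ``gene  region_id  chrom  start  end``
  (BED-style 0-based half-open coordinates);
* haplotypes — VCF with phased GT fields, biallelic SNPs only;
* coverage matrix — TSV, one row per panel variant keyed by rsID, one 0/1
  column per ``platform:mode`` pair.

Two fixtures ship with the package: a 34-variant CYP2C8/CYP2D6/CYP3A4/
CYP3A5 chloroquine-pathway panel and its published direct/LD coverage
matrix over five genotyping arrays (Omni 1S/2.5S/2.5/5 and Axiom).

Reader warnings (skipped VCF records, collapsed duplicate manifest rows)
are counted and surfaced — logged and, for the VCF reader, returned in a
stats object — never silent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .core import (
    GenomicInterval,
    GenomicPosition,
    ParseError,
    PlatformManifest,
    PanelVariant,
    ValidationError,
    VariantPanel,
    normalize_chrom,
)
from .coverage import (
    CoverageMatrix,
    CoverageResult,
    ProbeDesign,
    TargetRegion,
    build_matrix,
)
from .ld import HaplotypePanel

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

__all__ = [
    "read_panel",
    "write_panel",
    "read_manifest",
    "write_manifest",
    "read_probe_bed",
    "write_probe_bed",
    "read_regions",
    "write_regions",
    "read_vcf_haplotypes",
    "write_vcf_haplotypes",
    "VcfReadStats",
    "read_coverage_matrix",
    "write_coverage_matrix",
    "write_report",
    "write_matrix_long",
    "load_adme_panel",
    "load_platform_matrix",
    "PLATFORM_COLUMNS",
]

_PANEL_HEADER = ["gene", "rsid", "chrom", "pos"]
_REGION_HEADER = ["gene", "region_id", "chrom", "start", "end"]

#: (platform, mode) column order of the packaged coverage-matrix fixture.
PLATFORM_COLUMNS: tuple[tuple[str, str], ...] = tuple(
    [(p, "direct") for p in ("Omni1S", "Omni2.5S", "Omni2.5", "Omni5", "Axiom")]
    + [(p, "ld") for p in ("Omni1S", "Omni2.5S", "Omni2.5", "Omni5", "Axiom")]
)


def _read_tsv_rows(path: PathLike) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Header fields and (line number, fields) rows of a TSV file."""
    lines = Path(path).read_text().splitlines()
    rows: list[tuple[int, list[str]]] = []
    header: Optional[list[str]] = None
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if header is None:
            header = [f.strip() for f in fields]
        else:
            rows.append((lineno, fields))
    if header is None:
        raise ParseError(f"{path}: empty file")
    return header, rows


def read_panel(path: PathLike) -> VariantPanel:
    """Read a variant panel TSV (header: gene, rsid, chrom, pos)."""
    header, rows = _read_tsv_rows(path)
    if [h.lower() for h in header] != _PANEL_HEADER:
        raise ParseError(
            f"{path}: expected header {_PANEL_HEADER}, got {header}"
        )
    variants = []
    for lineno, fields in rows:
        if len(fields) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
        gene, rsid, chrom, pos_text = (f.strip() for f in fields)
        try:
            pos = int(pos_text)
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: malformed position {pos_text!r}"
            ) from None
        variants.append(
            PanelVariant(gene=gene, rsid=rsid, position=GenomicPosition(chrom, pos))
        )
    return VariantPanel(name=Path(path).stem, variants=variants)


def write_panel(panel: VariantPanel, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PANEL_HEADER) + "\n")
        for v in panel:
            fh.write(f"{v.gene}\t{v.rsid}\t{v.position.chrom}\t{v.position.pos}\n")


def read_manifest(path: PathLike, name: Optional[str] = None) -> PlatformManifest:
    """Read a platform manifest TSV (columns chrom, pos; rsid optional).

    Duplicate positions are collapsed with a logged warning.
    """
    header, rows = _read_tsv_rows(path)
    cols = {h.lower(): i for i, h in enumerate(header)}
    if "chrom" not in cols or "pos" not in cols:
        raise ParseError(
            f"{path}: manifest needs 'chrom' and 'pos' columns, got {header}"
        )
    if not rows:
        raise ParseError(f"{path}: manifest has no sites")
    sites: list[GenomicPosition] = []
    rsids: list[str] = []
    for lineno, fields in rows:
        try:
            pos = int(fields[cols["pos"]])
        except (ValueError, IndexError):
            raise ParseError(f"{path}:{lineno}: malformed pos field") from None
        sites.append(GenomicPosition(fields[cols["chrom"]], pos))
        if "rsid" in cols and len(fields) > cols["rsid"]:
            rsid = fields[cols["rsid"]].strip()
            if rsid:
                rsids.append(rsid)
    unique = set(sites)
    n_dup = len(sites) - len(unique)
    if n_dup:
        logger.warning("%s: collapsed %d duplicate manifest position(s)", path, n_dup)
    manifest = PlatformManifest(
        name=name or Path(path).stem,
        sites=unique,
        rsids=rsids or None,
    )
    logger.info("%s: %d unique sites", path, len(manifest))
    return manifest


def write_manifest(manifest: PlatformManifest, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\n")
        for site in sorted(manifest.sites, key=GenomicPosition.sort_key):
            fh.write(f"{site.chrom}\t{site.pos}\n")


def read_probe_bed(path: PathLike, name: Optional[str] = None) -> ProbeDesign:
    """Read a BED3+ probe/amplicon design (0-based half-open).

    Overlapping intervals are retained as-is; the union is computed at
    coverage time.
    """
    intervals = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: malformed BED coordinates") from None
        try:
            intervals.append(GenomicInterval(chrom, start, end))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return ProbeDesign(name=name or Path(path).stem, intervals=intervals)


def write_probe_bed(design: ProbeDesign, path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in design.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_regions(path: PathLike) -> list[TargetRegion]:
    """Read target regions TSV (gene, region_id, chrom, start, end)."""
    header, rows = _read_tsv_rows(path)
    if [h.lower() for h in header] != _REGION_HEADER:
        raise ParseError(f"{path}: expected header {_REGION_HEADER}, got {header}")
    regions = []
    for lineno, fields in rows:
        gene, region_id, chrom, start, end = (f.strip() for f in fields[:5])
        try:
            interval = GenomicInterval(chrom, int(start), int(end))
        except ValueError:
            raise ParseError(f"{path}:{lineno}: malformed coordinates") from None
        regions.append(TargetRegion(gene=gene, region_id=region_id, interval=interval))
    return regions


def write_regions(regions: Sequence[TargetRegion], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_REGION_HEADER) + "\n")
        for r in regions:
            fh.write(
                f"{r.gene}\t{r.region_id}\t{r.interval.chrom}\t"
                f"{r.interval.start}\t{r.interval.end}\n"
            )


@dataclass(frozen=True, slots=True)
class VcfReadStats:
    """Counted reader warnings for one VCF pass."""

    n_kept: int
    n_unphased: int
    n_multiallelic: int
    n_missing: int
    n_outside_region: int

    @property
    def n_skipped(self) -> int:
        return self.n_unphased + self.n_multiallelic + self.n_missing


def read_vcf_haplotypes(
    path: PathLike,
    region: Optional[GenomicInterval] = None,
    population: Optional[str] = None,
) -> tuple[HaplotypePanel, VcfReadStats]:
    """Read phased biallelic SNPs from a VCF into a haplotype matrix.

    The result has 2 x n_samples haplotype rows. Records that are
    unphased, multi-allelic/non-SNP, or carry missing genotypes are
    skipped with counted warnings (no imputation is attempted). An
    optional region restricts to sites whose 1-based position falls
    inside the 0-based half-open interval.

    Raises :class:`ValidationError` if no usable record remains.
    """
    from cyvcf2 import VCF  # deferred: import cost and optional at runtime

    vcf = VCF(str(path))
    columns: list[np.ndarray] = []
    positions: list[GenomicPosition] = []
    ids: list[str] = []
    n_unphased = n_multi = n_missing = n_outside = 0
    for record in vcf:
        pos = GenomicPosition(record.CHROM, record.POS)
        if region is not None and not region.contains_position(pos):
            n_outside += 1
            continue
        if len(record.ALT) != 1 or not record.is_snp:
            n_multi += 1
            continue
        gts = record.genotypes  # [[a0, a1, phased], ...]
        if any(not g[-1] for g in gts):
            n_unphased += 1
            continue
        alleles = [a for g in gts for a in g[:-1]]
        if any(a < 0 for a in alleles):
            n_missing += 1
            continue
        columns.append(np.asarray(alleles, dtype=np.int8))
        positions.append(pos)
        ids.append(record.ID or str(pos))
    vcf.close()
    stats = VcfReadStats(
        n_kept=len(columns),
        n_unphased=n_unphased,
        n_multiallelic=n_multi,
        n_missing=n_missing,
        n_outside_region=n_outside,
    )
    if stats.n_skipped:
        logger.warning(
            "%s: skipped %d record(s) (%d unphased, %d multi-allelic/non-SNP, "
            "%d with missing genotypes)",
            path,
            stats.n_skipped,
            n_unphased,
            n_multi,
            n_missing,
        )
    if not columns:
        raise ValidationError(
            f"{path}: no phased biallelic SNP records"
            + (" in region" if region is not None else "")
        )
    matrix = np.column_stack(columns)
    panel = HaplotypePanel(
        alleles=matrix,
        site_positions=positions,
        site_ids=ids,
        population=population,
    )
    return panel, stats


def write_vcf_haplotypes(
    panel: HaplotypePanel, path: PathLike, ref: str = "A", alt: str = "G"
) -> None:
    """Write a haplotype panel as a minimal phased VCF (biallelic SNPs).

    Haplotype rows 2i and 2i+1 become sample ``S{i}``; the panel must have
    an even number of haplotypes.
    """
    if panel.n_haplotypes % 2 != 0:
        raise ValidationError("VCF export needs an even number of haplotypes")
    n_samples = panel.n_haplotypes // 2
    sample_names = [f"S{i}" for i in range(n_samples)]
    site_order = sorted(
        range(panel.n_sites), key=lambda i: panel.site_positions[i].sort_key()
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(panel.site_positions[i].chrom for i in site_order):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for j in site_order:
            pos = panel.site_positions[j]
            site_id = panel.site_ids[j] if panel.site_ids else "."
            col = panel.alleles[:, j]
            gts = "\t".join(
                f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(n_samples)
            )
            fh.write(
                f"{pos.chrom}\t{pos.pos}\t{site_id}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_coverage_matrix(path: PathLike, panel: VariantPanel) -> CoverageMatrix:
    """Read a rsID-keyed 0/1 coverage matrix TSV aligned to a panel.

    Header: ``rsid`` then one ``platform:mode`` column per result. The row
    set must equal the panel's rsIDs exactly; rows are re-aligned to panel
    order.
    """
    header, rows = _read_tsv_rows(path)
    if not header or header[0].lower() != "rsid":
        raise ParseError(f"{path}: first column must be 'rsid'")
    columns: list[tuple[str, str]] = []
    for col in header[1:]:
        if ":" not in col:
            raise ParseError(
                f"{path}: column {col!r} is not of the form 'platform:mode'"
            )
        platform, mode = col.rsplit(":", 1)
        if mode not in ("direct", "ld"):
            raise ParseError(f"{path}: unknown mode {mode!r} in column {col!r}")
        columns.append((platform, mode))
    by_rsid: dict[str, list[bool]] = {}
    for lineno, fields in rows:
        rsid = fields[0].strip()
        values = fields[1:]
        if len(values) != len(columns):
            raise ParseError(f"{path}:{lineno}: expected {len(columns)} cells")
        flags = []
        for v in values:
            v = v.strip()
            if v not in ("0", "1"):
                raise ParseError(f"{path}:{lineno}: cell value {v!r} not in {{0,1}}")
            flags.append(v == "1")
        if rsid in by_rsid:
            raise ValidationError(f"{path}: duplicate rsID row {rsid}")
        by_rsid[rsid] = flags
    panel_rsids = set(panel.rsids)
    extra = sorted(set(by_rsid) - panel_rsids)
    missing = sorted(panel_rsids - set(by_rsid))
    if extra or missing:
        raise ValidationError(
            f"{path}: matrix rows do not match panel "
            f"(unknown: {extra or 'none'}; missing: {missing or 'none'})"
        )
    cells = tuple(tuple(by_rsid[rsid]) for rsid in panel.rsids)
    return CoverageMatrix(panel=panel, columns=tuple(columns), cells=cells)


def write_coverage_matrix(matrix: CoverageMatrix, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("rsid\t" + "\t".join(f"{p}:{m}" for p, m in matrix.columns) + "\n")
        for v, row in zip(matrix.panel, matrix.cells):
            fh.write(v.rsid + "\t" + "\t".join(str(int(c)) for c in row) + "\n")


def write_report(
    results: Sequence[CoverageResult],
    path: PathLike,
    format: str = "tsv",
    panel: Optional[VariantPanel] = None,
) -> None:
    """Write per-platform coverage summaries (and, for JSON, per-variant
    detail) with deterministic column order and 2-decimal percentages."""
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("platform\tmode\tcovered_n\ttotal_n\tpercent\n")
            for r in results:
                fh.write(
                    f"{r.platform}\t{r.mode}\t{r.covered_n}\t{r.total_n}\t"
                    f"{r.percent_str}\n"
                )
    elif format == "json":
        payload = []
        for r in results:
            entry = {
                "platform": r.platform,
                "mode": r.mode,
                "covered_n": r.covered_n,
                "total_n": r.total_n,
                "percent": float(r.percent_str),
            }
            if panel is not None:
                entry["per_variant"] = [
                    {"rsid": v.rsid, "covered": bool(flag)}
                    for v, flag in zip(panel, r.per_variant)
                ]
            payload.append(entry)
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise ValidationError(f"unknown report format {format!r}")


def write_matrix_long(matrix: CoverageMatrix, path: PathLike) -> None:
    """Long-format export (variant, platform, mode, covered) suitable for
    heatmap rendering."""
    with open(path, "w") as fh:
        fh.write("rsid\tgene\tplatform\tmode\tcovered\n")
        for v, row in zip(matrix.panel, matrix.cells):
            for (platform, mode), flag in zip(matrix.columns, row):
                fh.write(f"{v.rsid}\t{v.gene}\t{platform}\t{mode}\t{int(flag)}\n")


def _fixture_path(filename: str):
    return resources.files("admecov.data").joinpath(filename)


def load_adme_panel() -> VariantPanel:
    """The packaged 34-variant chloroquine-pathway ADME panel
    (CYP2C8, CYP2D6, CYP3A4, CYP3A5; Hg19 coordinates)."""
    with resources.as_file(_fixture_path("adme_core_panel.tsv")) as p:
        panel = read_panel(p)
    return VariantPanel(name="ADME core", variants=panel.variants)


def load_platform_matrix() -> CoverageMatrix:
    """The packaged direct/LD coverage matrix of the ADME panel over five
    genotyping arrays (Omni 1S, 2.5S, 2.5, 5 and Axiom)."""
    panel = load_adme_panel()
    with resources.as_file(_fixture_path("platform_coverage_matrix.tsv")) as p:
        return read_coverage_matrix(p, panel)
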