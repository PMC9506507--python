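"""End-to-end orchestration: config, group comparisons, annotation, reports.

A run reads the manifest, the intensity table and (optionally) a BED gene
annotation, estimates per-probe log2 ratios against the control panel once,
builds the bin set once, and then executes each configured two-group
comparison: per-bin t-tests, Bonferroni control, merging of significant bins
into regions, gain/loss calls and gene annotation.  Each comparison writes a
region report, a per-bin results table and a gene table; a JSON run manifest
records the parameters, probe/bin counts and the family size actually tested,
so a rerun with identical inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .io import (
    GeneAnnotation, Manifest, RegionReport, SampleIntensitySet, ValidationError,
    read_bed, read_intensity_table, read_manifest, write_region_report,
)
from .estimation import DEFAULT_MIN_COMBINED, probe_log2_ratios
from .binning import (
    DEFAULT_MAX_SIZE, DEFAULT_MIN_PROBES, DEFAULT_TILE, aggregate_bins, build_bins,
)
from .stats import (
    DEFAULT_ALPHA, DEFAULT_THETA, Region, compare_groups, merge_significant_bins,
    results_frame,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "annotate_region", "run_pipeline",
           "regions_to_report"]


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    manifest: str
    intensities: str
    output_dir: str
    samples: Mapping[str, Mapping[str, str]]   # sample -> {role, [group]}
    comparisons: Sequence[tuple[str, str]]
    annotation: str | None = None
    min_probes: int = DEFAULT_MIN_PROBES
    tile: int = DEFAULT_TILE
    max_size: int = DEFAULT_MAX_SIZE
    alpha: float = DEFAULT_ALPHA
    theta: float = DEFAULT_THETA
    min_combined: float = DEFAULT_MIN_COMBINED
    harmonize_chroms: bool = False
    welch: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValidationError("config defines no samples")
        groups = set()
        n_controls = 0
        for sid, entry in self.samples.items():
            role = entry.get("role")
            if role not in ("query", "control"):
                raise ValidationError(f"sample {sid!r}: role must be query|control")
            if role == "query":
                if not entry.get("group"):
                    raise ValidationError(f"query sample {sid!r} needs a group")
                groups.add(entry["group"])
            else:
                n_controls += 1
        if n_controls < 2:
            raise ValidationError("need >= 2 control samples")
        if not self.comparisons:
            raise ValidationError("config defines no comparisons")
        for pair in self.comparisons:
            if len(pair) != 2 or pair[0] == pair[1]:
                raise ValidationError(f"comparison {pair!r} must be two distinct groups")
            for g in pair:
                if g not in groups:
                    raise ValidationError(f"comparison references unknown group {g!r}")
        if self.min_probes < 1:
            raise ValidationError("min_probes must be >= 1")
        if not (1 <= self.tile <= self.max_size) or self.max_size % self.tile:
            raise ValidationError("need tile <= max_size, max_size % tile == 0")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.theta <= 0:
            raise ValidationError("theta must be > 0")
        if self.min_combined < 0:
            raise ValidationError("min_combined must be >= 0")

    @property
    def roles(self) -> dict[str, str]:
        return {s: e["role"] for s, e in self.samples.items()}

    @property
    def groups(self) -> dict[str, str]:
        return {s: e["group"] for s, e in self.samples.items()
                if e["role"] == "query"}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config {path}: expected a mapping")
    params = raw.pop("parameters", {}) or {}
    known = {"manifest", "intensities", "output_dir", "samples", "comparisons",
             "annotation", "log_level"}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"config {path}: unknown keys {sorted(unknown)}")
    comparisons = [tuple(c) for c in raw.get("comparisons", [])]
    return RunConfig(
        manifest=raw.get("manifest", ""),
        intensities=raw.get("intensities", ""),
        output_dir=raw.get("output_dir", "."),
        samples=raw.get("samples", {}),
        comparisons=comparisons,
        annotation=raw.get("annotation"),
        log_level=raw.get("log_level", "INFO"),
        **params,
    )


def _harmonize(chrom: str) -> str:
    return chrom if chrom.lower().startswith("chr") else f"chr{chrom}"


def annotate_region(region: Region, annotation: GeneAnnotation) -> list[str]:
    """Names of annotation records overlapping the region by >= 1 bp.

    Overlap is evaluated in 1-based inclusive coordinates (a record starting
    exactly at the region end still overlaps by one base).  Names are
    deduplicated, preserving annotation input order.
    """
    names = [rec.name
             for rec in annotation.overlapping(region.chrom, region.start, region.end)]
    return list(dict.fromkeys(names))


def regions_to_report(regions: Sequence[Region]) -> RegionReport:
    frame = pd.DataFrame({
        "location": [r.location for r in regions],
        "adj_p": [r.adj_p for r in regions],
        "log2_ratio": [r.log2_ratio for r in regions],
        "length_bp": pd.array([r.length for r in regions], dtype="int64"),
        "state": [r.state for r in regions],
        "genes": [tuple(r.genes) for r in regions],
    }, columns=["location", "adj_p", "log2_ratio", "length_bp", "state", "genes"])
    return RegionReport(frame)


def _gene_table(regions: Sequence[Region], annotation: GeneAnnotation | None
                ) -> pd.DataFrame:
    """Table-3-style gene list: one row per gene over all reported regions."""
    rows = []
    seen = set()
    for region in regions:
        recs = (annotation.overlapping(region.chrom, region.start, region.end)
                if annotation is not None else [])
        for rec in recs:
            if rec.name in seen:
                continue
            seen.add(rec.name)
            rows.append({"gene_id": rec.name, "gene_name": rec.name,
                         "region": region.location,
                         "function": rec.description})
    return pd.DataFrame(rows, columns=["gene_id", "gene_name", "region", "function"])


def run_pipeline(config: RunConfig) -> dict[tuple[str, str], RegionReport]:
    """Execute every configured comparison; returns reports keyed by pair.

    A failure in one comparison is logged and recorded in the run manifest;
    the remaining comparisons still run.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = read_manifest(config.manifest)
    if config.harmonize_chroms:
        probes = manifest.probes.assign(chrom=manifest.probes["chrom"].map(_harmonize))
        manifest = Manifest(probes)
    intensities = read_intensity_table(config.intensities, manifest, config.roles)
    annotation = None
    if config.annotation:
        annotation = read_bed(config.annotation)
        if config.harmonize_chroms:
            from dataclasses import replace
            annotation = GeneAnnotation(
                [replace(rec, chrom=_harmonize(rec.chrom))
                 for rec in annotation.records])

    ratios = probe_log2_ratios(intensities, min_combined=config.min_combined)
    n_excluded = int((~ratios.mask).sum())
    bins = build_bins(manifest, mask=ratios.mask, min_probes=config.min_probes,
                      tile=config.tile, max_size=config.max_size)
    values = aggregate_bins(ratios, bins)

    group_of = config.groups
    reports: dict[tuple[str, str], RegionReport] = {}
    run_info: dict = {
        "version": __version__,
        "parameters": {
            "min_probes": config.min_probes, "tile": config.tile,
            "max_size": config.max_size, "alpha": config.alpha,
            "theta": config.theta, "min_combined": config.min_combined,
            "welch": config.welch,
        },
        "n_probes": len(manifest),
        "n_probes_excluded": n_excluded,
        "n_bins": len(bins),
        "comparisons": {},
    }

    for g_a, g_b in config.comparisons:
        tag = f"{g_a}_vs_{g_b}"
        try:
            samples = [s for s in values.values.columns
                       if group_of.get(s) in (g_a, g_b)]
            sub = values.values[samples]
            from .binning import BinValueMatrix
            sub_values = BinValueMatrix(values=sub, binset=values.binset,
                                        bin_positions=values.bin_positions)
            results = compare_groups(sub_values, group_of, alpha=config.alpha,
                                     order=(g_a, g_b), welch=config.welch)
            regions = merge_significant_bins(results, bins, theta=config.theta)
            if annotation is not None:
                regions = [r.with_genes(annotate_region(r, annotation))
                           for r in regions]
            report = regions_to_report(regions)
            write_region_report(report, outdir / f"regions_{tag}.tsv")
            results_frame(results).to_csv(outdir / f"bins_{tag}.tsv", sep="\t",
                                          index=False)
            _gene_table(regions, annotation).to_csv(
                outdir / f"genes_{tag}.tsv", sep="\t", index=False)
            reports[(g_a, g_b)] = report
            run_info["comparisons"][tag] = {
                "status": "ok",
                "n_bins_tested": len(results),
                "n_significant": int(sum(r.significant for r in results)),
                "n_regions": len(regions),
            }
            log.info("comparison %s: %d bins tested, %d significant, %d regions",
                     tag, len(results), sum(r.significant for r in results),
                     len(regions))
        except Exception as exc:  # keep other comparisons running
            log.error("comparison %s failed: %s", tag, exc)
            run_info["comparisons"][tag] = {"status": f"error: {exc}"}

    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(run_info, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return reports
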