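"""Readers and writers for the pipeline's tabular formats.

This module is the single source of truth for coordinate conventions:

* **Internal coordinates are 1-based inclusive**; the length of an interval is
  ``end - start + 1``.  A region printed as ``chr8:100000001-100750000`` is
  therefore 750,000 bp long.
* **BED input is 0-based half-open** (the BED standard) and is converted to the
  internal convention on read (``start + 1``, ``end``); writing converts back,
  so a read/write round trip reproduces the original BED coordinates exactly.

Formats handled here:

* probe manifest TSV (``probe_id``, ``chrom``, ``pos``),
* wide intensity TSV (``probe_id`` plus ``<sample>.meth`` / ``<sample>.unmeth``
  column pairs; sample roles come from a sidecar mapping),
* BED4+ gene annotation,
* the region report TSV (``location``, ``adj_p``, ``log2_ratio``, ``length_bp``,
  ``state``, ``genes``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "Manifest",
    "SampleIntensitySet",
    "GeneRecord",
    "GeneAnnotation",
    "RegionReport",
    "REPORT_COLUMNS",
    "read_manifest",
    "write_manifest",
    "read_intensity_table",
    "write_intensity_table",
    "read_bed",
    "write_bed",
    "read_region_report",
    "write_region_report",
    "parse_location",
    "format_location",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """Well-formed input that violates a pipeline invariant."""


REPORT_COLUMNS = ("location", "adj_p", "log2_ratio", "length_bp", "state", "genes")

_LOCATION_RE = re.compile(r"^(?P<chrom>[^:\s]+):(?P<start>\d+)-(?P<end>\d+)$")


def chrom_sort_key(chrom: str) -> tuple:
    """Natural chromosome ordering: chr1 < chr2 < ... < chr10 < chrX."""
    body = chrom[3:] if chrom.lower().startswith("chr") else chrom
    try:
        return (0, int(body), "")
    except ValueError:
        return (1, 0, body)


def parse_location(location: str) -> tuple[str, int, int]:
    """Parse a ``chrom:start-end`` string (1-based inclusive coordinates)."""
    m = _LOCATION_RE.match(location.strip())
    if m is None:
        raise FormatError(f"malformed genomic location {location!r}")
    start, end = int(m["start"]), int(m["end"])
    if start < 1 or end < start:
        raise FormatError(f"invalid coordinates in location {location!r}")
    return m["chrom"], start, end


def format_location(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Manifest:
    """Ordered CpG probe coordinates; the sole determinant of the bin set.

    ``probes`` has columns ``probe_id``, ``chrom``, ``pos`` (1-based), sorted by
    (chromosome, position) with a natural chromosome order, and a RangeIndex.
    """

    probes: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.probes
        missing = {"probe_id", "chrom", "pos"} - set(df.columns)
        if missing:
            raise FormatError(f"manifest missing columns: {sorted(missing)}")
        if df["probe_id"].duplicated().any():
            dups = df.loc[df["probe_id"].duplicated(), "probe_id"].unique()[:5]
            raise ValidationError(f"duplicate probe_ids in manifest: {list(dups)}")
        if len(df) and (df["pos"] < 1).any():
            raise ValidationError("manifest positions must be >= 1")

    def __len__(self) -> int:
        return len(self.probes)

    def __eq__(self, other) -> bool:
        return isinstance(other, Manifest) and self.probes.equals(other.probes)

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.probes["probe_id"])

    @property
    def chroms(self) -> list[str]:
        """Chromosomes in manifest (sorted) order."""
        return list(dict.fromkeys(self.probes["chrom"]))


def _sorted_manifest_frame(df: pd.DataFrame) -> pd.DataFrame:
    key = df["chrom"].map(chrom_sort_key)
    order = sorted(range(len(df)), key=lambda i: (key.iloc[i], int(df["pos"].iloc[i])))
    return df.iloc[order].reset_index(drop=True)


def read_manifest(path) -> Manifest:
    """Read a probe manifest TSV (columns probe_id, chrom, pos).

    Rows may appear in any order; the result is sorted by (chrom, pos).
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    missing = {"probe_id", "chrom", "pos"} - set(df.columns)
    if missing:
        raise FormatError(f"manifest {path} missing columns: {sorted(missing)}")
    pos = pd.to_numeric(df["pos"], errors="coerce")
    if pos.isna().any() or not np.allclose(pos.dropna() % 1, 0):
        raise FormatError(f"manifest {path}: non-integer pos values")
    df = df.assign(pos=pos.astype(np.int64))[["probe_id", "chrom", "pos"]]
    return Manifest(_sorted_manifest_frame(df))


def write_manifest(manifest: Manifest, path) -> None:
    manifest.probes.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample intensities
# ---------------------------------------------------------------------------

VALID_ROLES = ("query", "control")


@dataclass
class SampleIntensitySet:
    """Per-sample methylated/unmethylated intensities aligned to a manifest.

    ``meth`` and ``unmeth`` are probes x samples DataFrames indexed by probe_id
    in manifest order; missing probe measurements are NaN (never zero — a zero
    would masquerade as a deletion).  ``roles`` maps each sample to ``"query"``
    or ``"control"``.
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    roles: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.meth.index.equals(self.unmeth.index):
            raise ValidationError("meth/unmeth probe indexes differ")
        if list(self.meth.columns) != list(self.unmeth.columns):
            raise ValidationError("meth/unmeth sample columns differ")
        for df in (self.meth, self.unmeth):
            if (df.to_numpy() < 0).any():
                raise ValidationError("negative intensities are not allowed")
        for s in self.meth.columns:
            role = self.roles.get(s)
            if role not in VALID_ROLES:
                raise ValidationError(f"sample {s!r} has invalid role {role!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meth.columns)

    @property
    def query_samples(self) -> list[str]:
        return [s for s in self.sample_ids if self.roles[s] == "query"]

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.sample_ids if self.roles[s] == "control"]

    def subset(self, samples: Sequence[str]) -> "SampleIntensitySet":
        samples = list(samples)
        return SampleIntensitySet(
            self.meth[samples], self.unmeth[samples],
            {s: self.roles[s] for s in samples},
        )


def read_intensity_table(path, manifest: Manifest,
                         roles: Mapping[str, str],
                         min_coverage: float = 0.5) -> SampleIntensitySet:
    """Read a wide intensity TSV aligned against ``manifest``.

    The table has a ``probe_id`` column followed by ``<sample>.meth`` /
    ``<sample>.unmeth`` column pairs.  Probes present in the table but absent
    from the manifest are dropped with a logged count; manifest probes absent
    from the table become NaN (missing).  A sample covering fewer than
    ``min_coverage`` of the manifest probes is rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    if "probe_id" not in df.columns:
        raise FormatError(f"intensity table {path}: missing probe_id column")
    channels: dict[str, dict[str, str]] = {}
    for col in df.columns:
        if col == "probe_id":
            continue
        sample, dot, channel = col.rpartition(".")
        if not dot or channel not in ("meth", "unmeth") or not sample:
            raise FormatError(f"intensity table {path}: unrecognized column {col!r}")
        channels.setdefault(sample, {})[channel] = col
    samples = list(channels)
    for s in samples:
        if set(channels[s]) != {"meth", "unmeth"}:
            raise FormatError(f"intensity table {path}: sample {s!r} lacks a channel")
    if df["probe_id"].duplicated().any():
        raise ValidationError(f"intensity table {path}: duplicated probe rows")

    known = df["probe_id"].isin(manifest.probe_ids)
    n_dropped = int((~known).sum())
    if n_dropped:
        log.warning("intensity table %s: dropped %d probes absent from manifest",
                    path, n_dropped)
    df = df.loc[known].set_index("probe_id")

    meth = pd.DataFrame(
        {s: pd.to_numeric(df[channels[s]["meth"]], errors="coerce") for s in samples}
    ).reindex(manifest.probe_ids)
    unmeth = pd.DataFrame(
        {s: pd.to_numeric(df[channels[s]["unmeth"]], errors="coerce") for s in samples}
    ).reindex(manifest.probe_ids)
    for name, frame in (("meth", meth), ("unmeth", unmeth)):
        if (frame.to_numpy() < 0).any():
            raise ValidationError(f"intensity table {path}: negative {name} intensity")
    for s in samples:
        covered = (meth[s].notna() & unmeth[s].notna()).mean()
        if covered < min_coverage:
            raise ValidationError(
                f"sample {s!r} covers only {covered:.0%} of manifest probes "
                f"(< {min_coverage:.0%})")
        if s not in roles:
            raise ValidationError(f"sample {s!r} has no declared role")
    return SampleIntensitySet(meth, unmeth, {s: roles[s] for s in samples})


def write_intensity_table(intensities: SampleIntensitySet, path) -> None:
    cols = {}
    for s in intensities.sample_ids:
        cols[f"{s}.meth"] = intensities.meth[s]
        cols[f"{s}.unmeth"] = intensities.unmeth[s]
    out = pd.DataFrame(cols, index=intensities.meth.index)
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Gene annotation (BED)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    """One annotated feature in internal 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    name: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"gene {self.name}: start > end")
        if not self.name:
            raise ValidationError("gene record with empty name")


@dataclass
class GeneAnnotation:
    """Gene intervals for region annotation, with cached interval trees."""

    records: list[GeneRecord]
    _trees: dict = field(default_factory=dict, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.records)

    def _tree(self, chrom: str):
        from intervaltree import IntervalTree

        if chrom not in self._trees:
            tree = IntervalTree()
            for i, rec in enumerate(self.records):
                if rec.chrom == chrom:
                    # half-open tree interval [start, end + 1) covers the
                    # 1-based inclusive record
                    tree[rec.start:rec.end + 1] = i
            self._trees[chrom] = tree
        return self._trees[chrom]

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneRecord]:
        """Records overlapping [start, end] by >= 1 bp, in input order."""
        hits = self._tree(chrom).overlap(start, end + 1)
        return [self.records[i] for i in sorted(iv.data for iv in hits)]


def read_bed(path) -> GeneAnnotation:
    """Read a BED4+ annotation into 1-based inclusive coordinates.

    Columns beyond the fourth are joined into the record's free-text
    ``description`` (used as the "function" field of gene tables).
    """
    records: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"{path}:{lineno}: BED line has {len(fields)} columns, "
                    "need >= 4 (name required)")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise FormatError(f"{path}:{lineno}: end < start")
            if end == start:
                raise FormatError(f"{path}:{lineno}: zero-length interval")
            if not name.strip():
                raise FormatError(f"{path}:{lineno}: empty feature name")
            records.append(GeneRecord(
                chrom=chrom, start=start + 1, end=end, name=name.strip(),
                description=" ".join(f.strip() for f in fields[4:]).strip(),
            ))
    return GeneAnnotation(records)


def write_bed(annotation: GeneAnnotation, path) -> None:
    """Write records back to BED (0-based half-open) coordinates."""
    with open(path, "w") as fh:
        for rec in annotation.records:
            cols = [rec.chrom, str(rec.start - 1), str(rec.end), rec.name]
            if rec.description:
                cols.append(rec.description)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Region report
# ---------------------------------------------------------------------------

@dataclass
class RegionReport:
    """Tabular CNV-region summary: one row per merged significant region.

    ``frame`` columns: location ("chrN:start-end", 1-based inclusive), adj_p,
    log2_ratio, length_bp, state (gain/loss/neutral), genes (tuple of names).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.frame.columns) != list(REPORT_COLUMNS):
            raise FormatError(
                f"region report columns must be {REPORT_COLUMNS}, "
                f"got {list(self.frame.columns)}")
        for _, row in self.frame.iterrows():
            _, start, end = parse_location(row["location"])
            if int(row["length_bp"]) != end - start + 1:
                raise ValidationError(
                    f"region {row['location']}: length_bp {row['length_bp']} "
                    f"inconsistent with coordinates ({end - start + 1})")
            if row["state"] not in ("gain", "loss", "neutral"):
                raise ValidationError(f"invalid state {row['state']!r}")

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, RegionReport) and self.frame.equals(other.frame)


def write_region_report(report: RegionReport, path) -> None:
    """Write the report TSV; floats keep full precision so it round-trips."""
    out = report.frame.copy()
    out["genes"] = [";".join(g) for g in out["genes"]]
    out["adj_p"] = [repr(float(v)) for v in out["adj_p"]]
    out["log2_ratio"] = [repr(float(v)) for v in out["log2_ratio"]]
    out.to_csv(path, sep="\t", index=False)


def read_region_report(path) -> RegionReport:
    df = pd.read_csv(
        path, sep="\t", float_precision="round_trip",
        dtype={"location": str, "state": str, "genes": str, "length_bp": np.int64},
    )
    if df.empty and set(REPORT_COLUMNS) - set(df.columns):
        raise FormatError(f"region report {path}: wrong header")
    genes = [
        tuple(g.split(";")) if isinstance(g, str) and g else ()
        for g in df.get("genes", [])
    ]
    frame = pd.DataFrame({
        "location": df["location"].astype(str) if len(df) else pd.Series(dtype=str),
        "adj_p": df["adj_p"].astype(float) if len(df) else pd.Series(dtype=float),
        "log2_ratio": (df["log2_ratio"].astype(float) if len(df)
                       else pd.Series(dtype=float)),
        "length_bp": (df["length_bp"].astype(np.int64) if len(df)
                      else pd.Series(dtype=np.int64)),
        "state": df["state"].astype(str) if len(df) else pd.Series(dtype=str),
        "genes": pd.Series(genes, dtype=object) if len(df) else pd.Series(dtype=object),
    }, columns=list(REPORT_COLUMNS))
    return RegionReport(frame)
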