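"""Synthetic EPIC-like cohorts with known copy-number ground truth.

The generator emulates the statistical structure of Infinium methylation-array
intensity data that the estimation stage relies on, without replicating array
chemistry.  For probe ``p`` in sample ``s`` the combined (methylated +
unmethylated) intensity is

    I_{p,s} = B_p * gamma_s * (c_eff / 2) * 2 ** eps_{p,s}

where ``B_p`` is a log-normal per-probe baseline brightness, ``gamma_s`` a
log-normal per-sample scale factor (array/DNA-input variation), ``eps`` is
Gaussian multiplicative noise on the log2 scale, and ``c_eff`` is the
cell-fraction-weighted effective copy number

    c_eff = 2 * (1 + phi * (c / 2 - 1))

inside an implanted CNV (``2`` elsewhere and for all control samples, which
are diploid genome-wide).  The intensity is split into the two channels by a
Beta-distributed methylated fraction; the split is irrelevant downstream
because estimation only ever uses the channel sum.

The expected log2 copy-number ratio of an implanted event is therefore
``log2(1 + phi * (c/2 - 1))``: -1 for a pure heterozygous deletion, +0.585
for a pure single-copy gain, attenuated toward 0 by the cell fraction phi.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io import Manifest, SampleIntensitySet, ValidationError, _sorted_manifest_frame

log = logging.getLogger(__name__)

__all__ = [
    "CNVSpec",
    "CohortDesign",
    "Cohort",
    "generate_manifest",
    "expected_log2_ratio",
    "simulate_cohort",
]

TRUTH_COLUMNS = ("sample_id", "chrom", "start", "end",
                 "copy_number", "cell_fraction", "expected_log2_ratio")


@dataclass(frozen=True)
class CNVSpec:
    """A copy-number event implanted into one sample group.

    Coordinates are 1-based inclusive.  ``copy_number`` is the integer copy
    state of the affected cells (diploid = 2) and ``cell_fraction`` the
    proportion of cells carrying it (tissue purity), which attenuates the
    observable log2 ratio toward zero.
    """

    chrom: str
    start: int
    end: int
    copy_number: int
    cell_fraction: float
    group: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(f"CNV {self.chrom}:{self.start}-{self.end}: bad span")
        if self.copy_number < 0 or self.copy_number != int(self.copy_number):
            raise ValidationError("copy_number must be a non-negative integer")
        if not 0.0 <= self.cell_fraction <= 1.0:
            raise ValidationError("cell_fraction must lie in [0, 1]")


def expected_log2_ratio(spec: CNVSpec) -> float:
    """Expected log2 copy-number ratio of an implanted event.

    Returns ``log2(1 + phi * (c/2 - 1))``; a homozygous deletion at full cell
    fraction (c=0, phi=1) has no finite log2 ratio and is rejected.
    """
    rel = 1.0 + spec.cell_fraction * (spec.copy_number / 2.0 - 1.0)
    if rel <= 0.0:
        raise ValidationError(
            f"copy_number={spec.copy_number} at cell_fraction={spec.cell_fraction} "
            "has no finite log2 ratio")
    return math.log2(rel)


def generate_manifest(n_chrom: int, chrom_length: int, probe_density: float,
                      seed: int, min_bin_probes: int = 15) -> Manifest:
    """Random CpG manifest: probes at sorted unique uniform positions.

    Each base pair carries probability ``probe_density`` of hosting a probe,
    so a chromosome receives ~ ``chrom_length * probe_density`` probes.
    Deterministic given ``seed``.  A chromosome too sparse to ever yield a
    bin of ``min_bin_probes`` probes triggers a warning, not an error.
    """
    if n_chrom < 1:
        raise ValidationError("n_chrom must be >= 1")
    if chrom_length < 150_000:
        raise ValidationError("chrom_length must be >= 150,000 bp")
    if probe_density < 0:
        raise ValidationError("probe_density must be >= 0")
    rng = np.random.default_rng(seed)
    frames = []
    for c in range(1, n_chrom + 1):
        n = rng.binomial(chrom_length, min(probe_density, 1.0))
        pos = np.unique(rng.integers(1, chrom_length + 1, size=n)) if n else \
            np.empty(0, dtype=np.int64)
        if len(pos) < min_bin_probes:
            log.warning("chr%d: only %d probes — too sparse for any %d-probe bin",
                        c, len(pos), min_bin_probes)
        frames.append(pd.DataFrame({
            "probe_id": [f"cg{c:02d}_{i:06d}" for i in range(len(pos))],
            "chrom": f"chr{c}",
            "pos": pos.astype(np.int64),
        }))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["probe_id", "chrom", "pos"])
    return Manifest(_sorted_manifest_frame(df))


@dataclass
class CohortDesign:
    """Study-condition parameters for one simulated cohort.

    Defaults describe a small methylation-array cohort: probe baselines spread
    over roughly an order of magnitude around ~2,000 fluorescence units
    (log-normal, sd 0.7 nats), ±10% per-sample scale variation, per-probe
    multiplicative noise of 0.2 on the log2 scale, and a 20-sample diploid
    control panel.
    """

    groups: Mapping[str, int]
    control_count: int = 20
    baseline_log_mean: float = 7.6   # ln scale; e^7.6 ~ 2,000 units
    baseline_log_sd: float = 0.7     # ln scale
    sample_scale_sd: float = 0.1     # ln scale
    noise_sd: float = 0.2            # log2 scale
    meth_fraction_alpha: float = 2.0
    meth_fraction_beta: float = 2.0
    cnvs: Sequence[CNVSpec] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("at least one sample group is required")
        for g, n in self.groups.items():
            if n < 1:
                raise ValidationError(f"group {g!r} must have >= 1 sample")
        if self.control_count < 2:
            raise ValidationError("control_count must be >= 2")
        for name in ("baseline_log_sd", "sample_scale_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for spec in self.cnvs:
            if spec.group not in self.groups:
                raise ValidationError(f"CNV targets unknown group {spec.group!r}")
        self._check_overlaps()

    def _check_overlaps(self) -> None:
        by_key: dict[tuple[str, str], list[CNVSpec]] = {}
        for spec in self.cnvs:
            by_key.setdefault((spec.group, spec.chrom), []).append(spec)
        for specs in by_key.values():
            specs = sorted(specs, key=lambda s: s.start)
            for a, b in zip(specs, specs[1:]):
                if b.start <= a.end:
                    raise ValidationError(
                        f"overlapping CNVs for group {a.group!r} on {a.chrom}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}")


class Cohort(NamedTuple):
    """Simulated intensities plus group labels and the ground-truth table."""

    intensities: SampleIntensitySet
    groups: dict[str, str]          # query sample -> group label
    truth: pd.DataFrame             # TRUTH_COLUMNS, one row per (sample, CNV)


def simulate_cohort(manifest: Manifest, design: CohortDesign) -> Cohort:
    """Draw a full cohort of intensities from ``design`` over ``manifest``.

    All randomness flows from one generator seeded with ``design.seed``, so a
    fixed design reproduces the cohort exactly.  Control samples are diploid
    everywhere; query samples of a CNV's target group carry the event at the
    design's cell fraction.
    """
    chroms = set(manifest.chroms)
    for spec in design.cnvs:
        if spec.chrom not in chroms:
            raise ValidationError(f"CNV chromosome {spec.chrom!r} not in manifest")

    sample_ids: list[str] = []
    group_of: dict[str, str] = {}
    for g, n in design.groups.items():
        for i in range(1, n + 1):
            sid = f"{g}_{i:02d}"
            sample_ids.append(sid)
            group_of[sid] = g
    controls = [f"control_{i:02d}" for i in range(1, design.control_count + 1)]
    all_samples = sample_ids + controls
    roles = {s: "query" for s in sample_ids} | {s: "control" for s in controls}

    n_p, n_s = len(manifest), len(all_samples)
    rng = np.random.default_rng(design.seed)
    baseline = rng.lognormal(design.baseline_log_mean, design.baseline_log_sd, n_p)
    scale = rng.lognormal(0.0, design.sample_scale_sd, n_s)
    eps = rng.normal(0.0, design.noise_sd, size=(n_p, n_s))
    meth_frac = rng.beta(design.meth_fraction_alpha, design.meth_fraction_beta,
                         size=(n_p, n_s))

    chrom_arr = manifest.probes["chrom"].to_numpy()
    pos_arr = manifest.probes["pos"].to_numpy()
    c_eff = np.full((n_p, n_s), 2.0)
    truth_rows = []
    for spec in design.cnvs:
        in_region = (chrom_arr == spec.chrom) & (pos_arr >= spec.start) & \
            (pos_arr <= spec.end)
        exp_ratio = expected_log2_ratio(spec)
        cols = [j for j, s in enumerate(all_samples)
                if group_of.get(s) == spec.group]
        c_eff[np.ix_(in_region, cols)] = 2.0 * (2.0 ** exp_ratio)
        for j in cols:
            truth_rows.append((all_samples[j], spec.chrom, spec.start, spec.end,
                               spec.copy_number, spec.cell_fraction, exp_ratio))

    intensity = baseline[:, None] * scale[None, :] * (c_eff / 2.0) * \
        np.exp2(eps)
    meth = pd.DataFrame(intensity * meth_frac, index=manifest.probe_ids,
                        columns=all_samples)
    unmeth = pd.DataFrame(intensity * (1.0 - meth_frac), index=manifest.probe_ids,
                          columns=all_samples)
    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))
    return Cohort(SampleIntensitySet(meth, unmeth, roles), group_of, truth)


def write_truth(truth: pd.DataFrame, path) -> None:
    """Ground truth as BED-compatible TSV (coordinates stay 1-based here)."""
    truth.to_csv(path, sep="\t", index=False)
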