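"""Per-bin two-group inference, Bonferroni control, region merging, CNV calls.

Each bin's per-sample mean log2 ratios are compared between exactly two groups
with the pooled-variance (Student) two-sample t-test; raw p-values are
Bonferroni-adjusted by the number of bins actually tested, and bins with
adjusted p below alpha are significant.  Maximal runs of significant bins that
are consecutive in the bin set, adjacent on the chromosome and share the sign
of their group difference are merged into regions; a region reports the
minimum adjusted p and the mean delta of its member bins and is called a gain
(delta > theta), a loss (delta < -theta) or neutral.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .io import ValidationError, format_location, parse_location
from .binning import Bin, BinSet, BinValueMatrix

log = logging.getLogger(__name__)

__all__ = [
    "TTest",
    "BinTestResult",
    "Region",
    "students_t",
    "bonferroni",
    "compare_groups",
    "merge_significant_bins",
    "region_length",
    "call_state",
    "results_frame",
]

DEFAULT_ALPHA = 0.05
DEFAULT_THETA = 0.2


class TTest(NamedTuple):
    t: float
    df: int
    p: float
    degenerate: bool = False


def _pooled_t(mean_a, mean_b, var_a, var_b, n_a: int, n_b: int, welch: bool):
    """Vectorized two-sample t.  Inputs are sample means and ddof=1 variances.

    Degenerate zero-variance cells: equal means -> t=0, p=1; unequal means ->
    t=+/-inf, p=0 (flagged by the caller via the returned se==0 mask).
    """
    delta = np.asarray(mean_a, float) - np.asarray(mean_b, float)
    var_a = np.asarray(var_a, float)
    var_b = np.asarray(var_b, float)
    if welch:
        se2 = var_a / n_a + var_b / n_b
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2 ** 2 / ((var_a / n_a) ** 2 / (n_a - 1)
                             + (var_b / n_b) ** 2 / (n_b - 1))
        df = np.where(np.isfinite(df), df, n_a + n_b - 2)
    else:
        pooled = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
        se2 = pooled * (1.0 / n_a + 1.0 / n_b)
        df = np.full_like(delta, n_a + n_b - 2, dtype=float)
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
    zero_se = se == 0
    t = np.where(zero_se & (delta == 0), 0.0, t)
    p = np.where(zero_se, np.where(delta == 0, 1.0, 0.0),
                 2.0 * scipy.stats.t.sf(np.abs(np.where(zero_se, 0.0, t)), df))
    return t, df, p, zero_se & (delta != 0)


def students_t(x_a, x_b, welch: bool = False) -> TTest:
    """Two-sample t-test (pooled-variance Student by default).

    ``df = n_a + n_b - 2`` for the pooled test; the p-value is two-sided.
    If both groups have zero variance the test is degenerate: equal means give
    (t=0, p=1), unequal means (t=+/-inf, p=0, degenerate=True).
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if x_a.size < 2 or x_b.size < 2:
        raise ValidationError("each group needs >= 2 observations")
    t, df, p, degen = _pooled_t(
        x_a.mean(), x_b.mean(), x_a.var(ddof=1), x_b.var(ddof=1),
        x_a.size, x_b.size, welch)
    return TTest(float(t), float(df), float(p), bool(degen))


def bonferroni(raw_p, n_tests: int):
    """Bonferroni family-wise adjustment: ``min(1, p * n_tests)``."""
    p = np.asarray(raw_p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if n_tests < 1:
        raise ValidationError("n_tests must be >= 1")
    adj = np.minimum(1.0, p * n_tests)
    return float(adj) if np.isscalar(raw_p) else adj


@dataclass(frozen=True)
class BinTestResult:
    """One bin's two-group comparison (delta = mean_a - mean_b)."""

    bin: Bin
    binset_index: int
    mean_a: float
    mean_b: float
    delta: float
    t: float
    df: float
    p_raw: float
    p_adj: float
    significant: bool
    degenerate: bool = False


def compare_groups(values: BinValueMatrix, labels: Mapping[str, str],
                   alpha: float = DEFAULT_ALPHA,
                   order: tuple[str, str] | None = None,
                   welch: bool = False) -> list[BinTestResult]:
    """Test every bin between exactly two groups of query samples.

    ``labels`` maps sample id to group; ``order=(A, B)`` fixes the direction
    of delta = mean(A) - mean(B) (default: order of first appearance among the
    matrix columns).  The Bonferroni family size is the number of bins
    actually tested.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    samples = list(values.values.columns)
    for s in samples:
        if s not in labels:
            raise ValidationError(f"sample {s!r} has no group label")
    groups = list(dict.fromkeys(labels[s] for s in samples))
    if len(groups) != 2:
        raise ValidationError(
            f"exactly two groups required, got {len(groups)}: {groups} "
            "(drive pairwise comparisons from the pipeline configuration)")
    if order is not None:
        if sorted(order) != sorted(groups):
            raise ValidationError(f"order {order} does not match groups {groups}")
        groups = list(order)
    g_a, g_b = groups
    cols_a = [s for s in samples if labels[s] == g_a]
    cols_b = [s for s in samples if labels[s] == g_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValidationError("each group needs >= 2 samples")

    A = values.values[cols_a].to_numpy()
    B = values.values[cols_b].to_numpy()
    if not (np.isfinite(A).all() and np.isfinite(B).all()):
        raise ValidationError("bin value matrix contains non-finite values")
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    var_a, var_b = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    t, df, p, degen = _pooled_t(mean_a, mean_b, var_a, var_b,
                                len(cols_a), len(cols_b), welch)
    n_tests = len(values.values)
    if n_tests == 0:
        return []
    p_adj = bonferroni(p, n_tests)
    results = []
    for k in range(n_tests):
        results.append(BinTestResult(
            bin=values.binset.bins[values.bin_positions[k]],
            binset_index=int(values.bin_positions[k]),
            mean_a=float(mean_a[k]), mean_b=float(mean_b[k]),
            delta=float(mean_a[k] - mean_b[k]),
            t=float(t[k]), df=float(df[k]),
            p_raw=float(p[k]), p_adj=float(p_adj[k]),
            significant=bool(p_adj[k] < alpha),
            degenerate=bool(degen[k]),
        ))
    return results


@dataclass(frozen=True)
class Region:
    """A maximal run of consecutive same-sign significant bins."""

    chrom: str
    start: int
    end: int
    bin_indices: tuple[int, ...]     # positions in the BinSet
    adj_p: float                     # min over member bins
    log2_ratio: float                # mean of member deltas
    state: str = "neutral"
    genes: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def location(self) -> str:
        return format_location(self.chrom, self.start, self.end)

    def with_genes(self, genes: Sequence[str]) -> "Region":
        return replace(self, genes=tuple(genes))


def call_state(log2_ratio: float, theta: float = DEFAULT_THETA) -> str:
    """Gain if the ratio exceeds ``theta``, loss if below ``-theta``."""
    if theta <= 0:
        raise ValidationError("theta must be > 0")
    if log2_ratio > theta:
        return "gain"
    if log2_ratio < -theta:
        return "loss"
    return "neutral"


def merge_significant_bins(results: Sequence[BinTestResult], bins: BinSet,
                           theta: float = DEFAULT_THETA) -> list[Region]:
    """Merge significant bins into regions.

    Bins merge when they are consecutive in the bin set (no intervening
    emitted bin), lie on the same chromosome, and their deltas share a sign.
    The region inherits min(adjusted p) and mean(delta) and is state-called
    against ``theta``.
    """
    ordered = sorted(results, key=lambda r: r.binset_index)
    regions: list[Region] = []
    run: list[BinTestResult] = []

    def emit(run: list[BinTestResult]) -> None:
        if not run:
            return
        ratio = float(np.mean([r.delta for r in run]))
        regions.append(Region(
            chrom=run[0].bin.chrom,
            start=run[0].bin.start,
            end=run[-1].bin.end,
            bin_indices=tuple(r.binset_index for r in run),
            adj_p=float(min(r.p_adj for r in run)),
            log2_ratio=ratio,
            state=call_state(ratio, theta),
        ))

    for res in ordered:
        if not res.significant:
            emit(run)
            run = []
            continue
        if run and (res.bin.chrom == run[-1].bin.chrom
                    and res.binset_index == run[-1].binset_index + 1
                    and np.sign(res.delta) == np.sign(run[-1].delta)):
            run.append(res)
        else:
            emit(run)
            run = [res]
    emit(run)
    return regions


def region_length(region) -> int:
    """Length in bp (end - start + 1) of a Region, location string or tuple."""
    if isinstance(region, Region):
        return region.length
    if isinstance(region, str):
        _, start, end = parse_location(region)
        return end - start + 1
    chrom, start, end = region
    return end - start + 1


def results_frame(results: Sequence[BinTestResult]) -> pd.DataFrame:
    """Flatten per-bin results for the full-results TSV."""
    return pd.DataFrame({
        "bin": [r.bin.label for r in results],
        "chrom": [r.bin.chrom for r in results],
        "start": [r.bin.start for r in results],
        "end": [r.bin.end for r in results],
        "n_probes": [r.bin.n_probes for r in results],
        "mean_a": [r.mean_a for r in results],
        "mean_b": [r.mean_b for r in results],
        "delta": [r.delta for r in results],
        "t": [r.t for r in results],
        "df": [r.df for r in results],
        "p_raw": [r.p_raw for r in results],
        "p_adj": [r.p_adj for r in results],
        "significant": [r.significant for r in results],
    })
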