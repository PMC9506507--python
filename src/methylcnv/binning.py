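"""Fixed genomic bins and per-sample bin aggregation.

Bins are the unit of statistical testing.  They are a pure function of the
probe manifest (plus the probe retention mask and the three size parameters),
so the bin set is identical for every sample and every cohort drawn on the
same array — the property that lets a per-bin two-group test be well defined.

Construction: each chromosome is tiled from position 1 into consecutive
``tile``-bp windows.  Windows are accumulated left to right until the
accumulated probe count reaches ``min_probes``; the accumulated span is then
emitted as one bin and accumulation restarts.  If the span would exceed
``max_size`` before reaching ``min_probes``, the accumulator is flushed
without emitting a bin.  Every emitted bin therefore holds >= ``min_probes``
probes and spans between ``tile`` and ``max_size`` bp (a whole number of
tiles); a window reaching ``min_probes`` exactly at ``max_size`` is emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .io import Manifest, ValidationError, format_location
from .estimation import LogRatioMatrix

log = logging.getLogger(__name__)

__all__ = ["Bin", "BinSet", "BinValueMatrix", "build_bins", "aggregate_bins"]

DEFAULT_MIN_PROBES = 15
DEFAULT_TILE = 50_000
DEFAULT_MAX_SIZE = 150_000


@dataclass(frozen=True)
class Bin:
    chrom: str
    start: int          # 1-based inclusive
    end: int
    probe_indices: np.ndarray = field(compare=False)  # rows of the manifest

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    @property
    def n_probes(self) -> int:
        return len(self.probe_indices)

    @property
    def label(self) -> str:
        return format_location(self.chrom, self.start, self.end)

    def __eq__(self, other) -> bool:
        return (isinstance(other, Bin)
                and (self.chrom, self.start, self.end) ==
                (other.chrom, other.start, other.end)
                and np.array_equal(self.probe_indices, other.probe_indices))


@dataclass
class BinSet:
    """Ordered, non-overlapping bins plus the parameters that produced them."""

    bins: list[Bin]
    probe_ids: pd.Index          # the manifest probe index the bins refer to
    min_probes: int = DEFAULT_MIN_PROBES
    tile: int = DEFAULT_TILE
    max_size: int = DEFAULT_MAX_SIZE

    def __len__(self) -> int:
        return len(self.bins)

    def __eq__(self, other) -> bool:
        return (isinstance(other, BinSet)
                and self.bins == other.bins
                and self.probe_ids.equals(other.probe_ids)
                and (self.min_probes, self.tile, self.max_size) ==
                (other.min_probes, other.tile, other.max_size))

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin": [b.label for b in self.bins],
            "chrom": [b.chrom for b in self.bins],
            "start": [b.start for b in self.bins],
            "end": [b.end for b in self.bins],
            "n_probes": [b.n_probes for b in self.bins],
        })

    def to_bed(self, path) -> None:
        """BED export (0-based half-open) for genome-browser inspection."""
        with open(path, "w") as fh:
            for b in self.bins:
                fh.write(f"{b.chrom}\t{b.start - 1}\t{b.end}\t{b.label}\n")


def build_bins(manifest: Manifest, mask: pd.Series | np.ndarray | None = None,
               min_probes: int = DEFAULT_MIN_PROBES, tile: int = DEFAULT_TILE,
               max_size: int = DEFAULT_MAX_SIZE) -> BinSet:
    """Construct the bin set for a manifest (greedy tile merge, see module doc).

    ``mask`` marks retained probes (default: all).  Deterministic; a
    chromosome may legitimately yield zero bins.
    """
    if min_probes < 1:
        raise ValidationError("min_probes must be >= 1")
    if tile < 1 or max_size < tile:
        raise ValidationError("need 1 <= tile <= max_size")
    if max_size % tile != 0:
        raise ValidationError("max_size must be a multiple of tile")
    if mask is None:
        kept = np.ones(len(manifest), dtype=bool)
    else:
        kept = np.asarray(mask, dtype=bool)
        if kept.shape != (len(manifest),):
            raise ValidationError("mask length does not match manifest")

    chrom_arr = manifest.probes["chrom"].to_numpy()
    pos_arr = manifest.probes["pos"].to_numpy()
    max_tiles = max_size // tile
    bins: list[Bin] = []
    for chrom in manifest.chroms:
        rows = np.flatnonzero((chrom_arr == chrom) & kept)
        if rows.size == 0:
            continue
        pos = pos_arr[rows]  # sorted, manifest is coordinate-ordered
        n_windows = int(np.ceil(pos[-1] / tile))
        # probe pointer range per window via binary search on sorted positions
        edges = np.searchsorted(pos, np.arange(1, n_windows + 1) * tile,
                                side="right")
        acc_start_win = 0
        acc_lo = 0
        for w in range(n_windows):
            hi = edges[w]
            n_acc = hi - acc_lo
            if n_acc >= min_probes:
                bins.append(Bin(
                    chrom=chrom,
                    start=acc_start_win * tile + 1,
                    end=(w + 1) * tile,
                    probe_indices=rows[acc_lo:hi],
                ))
                acc_start_win, acc_lo = w + 1, hi
            elif (w + 1 - acc_start_win) >= max_tiles:
                # flush: span hit max_size short of min_probes; no bin emitted
                acc_start_win, acc_lo = w + 1, hi
        # trailing accumulator (< min_probes) is discarded
    return BinSet(bins=bins, probe_ids=manifest.probe_ids,
                  min_probes=min_probes, tile=tile, max_size=max_size)


@dataclass
class BinValueMatrix:
    """Per-bin, per-query-sample mean log2 ratios.

    ``values`` rows are labelled ``chrom:start-end``; ``bin_positions`` maps
    each row back to its index in ``binset`` (bins whose probes were all
    excluded post-hoc are dropped and do not appear).
    """

    values: pd.DataFrame
    binset: BinSet
    bin_positions: np.ndarray


def aggregate_bins(ratios: LogRatioMatrix, bins: BinSet) -> BinValueMatrix:
    """Mean per-probe ratio over each bin's retained probes, per sample.

    The ratio matrix must come from the same manifest the bins were built on.
    Bins left with no finite probe value are dropped with a logged count.
    """
    if not ratios.values.index.equals(bins.probe_ids):
        raise ValidationError("ratio matrix and bin set built from different "
                              "manifests")
    mat = ratios.values.to_numpy()
    rows = []
    positions = []
    labels = []
    n_dropped = 0
    for k, b in enumerate(bins.bins):
        sub = mat[b.probe_indices, :]
        finite = np.isfinite(sub)
        if not finite.any():
            n_dropped += 1
            continue
        with np.errstate(invalid="ignore"):
            rows.append(np.nanmean(sub, axis=0))
        positions.append(k)
        labels.append(b.label)
    if n_dropped:
        log.warning("aggregate_bins: dropped %d/%d bins with no retained probes",
                    n_dropped, len(bins))
    values = pd.DataFrame(
        np.asarray(rows) if rows else np.empty((0, ratios.values.shape[1])),
        index=pd.Index(labels, name="bin"),
        columns=ratios.values.columns,
    )
    return BinValueMatrix(values=values, binset=bins,
                          bin_positions=np.asarray(positions, dtype=int))
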