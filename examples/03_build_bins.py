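"""Construct the fixed genomic bin set from a probe manifest.

Bins hold at least 15 CpG probes and span 50-150 kb (whole 50-kb tiles).
They depend only on the manifest, so the same bin set applies to every
sample — the property that makes per-bin group comparisons meaningful.
"""

from collections import Counter

from methylcnv import build_bins, generate_manifest

manifest = generate_manifest(n_chrom=2, chrom_length=5_000_000,
                             probe_density=4e-4, seed=3)
bins = build_bins(manifest)  # defaults: min_probes=15, tile=50 kb, max 150 kb

sizes = Counter(b.size for b in bins.bins)
print(f"{len(manifest)} probes -> {len(bins)} bins")
print("bin sizes (bp -> count):",
      {size: sizes[size] for size in sorted(sizes)})
print("min probes per bin:", min(b.n_probes for b in bins.bins))
print("\nfirst three bins:")
print(bins.frame.head(3).to_string(index=False))
# Single 50-kb tiles already holding 15 probes become bins directly; sparser
# stretches merge 2-3 adjacent tiles, and stretches that cannot reach 15
# probes within 150 kb are skipped entirely.
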