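import numpy as np
import pandas as pd
import pytest

from methylcnv import (
    CNVSpec, CohortDesign, Manifest, aggregate_bins, build_bins, compare_groups,
    generate_manifest, probe_log2_ratios, simulate_cohort,
)


def make_manifest(positions: dict[str, list[int]]) -> Manifest:
    """Manifest from explicit per-chromosome probe positions."""
    rows = []
    for chrom, pos_list in positions.items():
        for i, pos in enumerate(sorted(pos_list)):
            rows.append((f"{chrom}_p{i:04d}", chrom, pos))
    df = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"])
    return Manifest(df.reset_index(drop=True))


def run_replicate(seed: int, *, noise_sd: float = 0.2, cnvs=(),
                  groups=None, control_count: int = 20,
                  chrom_length: int = 10_000_000, probe_density: float = 4e-4,
                  alpha: float = 0.05):
    """One full synthetic pipeline replicate; returns intermediate objects."""
    manifest = generate_manifest(1, chrom_length, probe_density, seed=seed)
    design = CohortDesign(groups=groups or {"case": 8, "ref": 8},
                          control_count=control_count, noise_sd=noise_sd,
                          cnvs=tuple(cnvs), seed=seed)
    cohort = simulate_cohort(manifest, design)
    ratios = probe_log2_ratios(cohort.intensities)
    bins = build_bins(manifest, mask=ratios.mask)
    values = aggregate_bins(ratios, bins)
    results = compare_groups(values, cohort.groups, alpha=alpha,
                             order=("case", "ref"))
    return manifest, cohort, ratios, bins, values, results


@pytest.fixture(scope="session")
def small_cohort():
    """A compact no-CNV cohort reused by estimation/binning tests."""
    manifest = generate_manifest(1, 1_000_000, 1e-3, seed=7)
    design = CohortDesign(groups={"case": 4, "ref": 4}, control_count=12,
                          noise_sd=0.1, seed=7)
    cohort = simulate_cohort(manifest, design)
    return manifest, design, cohort


@pytest.fixture
def deletion_spec():
    return CNVSpec(chrom="chr1", start=2_000_001, end=2_200_000,
                   copy_number=1, cell_fraction=1.0, group="case")
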