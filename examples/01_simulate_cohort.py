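"""Simulate a methylation-array cohort with one implanted deletion.

Builds a random CpG manifest, draws intensities for two query groups plus a
diploid control panel, and implants a heterozygous deletion (copy number 1 at
full cell fraction) into the "case" group.
"""

from methylcnv import CNVSpec, CohortDesign, expected_log2_ratio, \
    generate_manifest, simulate_cohort

manifest = generate_manifest(n_chrom=1, chrom_length=5_000_000,
                             probe_density=6e-4, seed=1)
deletion = CNVSpec(chrom="chr1", start=2_000_001, end=2_200_000,
                   copy_number=1, cell_fraction=1.0, group="case")
design = CohortDesign(groups={"case": 6, "ref": 6}, control_count=15,
                      noise_sd=0.1, cnvs=(deletion,), seed=1)
cohort = simulate_cohort(manifest, design)

print(f"manifest: {len(manifest)} probes on {manifest.chroms}")
print(f"samples:  {len(cohort.intensities.query_samples)} query + "
      f"{len(cohort.intensities.control_samples)} controls")
print(f"implanted deletion at {deletion.chrom}:{deletion.start}-{deletion.end}, "
      f"expected log2 ratio {expected_log2_ratio(deletion):+.3f}")
print("\nground truth (one row per affected sample):")
print(cohort.truth.head(3).to_string(index=False))
# The expected log2 ratio of -1.0 is what a query/reference intensity ratio of
# 1/2 (one copy lost out of two, in every cell) looks like on the log2 scale.
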