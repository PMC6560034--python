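"""Simulate a synthetic cohort with known facial-genetic ground truth.

Builds admixed genotypes under a Balding-Nichols model, an unadmixed
reference panel, covariates, and 3D faces shaped by sex/age/BMI/ancestry
and causal-SNP effect fields, then writes everything to plain-text files
(VCF, coordinate tables, CSV, JSON).
"""

import numpy as np

from facedna import simulate_cohort, write_cohort

cohort = simulate_cohort(
    n_individuals=150, n_panel=60, n_snps=500, n_causal_snps=4,
    n_landmarks=120, seed=7,
)
manifest = write_cohort(cohort, "scratch/example_cohort")

maf = np.nanmean(cohort.genotypes, axis=0) / 2
print(f"individuals: {cohort.n_individuals}, SNPs: {cohort.n_snps}, "
      f"landmarks: {cohort.faces.shape[1]}")
print(f"mean minor-allele frequency: {np.minimum(maf, 1 - maf).mean():.3f}")
print(f"causal SNPs (ground truth): {cohort.causal_snps}")
print(f"effect fields: {[e.feature_name for e in cohort.effects]}")
print(f"written to scratch/example_cohort ({manifest})")
# The causal SNP ids and effect fields are the ground truth that the
# association scan and classifiers downstream are expected to recover.
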