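"""QC a simulated panel pair and compare per-site nucleotide diversity.

Reads the VCF fixture written by 01_simulate_accession.py (run that
first), applies the QC chain (DH heterozygote masking, pooled-minor
allele harmonization, monomorphic / HWE / missingness filters), then
compares per-site pi between LR and DH and bins the joint SFS.
"""

from pathlib import Path

import numpy as np

from dhdrift import (
    compare_pair_diversity,
    define_alternative_allele,
    filter_hwe,
    filter_monomorphic,
    joint_sfs,
    mask_dh_heterozygotes,
    read_genotypes,
    read_sample_sheet,
    site_counts,
)

fx = Path("scratch/example_accession")
sheet = read_sample_sheet(fx / "samples.tsv")
lr = read_genotypes(fx / "lr.vcf", sheet)
dh = read_genotypes(fx / "dh.vcf", sheet)

dh, n_masked = mask_dh_heterozygotes(dh)
lr, dh = define_alternative_allele([lr, dh])
n_before = lr.n_sites
lr, dh = filter_monomorphic([lr, dh])
remove = filter_hwe({"SIM1": lr})
keep = np.flatnonzero(~remove)
lr, dh = lr.take_sites(keep), dh.take_sites(keep)

print(f"DH heterozygous calls masked:  {n_masked}")
print(f"sites after monomorphic+HWE:   {lr.n_sites} (from {n_before})")

res = compare_pair_diversity(lr, dh)
print(f"mean per-site pi (LR):         {res.mean_pi_lr:.4f}")
print(f"mean per-site pi (DH):         {res.mean_pi_dh:.4f}")
print(f"Mann-Whitney two-sided p:      {res.p_value:.3g}")

sfs = joint_sfs(site_counts(lr, dh), n_bins=10)
diag = np.trace(sfs.counts) / sfs.n_sites
print(f"jSFS sites on the diagonal:    {100 * diag:.1f}%")
# pi(DH) < pi(LR) reflects both the instantaneous inbreeding of DH
# production and selection purging alternative alleles from the library;
# off-diagonal jSFS mass marks sites whose frequency shifted between panels.
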