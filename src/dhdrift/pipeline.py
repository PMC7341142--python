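"""End-to-end analysis of one LR/DH accession pair from files to TSVs.

Glues the modules together in the canonical order: read panels, QC
(alternative-allele harmonization, DH heterozygote masking, monomorphic /
HWE / missingness filters), per-site diversity and the jSFS, both outlier
tests with fates, haplotype windows, and the heterozygosity enrichment of
aSFS outliers against frequency-matched LD-pruned controls.  All
randomness derives from the single ``seed``, so outputs are byte-stable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from dhdrift import diversity, enrichment, genotype_io, haplotypes, outliers


def run_accession_pipeline(
    lr_vcf: str | Path,
    dh_vcf: str | Path,
    sheet_path: str | Path,
    out_dir: str | Path,
    seed: int = 0,
    *,
    map_path: str | Path | None = None,
    hwe_alpha: float = 0.05,
    max_missing: float = 0.99,
    model: outliers.ModelConfig | None = None,
    window_kb: int = 50,
    n_boot: int = 1000,
) -> dict[str, Path]:
    """Run the full single-accession analysis and write TSV reports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = model or outliers.ModelConfig()

    sheet = genotype_io.read_sample_sheet(sheet_path)
    lr = genotype_io.read_genotypes(lr_vcf, sheet)
    dh = genotype_io.read_genotypes(dh_vcf, sheet)
    accession = sheet.accessions[0]

    dh, n_masked = genotype_io.mask_dh_heterozygotes(dh)
    lr, dh = genotype_io.define_alternative_allele([lr, dh])
    lr, dh = genotype_io.filter_monomorphic([lr, dh])
    hwe_remove = genotype_io.filter_hwe({accession: lr}, alpha=hwe_alpha)
    keep = np.flatnonzero(~hwe_remove)
    lr, dh = lr.take_sites(keep), dh.take_sites(keep)
    miss_frac = np.maximum(lr.missing_mask().mean(axis=0), dh.missing_mask().mean(axis=0))
    keep = np.flatnonzero(miss_frac <= max_missing)
    lr, dh = lr.take_sites(keep), dh.take_sites(keep)

    counts = genotype_io.site_counts(lr, dh)
    paths: dict[str, Path] = {}

    pair = diversity.compare_pair_diversity(lr, dh)
    paths["site_pi"] = out / "site_pi.tsv"
    pair.sites.to_csv(paths["site_pi"], sep="\t", index=False, float_format="%.8g")

    jsfs = diversity.joint_sfs(counts)
    paths["jsfs"] = out / "jsfs.tsv"
    jsfs.to_frame().to_csv(paths["jsfs"], sep="\t", index=False)

    asfs = outliers.asfs_classify_panel(counts, model)
    asfs["accession"] = accession
    paths["asfs"] = out / "asfs.tsv"
    asfs.to_csv(paths["asfs"], sep="\t", index=False, float_format="%.8g")

    joint = outliers.joint_probability_panel(counts, model)
    joint["outlier"] = outliers.flag_joint_outliers(
        joint["neg_log10_P"], model.outlier_fraction
    )
    joint["accession"] = accession
    paths["jointprob"] = out / "jointprob.tsv"
    joint.to_csv(paths["jointprob"], sep="\t", index=False, float_format="%.8g")

    fates = [
        outliers.outlier_fate(
            genotype_io.SiteCounts(r.site_id, r.l, r.n_L, r.d, r.n_D),
            r.asfs_class != "inside",
        )
        for r in asfs.itertuples()
    ]
    paths["fates"] = out / "fates.tsv"
    pd.DataFrame({"site_id": asfs["site_id"], "fate": fates}).to_csv(
        paths["fates"], sep="\t", index=False
    )

    windows = haplotypes.make_physical_windows(lr.sites, window_kb * 1000)
    hw = haplotypes.window_haplotype_analysis(lr, dh, windows)
    paths["haplotypes"] = out / "haplotypes.tsv"
    haplotypes.haplotype_table_frame(hw, accession).to_csv(
        paths["haplotypes"], sep="\t", index=False, float_format="%.8g"
    )

    het = diversity.genotype_frequencies(lr).set_index("site_id")["freq_het"]
    out_ids = set(asfs.loc[asfs["asfs_class"] != "inside", "site_id"])
    pool_ids = set(asfs["site_id"]) - out_ids
    lr_freq = pd.Series(
        counts["l"].to_numpy() / np.maximum(counts["n_L"].to_numpy(), 1),
        index=counts["site_id"],
    )
    rows = []
    if len(out_ids) >= 2 and len(pool_ids) >= 2:
        pruned = enrichment.prune_ld(lr, pool_ids)
        ctrl = enrichment.frequency_match_sample(
            lr_freq[sorted(out_ids)], lr_freq[sorted(pruned)], seed=seed
        )
        if len(ctrl) >= 2:
            res = enrichment.heterozygosity_enrichment(
                het[sorted(out_ids)].to_numpy(), het[ctrl].to_numpy(),
                n_boot=n_boot, seed=seed,
            )
            rows.append(
                (accession, "outliers", res.n_outliers, res.mean_het_outliers, res.p_value)
            )
            rows.append(
                (accession, "controls", res.n_controls, res.mean_het_controls, res.p_value)
            )
    paths["het_enrichment"] = out / "het_enrichment.tsv"
    pd.DataFrame(
        rows, columns=["accession", "group", "n_snps", "mean_het", "boot_p"]
    ).to_csv(paths["het_enrichment"], sep="\t", index=False, float_format="%.8g")

    return paths
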