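"""Genotype panel I/O, QC filters and imputation error metrics.

The carriers here are deliberately simple: a :class:`GenotypeMatrix` holds
an alternative-allele dosage table (samples x sites, ``-1`` for missing)
plus optional phased haplotypes, and all downstream statistics consume
per-site sufficient statistics derived from it.  VCF parsing goes through
cyvcf2; writing produces plain-text VCF so fixtures round-trip exactly.

QC follows the order used for SNP-array landrace/DH panels: harmonize the
alternative allele as the pooled minor allele, drop sites monomorphic
across all accessions, drop sites violating Hardy-Weinberg equilibrium
(exact mid-p test) in every landrace accession, mask residual DH
heterozygotes as missing, and drop near-all-missing sites.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

MISSING = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "site_id"]


@dataclass
class GenotypeMatrix:
    """Samples x sites alternative-allele dosage table.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers (rows of ``dosages``).
    sites : pandas.DataFrame
        One row per site with columns ``chrom, pos, ref, alt, site_id``,
        sorted by (chrom, pos); positions are 1-based as in VCF.
    dosages : ndarray of shape (n_samples, n_sites)
        Alternative-allele counts in {0, 1, 2}; ``-1`` marks missing.
    haplotypes : ndarray of shape (n_samples, n_sites, 2), optional
        Phased alleles in {0, 1}; ``-1`` marks missing/unphased cells.
        Wherever both alleles are present their sum equals the dosage.
    """

    samples: list[str]
    sites: pd.DataFrame
    dosages: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        if self.dosages.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> np.ndarray:
        return self.sites["site_id"].to_numpy()

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the sites at positional ``index``."""
        index = np.asarray(index)
        hap = self.haplotypes[:, index, :] if self.haplotypes is not None else None
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[index].reset_index(drop=True),
            dosages=self.dosages[:, index].copy(),
            haplotypes=None if hap is None else hap.copy(),
        )

    def take_samples(self, names: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        idx = np.array([pos[n] for n in names])
        hap = self.haplotypes[idx] if self.haplotypes is not None else None
        return GenotypeMatrix(
            samples=list(names),
            sites=self.sites.copy(),
            dosages=self.dosages[idx].copy(),
            haplotypes=None if hap is None else hap.copy(),
        )

    def validate(self) -> None:
        """Raise if internal invariants are broken."""
        d = self.dosages
        ok = (d == MISSING) | ((d >= 0) & (d <= 2))
        if not ok.all():
            raise ValueError("dosages outside {missing, 0, 1, 2}")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        if self.sites["site_id"].duplicated().any():
            raise ValueError("duplicate site ids")
        if self.haplotypes is not None:
            h = self.haplotypes
            both = (h[..., 0] >= 0) & (h[..., 1] >= 0)
            s = h[..., 0] + h[..., 1]
            if np.any(both & (self.dosages != s)):
                raise ValueError("phased alleles inconsistent with dosage")


@dataclass
class SampleSheet:
    """Maps samples to accessions and to the LR or DH population."""

    table: pd.DataFrame  # columns: sample, accession, population

    def __post_init__(self) -> None:
        required = {"sample", "accession", "population"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"sample sheet needs columns {sorted(required)}")
        bad = set(self.table["population"]) - {"LR", "DH"}
        if bad:
            raise ValueError(f"population must be LR or DH, got {sorted(bad)}")
        if self.table["sample"].duplicated().any():
            dup = self.table.loc[self.table["sample"].duplicated(), "sample"]
            raise ValueError(f"duplicate samples in sheet: {list(dup)}")

    def samples_for(self, accession: str | None = None, population: str | None = None) -> list[str]:
        t = self.table
        if accession is not None:
            t = t[t["accession"] == accession]
        if population is not None:
            t = t[t["population"] == population]
        return list(t["sample"])

    @property
    def accessions(self) -> list[str]:
        return sorted(self.table["accession"].unique())


@dataclass
class ImputationQC:
    """Per-site imputation error summary: E = 1 - z / (k - m)."""

    per_site: pd.DataFrame  # columns: site_id, z, k, m, E
    mean_error: float


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep="\t", dtype={"sample": str, "accession": str}))


def read_genotypes(vcf_path: str | Path, sheet: SampleSheet | None = None) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into a :class:`GenotypeMatrix`.

    Multiallelic or indel records raise with the offending locus.  Phase is
    retained per cell when the VCF encodes it (homozygous calls are
    trivially phased).  Sites are sorted by (chrom, pos).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    if sheet is not None:
        known = set(sheet.table["sample"])
        unknown = [s for s in samples if s not in known]
        if unknown:
            raise ValueError(f"VCF samples absent from sample sheet: {unknown}")

    rows, dos, haps = [], [], []
    any_phase = False
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"multiallelic record at {v.CHROM}:{v.POS}")
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            raise ValueError(f"non-SNP record at {v.CHROM}:{v.POS}")
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0], vid))
        d = np.empty(len(samples), dtype=np.int16)
        h = np.full((len(samples), 2), MISSING, dtype=np.int8)
        for i, (a0, a1, phased) in enumerate((g[0], g[1], g[2]) for g in v.genotypes):
            if a0 < 0 or a1 < 0:
                d[i] = MISSING
            else:
                d[i] = a0 + a1
                if phased or a0 == a1:
                    h[i] = (a0, a1)
                    any_phase = True
        dos.append(d)
        haps.append(h)

    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    dosages = (
        np.stack(dos, axis=1) if dos else np.empty((len(samples), 0), dtype=np.int16)
    )
    hap = np.stack(haps, axis=1) if (haps and any_phase) else None
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    gm = GenotypeMatrix(samples, sites.iloc[order], dosages[:, order],
                        None if hap is None else hap[:, order, :])
    gm.validate()
    return gm


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a plain-text VCF 4.2 preserving dosage and phase exactly."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in gm.sites["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        hap = gm.haplotypes
        for j, site in gm.sites.iterrows():
            gts = []
            for i in range(gm.n_samples):
                d = gm.dosages[i, j]
                if hap is not None and hap[i, j, 0] >= 0 and hap[i, j, 1] >= 0:
                    gts.append(f"{hap[i, j, 0]}|{hap[i, j, 1]}")
                elif d == MISSING:
                    gts.append("./.")
                else:
                    gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(d)])
            fh.write(f"{site.chrom}\t{site.pos}\t{site.site_id}\t{site.ref}\t"
                     f"{site.alt}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# Per-site sufficient statistics


def site_counts(lr: GenotypeMatrix, dh: GenotypeMatrix) -> pd.DataFrame:
    """Per-site allele counts (l, n_L, d, n_D) over non-missing genotypes.

    ``l``/``d`` are alternative-allele counts and ``n_L``/``n_D`` genotyped
    chromosome counts (2 x non-missing diploids) in the LR and DH panels.
    """
    if not np.array_equal(lr.site_ids, dh.site_ids):
        raise ValueError("LR and DH panels must share an identical site list")
    lmiss = lr.missing_mask()
    dmiss = dh.missing_mask()
    l = np.where(lmiss, 0, lr.dosages).sum(axis=0)
    d = np.where(dmiss, 0, dh.dosages).sum(axis=0)
    n_L = 2 * (~lmiss).sum(axis=0)
    n_D = 2 * (~dmiss).sum(axis=0)
    return pd.DataFrame(
        {"site_id": lr.site_ids, "l": l, "n_L": n_L, "d": d, "n_D": n_D}
    )


# ---------------------------------------------------------------------------
# Allele harmonization and filters


def _pooled_alt_fraction(panels: list[GenotypeMatrix]) -> np.ndarray:
    alt = np.zeros(panels[0].n_sites, dtype=float)
    tot = np.zeros(panels[0].n_sites, dtype=float)
    for gm in panels:
        miss = gm.missing_mask()
        alt += np.where(miss, 0, gm.dosages).sum(axis=0)
        tot += 2.0 * (~miss).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)


def define_alternative_allele(panels: list[GenotypeMatrix]) -> list[GenotypeMatrix]:
    """Recode so the pooled minor allele across all panels is the alternative.

    Sites whose pooled alternative-allele frequency exceeds 0.5 have their
    coding flipped (dosage x -> 2 - x, ref/alt swapped); an exact 0.5 tie
    keeps the input coding.
    """
    ref0, alt0 = panels[0].sites["ref"].to_numpy(), panels[0].sites["alt"].to_numpy()
    for gm in panels[1:]:
        if not np.array_equal(gm.site_ids, panels[0].site_ids):
            raise ValueError("panels must share site ids")
        same = (gm.sites["ref"].to_numpy() == ref0) & (gm.sites["alt"].to_numpy() == alt0)
        if not same.all():
            bad = panels[0].site_ids[~same][:5]
            raise ValueError(f"mismatched ref/alt coding between panels at {list(bad)}")
    freq = _pooled_alt_fraction(panels)
    flip = freq > 0.5
    out = []
    for gm in panels:
        sites = gm.sites.copy()
        r = sites.loc[flip, "ref"].copy()
        sites.loc[flip, "ref"] = sites.loc[flip, "alt"].to_numpy()
        sites.loc[flip, "alt"] = r.to_numpy()
        dos = gm.dosages.copy()
        miss = dos == MISSING
        dos[:, flip] = 2 - dos[:, flip]
        dos[miss] = MISSING
        hap = None
        if gm.haplotypes is not None:
            hap = gm.haplotypes.copy()
            hmiss = hap == MISSING
            hap[:, flip, :] = 1 - hap[:, flip, :]
            hap[hmiss] = MISSING
        out.append(GenotypeMatrix(list(gm.samples), sites, dos, hap))
    return out


def mask_dh_heterozygotes(gm: GenotypeMatrix) -> tuple[GenotypeMatrix, int]:
    """Set residual heterozygous calls in a DH panel to missing.

    DH lines are homozygous by construction, so heterozygous calls are
    genotyping artifacts.  Returns the masked matrix and the cell count.
    """
    het = gm.dosages == 1
    dos = gm.dosages.copy()
    dos[het] = MISSING
    hap = None
    if gm.haplotypes is not None:
        hap = gm.haplotypes.copy()
        hap[het] = MISSING
    return GenotypeMatrix(list(gm.samples), gm.sites.copy(), dos, hap), int(het.sum())


def filter_monomorphic(panels: list[GenotypeMatrix]) -> list[GenotypeMatrix]:
    """Drop sites where only one allele is observed across all panels."""
    alt = np.zeros(panels[0].n_sites)
    tot = np.zeros(panels[0].n_sites)
    for gm in panels:
        miss = gm.missing_mask()
        alt += np.where(miss, 0, gm.dosages).sum(axis=0)
        tot += 2 * (~miss).sum(axis=0)
    mono = (tot > 0) & ((alt == 0) | (alt == tot))
    keep = np.flatnonzero(~mono)
    return [gm.take_sites(keep) for gm in panels]


def hwe_exact_midp(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test with the mid-p convention.

    Conditions on the observed allele counts and ranks heterozygote-count
    configurations by their conditional probability; mid-p is the summed
    probability of configurations strictly more extreme (less probable)
    than the observed one, plus half the probability of configurations
    exactly as probable (the observed configuration included).
    """
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotyped individuals")
    n_a = n_Aa + 2 * n_aa  # minor-allele labelling is irrelevant by symmetry
    hets = np.arange(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    # conditional log-probability of each compatible heterozygote count
    homa = (n_a - hets) // 2
    homA = n - hets - homa
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(homA + 1)
        - gammaln(hets + 1)
        - gammaln(homa + 1)
    )
    logp -= np.logaddexp.reduce(logp)
    p = np.exp(logp)
    p_obs = p[hets == n_Aa]
    if p_obs.size != 1:
        raise ValueError(f"heterozygote count {n_Aa} incompatible with allele count {n_a}")
    p_obs = p_obs[0]
    tol = 1e-12 * max(p_obs, 1.0)
    more_extreme = p < p_obs - tol
    equal = np.abs(p - p_obs) <= tol
    return float(p[more_extreme].sum() + 0.5 * p[equal].sum())


def _hwe_midp_per_site(gm: GenotypeMatrix) -> np.ndarray:
    """Vector of mid-p values per site; NaN where no genotyped individual."""
    out = np.full(gm.n_sites, np.nan)
    d = gm.dosages
    for j in range(gm.n_sites):
        col = d[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            continue
        out[j] = hwe_exact_midp(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
    return out


def filter_hwe(
    lr_panels: dict[str, GenotypeMatrix], alpha: float = 0.05
) -> np.ndarray:
    """Boolean removal mask: mid-p < alpha in every LR accession with data.

    A site is removed only when it violates Hardy-Weinberg equilibrium in
    *all* landrace accessions where at least one individual is genotyped;
    accessions with no data at the site abstain.
    """
    panels = list(lr_panels.values())
    n_sites = panels[0].n_sites
    remove = np.zeros(n_sites, dtype=bool)
    midp = np.stack([_hwe_midp_per_site(gm) for gm in panels])
    informative = ~np.isnan(midp)
    violated = informative & (midp < alpha)
    any_info = informative.any(axis=0)
    all_violate = np.where(informative, violated, True).all(axis=0)
    remove = any_info & all_violate
    return remove


def apply_exclusion_list(gm: GenotypeMatrix, excluded: "pd.DataFrame | set[str]") -> GenotypeMatrix:
    """Drop sites named on an external exclusion list.

    Array-specific quality criteria (off-target variants, call-rate flags,
    insertion-type probes) are not reproducible from genotypes alone, so
    they enter as a site list — either a set of ids or a table with a
    ``site_id`` column (an optional ``reason`` column is ignored here).
    """
    if isinstance(excluded, pd.DataFrame):
        excluded = set(excluded["site_id"])
    keep = np.flatnonzero(~np.isin(gm.site_ids, list(excluded)))
    return gm.take_sites(keep)


def filter_missingness(gm: GenotypeMatrix, max_missing_fraction: float = 0.99) -> GenotypeMatrix:
    """Drop sites whose missing-genotype fraction exceeds the threshold."""
    frac = gm.missing_mask().mean(axis=0)
    return gm.take_sites(np.flatnonzero(frac <= max_missing_fraction))


@dataclass
class PanelIntersection:
    """Outcome of matching two panels on physical position."""

    a: GenotypeMatrix
    b: GenotypeMatrix
    index_a: np.ndarray
    index_b: np.ndarray
    flipped_b: np.ndarray          # True where b was recoded ref<->alt to match a
    dropped: list[tuple[str, int]] = field(default_factory=list)


def intersect_panels(a: GenotypeMatrix, b: GenotypeMatrix) -> PanelIntersection:
    """Match two panels on (chrom, pos), allowing a ref/alt swap in ``b``.

    Positions present in both panels with identical allele pairs are kept;
    swapped pairs ((A,G) vs (G,A)) are kept with ``b`` recoded; incompatible
    pairs are dropped with a warning, not an error.
    """
    key_a = {(c, p): i for i, (c, p) in enumerate(zip(a.sites["chrom"], a.sites["pos"]))}
    idx_a, idx_b, flips, dropped = [], [], [], []
    for jb, (c, p, r, alt) in enumerate(
        zip(b.sites["chrom"], b.sites["pos"], b.sites["ref"], b.sites["alt"])
    ):
        ja = key_a.get((c, p))
        if ja is None:
            continue
        ra, aa = a.sites["ref"].iat[ja], a.sites["alt"].iat[ja]
        if (r, alt) == (ra, aa):
            idx_a.append(ja); idx_b.append(jb); flips.append(False)
        elif (alt, r) == (ra, aa):
            idx_a.append(ja); idx_b.append(jb); flips.append(True)
        else:
            dropped.append((c, int(p)))
            warnings.warn(
                f"incompatible alleles at {c}:{p} ({ra}/{aa} vs {r}/{alt}); site dropped"
            )
    idx_a = np.array(idx_a, dtype=int)
    idx_b = np.array(idx_b, dtype=int)
    flips = np.array(flips, dtype=bool)
    a_sub = a.take_sites(idx_a)
    b_sub = b.take_sites(idx_b)
    if flips.any():
        sites = b_sub.sites.copy()
        r = sites.loc[flips, "ref"].copy()
        sites.loc[flips, "ref"] = sites.loc[flips, "alt"].to_numpy()
        sites.loc[flips, "alt"] = r.to_numpy()
        dos = b_sub.dosages
        miss = dos == MISSING
        dos[:, flips] = 2 - dos[:, flips]
        dos[miss] = MISSING
        if b_sub.haplotypes is not None:
            hmiss = b_sub.haplotypes == MISSING
            b_sub.haplotypes[:, flips, :] = 1 - b_sub.haplotypes[:, flips, :]
            b_sub.haplotypes[hmiss] = MISSING
        b_sub = GenotypeMatrix(b_sub.samples, sites, dos, b_sub.haplotypes)
    # align b's site ids to a's so downstream joins work on one id space
    b_sub.sites["site_id"] = a_sub.sites["site_id"].to_numpy()
    return PanelIntersection(a_sub, b_sub, idx_a, idx_b, flips, dropped)


def imputation_error_rate(
    truth: GenotypeMatrix, imputed: GenotypeMatrix, masked_sites: list[str]
) -> ImputationQC:
    """Per-site imputation error E = 1 - z/(k - m) over masked sites.

    ``z`` counts imputed genotypes matching the withheld truth, ``k`` is the
    number of individuals and ``m`` the missing genotypes in the truth at
    the site.  Sites with k == m carry E = NaN and are excluded from the
    mean.
    """
    if truth.samples != imputed.samples:
        raise ValueError("truth and imputed panels must share samples")
    pos_t = {s: j for j, s in enumerate(truth.site_ids)}
    pos_i = {s: j for j, s in enumerate(imputed.site_ids)}
    rows = []
    for sid in masked_sites:
        if sid not in pos_t or sid not in pos_i:
            raise KeyError(f"masked site {sid} absent from a panel")
        t = truth.dosages[:, pos_t[sid]]
        m = imputed.dosages[:, pos_i[sid]]
        k = t.size
        miss = int((t == MISSING).sum())
        z = int(((t == m) & (t != MISSING)).sum())
        e = np.nan if k == miss else 1.0 - z / (k - miss)
        rows.append((sid, z, k, miss, e))
    per_site = pd.DataFrame(rows, columns=["site_id", "z", "k", "m", "E"])
    return ImputationQC(per_site, float(per_site["E"].mean(skipna=True)))


@dataclass
class SiteCounts:
    """Sufficient statistics for one site: allele and chromosome counts."""

    site_id: str
    l: int
    n_L: int
    d: int
    n_D: int

    def __post_init__(self) -> None:
        if not (0 <= self.l <= self.n_L and 0 <= self.d <= self.n_D):
            raise ValueError(
                f"invalid counts for {self.site_id}: "
                f"l={self.l}/{self.n_L}, d={self.d}/{self.n_D}"
            )
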