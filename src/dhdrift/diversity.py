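"""Per-site diversity statistics and the joint site frequency spectrum."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from dhdrift.genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


def site_pi(c: int | np.ndarray, n: int | np.ndarray) -> float | np.ndarray:
    """Per-site nucleotide diversity, the unbiased pairwise estimator.

    pi = 2 c (n - c) / (n (n - 1)) for ``c`` alternative alleles among
    ``n`` sampled chromosomes: the probability that two chromosomes drawn
    without replacement differ at the site.
    """
    c = np.asarray(c, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 2):
        raise ValueError("site_pi requires n >= 2 chromosomes")
    if np.any((c < 0) | (c > n)):
        raise ValueError("allele count must satisfy 0 <= c <= n")
    pi = 2.0 * c * (n - c) / (n * (n - 1.0))
    return float(pi) if pi.ndim == 0 else pi


@dataclass
class PairDiversity:
    """LR-vs-DH per-site diversity comparison for one accession pair."""

    sites: pd.DataFrame        # site_id, n_lr, c_lr, pi_lr, n_dh, c_dh, pi_dh
    mean_pi_lr: float
    mean_pi_dh: float
    p_value: float             # two-sided unpaired Mann-Whitney on the pi vectors


def _counts(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    miss = gm.missing_mask()
    c = np.where(miss, 0, gm.dosages).sum(axis=0)
    n = 2 * (~miss).sum(axis=0)
    return c, n


def compare_pair_diversity(lr: GenotypeMatrix, dh: GenotypeMatrix) -> PairDiversity:
    """Compare per-site pi between an LR accession and its DH library.

    Sites monomorphic across the pooled pair are removed first; the two
    resulting pi vectors (one per population, same site list) are compared
    with a two-sided unpaired Mann-Whitney-Wilcoxon test.
    """
    if not np.array_equal(lr.site_ids, dh.site_ids):
        raise ValueError("panels must share a site list")
    c_l, n_l = _counts(lr)
    c_d, n_d = _counts(dh)
    pooled_c = c_l + c_d
    pooled_n = n_l + n_d
    poly = (pooled_n > 0) & (pooled_c > 0) & (pooled_c < pooled_n) & (n_l >= 2) & (n_d >= 2)
    if poly.sum() < 2:
        raise ValueError("fewer than 2 polymorphic sites in the pair")
    pi_l = site_pi(c_l[poly], n_l[poly])
    pi_d = site_pi(c_d[poly], n_d[poly])
    if np.array_equal(pi_l, pi_d):
        p = 1.0  # identical vectors carry no rank signal
    else:
        method = "exact" if (len(pi_l) + len(pi_d) <= 20) else "asymptotic"
        p = float(mannwhitneyu(pi_l, pi_d, alternative="two-sided", method=method).pvalue)
    sites = pd.DataFrame(
        {
            "site_id": lr.site_ids[poly],
            "n_lr": n_l[poly],
            "c_lr": c_l[poly],
            "pi_lr": pi_l,
            "n_dh": n_d[poly],
            "c_dh": c_d[poly],
            "pi_dh": pi_d,
        }
    )
    return PairDiversity(sites, float(pi_l.mean()), float(pi_d.mean()), p)


@dataclass
class JointSFS:
    """2-D histogram of (LR frequency, DH frequency) over sites."""

    counts: np.ndarray         # (n_bins, n_bins) site counts
    bin_edges: np.ndarray      # shared edges on [0, 1]
    n_sites: int
    n_skipped: int

    def lr_marginal(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def dh_marginal(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (i, j, int(self.counts[i, j]))
            for i in range(self.counts.shape[0])
            for j in range(self.counts.shape[1])
        ]
        return pd.DataFrame(rows, columns=["lr_bin", "dh_bin", "count"])


def joint_sfs(counts: pd.DataFrame, n_bins: int = 25) -> JointSFS:
    """Bin sites by (l/n_L, d/n_D); bins half-open except the last.

    ``counts`` is the site-counts table with columns l, n_L, d, n_D.
    Sites with zero genotyped chromosomes in either panel are skipped.
    """
    usable = (counts["n_L"] > 0) & (counts["n_D"] > 0)
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.info("joint_sfs: skipped %d sites with no genotyped chromosomes", n_skipped)
    sub = counts[usable]
    f_lr = sub["l"].to_numpy() / sub["n_L"].to_numpy()
    f_dh = sub["d"].to_numpy() / sub["n_D"].to_numpy()
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    hist, _, _ = np.histogram2d(f_lr, f_dh, bins=[edges, edges])
    return JointSFS(hist.astype(int), edges, int(usable.sum()), n_skipped)


def genotype_frequencies(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-site genotype frequencies over non-missing diploid calls.

    Returns columns ``freq_hom_ref, freq_het, freq_hom_alt`` summing to 1
    per site; all-missing sites carry NaN (flagged undefined).
    """
    d = gm.dosages
    valid = d != MISSING
    n = valid.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f0 = ((d == 0).sum(axis=0)) / n
        f1 = ((d == 1).sum(axis=0)) / n
        f2 = ((d == 2).sum(axis=0)) / n
    undef = n == 0
    for f in (f0, f1, f2):
        f[undef] = np.nan
    return pd.DataFrame(
        {
            "site_id": gm.site_ids,
            "freq_hom_ref": f0,
            "freq_het": f1,
            "freq_hom_alt": f2,
        }
    )
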