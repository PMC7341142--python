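"""Functional characterization of outlier SNPs.

Two questions about allele-frequency outliers: (i) are they enriched for
heterozygous genotypes in the landrace, as expected if they tag recessive
deleterious variation kept heterozygous by selection, and (ii) do the
genomic windows around them carry different GERP-based genetic load than
frequency- and recombination-matched control SNPs.  Controls are drawn
from LD-pruned non-outliers, matched on allele-frequency bins and
recombination-rate quantiles so neither the frequency spectrum nor the
pericentromeric load gradient confounds the comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from dhdrift.genotype_io import MISSING, GenotypeMatrix
from dhdrift.haplotypes import GeneticMap

logger = logging.getLogger(__name__)


@dataclass
class GerpTrack:
    """Per-chromosome sorted (position, conservation score) arrays."""

    scores: dict[str, tuple[np.ndarray, np.ndarray]]

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "GerpTrack":
        out = {}
        for chrom, grp in table.groupby("chrom", sort=False):
            grp = grp.sort_values("pos")
            pos = grp["pos"].to_numpy(dtype=np.int64)
            if len(np.unique(pos)) != len(pos):
                raise ValueError(f"duplicate GERP positions on {chrom}")
            out[str(chrom)] = (pos, grp["score"].to_numpy(dtype=float))
        return cls(out)

    def score_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Scores at exact positions; NaN where the track has no entry."""
        pos = np.asarray(pos, dtype=np.int64)
        if chrom not in self.scores:
            return np.full(pos.shape, np.nan)
        track_pos, track_scores = self.scores[chrom]
        idx = np.searchsorted(track_pos, pos)
        ok = (idx < len(track_pos)) & (track_pos[np.minimum(idx, len(track_pos) - 1)] == pos)
        out = np.full(pos.shape, np.nan)
        out[ok] = track_scores[idx[ok]]
        return out


def ld_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared dosage correlation over pairwise-complete individuals.

    Returns NaN (undefined, distinct from 0) when fewer than two complete
    pairs remain or either vector has zero variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return float("nan")
    x, y = a[ok], b[ok]
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def prune_ld(
    gm: GenotypeMatrix,
    candidate_ids: set[str] | list[str],
    r2_max: float = 0.2,
    window_snps: int = 50,
    step: int = 5,
) -> set[str]:
    """Greedy sliding-window LD pruning of a candidate SNP set.

    Within each window of ``window_snps`` consecutive candidates (sliding
    by ``step``), one member of every pair with r^2 > ``r2_max`` is removed:
    the SNP with the lower non-missing count, then the later position.
    """
    candidate_ids = set(candidate_ids)
    sid = gm.site_ids
    removed: set[str] = set()
    nonmiss = (~gm.missing_mask()).sum(axis=0)
    for chrom, grp in gm.sites.groupby("chrom", sort=False):
        idx = [j for j in grp.index if sid[j] in candidate_ids]
        for start in range(0, max(len(idx) - 1, 1), step):
            win = idx[start : start + window_snps]
            for ai in range(len(win)):
                ja = win[ai]
                if sid[ja] in removed:
                    continue
                for bi in range(ai + 1, len(win)):
                    jb = win[bi]
                    if sid[jb] in removed:
                        continue
                    r2 = ld_r2(gm.dosages[:, ja], gm.dosages[:, jb])
                    if np.isnan(r2) or r2 <= r2_max:
                        continue
                    # drop the less informative SNP; later position on ties
                    if nonmiss[ja] < nonmiss[jb]:
                        removed.add(sid[ja])
                        break
                    removed.add(sid[jb])
    return candidate_ids - removed


def _bin_index(freq: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.digitize(freq, edges, right=False) - 1
    return np.clip(idx, 0, n_bins - 1)


def frequency_match_sample(
    outlier_freq: pd.Series,
    pool_freq: pd.Series,
    n_bins: int = 10,
    seed: int = 0,
) -> list[str]:
    """Sample frequency-matched controls from a pruned non-outlier pool.

    Both inputs map site id -> allele frequency.  Per frequency bin, as
    many controls as there are outliers are drawn without replacement; a
    short bin yields everything it has, with the deficit logged.
    """
    rng = np.random.default_rng(seed)
    out_bins = _bin_index(outlier_freq.to_numpy(dtype=float), n_bins)
    pool_bins = _bin_index(pool_freq.to_numpy(dtype=float), n_bins)
    pool_ids = pool_freq.index.to_numpy()
    controls: list[str] = []
    for b in range(n_bins):
        need = int((out_bins == b).sum())
        if need == 0:
            continue
        avail = pool_ids[pool_bins == b]
        if len(avail) < need:
            logger.warning(
                "frequency bin %d: pool holds %d < %d outliers (deficit %d)",
                b, len(avail), need, need - len(avail),
            )
            controls.extend(sorted(avail))
        else:
            controls.extend(sorted(rng.choice(avail, size=need, replace=False)))
    return controls


@dataclass
class HetEnrichment:
    """Bootstrap comparison of heterozygote frequencies between SNP groups."""

    mean_het_outliers: float
    mean_het_controls: float
    p_value: float
    n_outliers: int
    n_controls: int


def heterozygosity_enrichment(
    outlier_het: np.ndarray,
    control_het: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> HetEnrichment:
    """Bootstrap test for a difference in mean heterozygote frequency.

    Both groups are resampled with replacement ``n_boot`` times; the
    two-sided p-value is the fraction of resampled mean differences on the
    opposite side of zero from the observed difference, doubled and capped
    at 1.
    """
    a = np.asarray(outlier_het, dtype=float)
    b = np.asarray(control_het, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 SNPs per group")
    obs = a.mean() - b.mean()
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for r in range(n_boot):
        diffs[r] = rng.choice(a, len(a)).mean() - rng.choice(b, len(b)).mean()
    if obs == 0:
        p = 1.0
    else:
        opposite = (diffs <= 0).mean() if obs > 0 else (diffs >= 0).mean()
        p = min(1.0, 2.0 * opposite)
    return HetEnrichment(float(a.mean()), float(b.mean()), float(p), len(a), len(b))


def recombination_rates(
    gmap: GeneticMap,
    sites: pd.DataFrame,
    window_mbp: float = 1.0,
    n_quantiles: int = 5,
) -> pd.DataFrame:
    """Local recombination rate (cM/Mbp) per SNP, with quantile labels.

    The genome is tiled into ``window_mbp`` megabase windows; each tile's
    rate is its cM span divided by its length, each SNP inherits its
    tile's rate, and quantile edges are taken over the per-SNP rates.
    """
    window_bp = int(window_mbp * 1e6)
    rates = np.empty(len(sites))
    for chrom, grp in sites.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(dtype=float)
        tile = (pos // window_bp).astype(int)
        starts = tile * window_bp
        cm_span = np.asarray(gmap.cm_at(str(chrom), starts + window_bp)) - np.asarray(
            gmap.cm_at(str(chrom), starts)
        )
        rates[grp.index.to_numpy()] = cm_span / window_mbp
    out = sites[["site_id"]].copy()
    out["recomb_rate"] = rates
    if np.unique(rates).size == 1:
        out["recomb_quantile"] = 0
    else:
        ranks = pd.Series(rates).rank(method="first")
        out["recomb_quantile"] = pd.qcut(ranks, n_quantiles, labels=False, duplicates="drop")
    return out


def stratified_control_sample(
    outliers: pd.DataFrame,
    pool: pd.DataFrame,
    seed: int = 0,
    freq_col: str = "p_anc_hat",
    quantile_col: str = "recomb_quantile",
    freq_bin_width: float = 0.1,
) -> list[str]:
    """Controls matched on (ancestral-frequency bin x recombination quantile).

    Both frames need columns ``site_id``, ``freq_col`` and ``quantile_col``.
    Per cell, controls are drawn without replacement to the outlier count;
    deficits are logged, not fatal.
    """
    rng = np.random.default_rng(seed)
    n_bins = int(round(1.0 / freq_bin_width))

    def cells(df: pd.DataFrame) -> pd.Series:
        fb = _bin_index(df[freq_col].to_numpy(dtype=float), n_bins)
        return pd.Series(list(zip(fb, df[quantile_col])), index=df.index)

    out_cells = cells(outliers)
    pool_cells = cells(pool)
    controls: list[str] = []
    for cell, members in out_cells.groupby(out_cells):
        need = len(members)
        avail = pool.loc[pool_cells[pool_cells == cell].index, "site_id"].to_numpy()
        if len(avail) < need:
            logger.warning(
                "stratification cell %s: pool holds %d < %d outliers", cell, len(avail), need
            )
            controls.extend(sorted(avail))
        else:
            controls.extend(sorted(rng.choice(avail, size=need, replace=False)))
    return controls


@dataclass
class WindowLoad:
    """GERP-weighted genetic load in a 1 cM window around one focal SNP."""

    site_id: str
    model: str
    per_individual: np.ndarray
    mean_load: float
    n_contributing_sites: int


def gerp_window_load(
    focal_site_id: str,
    gm: GenotypeMatrix,
    gerp: GerpTrack,
    gmap: GeneticMap,
    model: str = "additive",
    window_cm: float = 1.0,
) -> WindowLoad:
    """Sum of positive GERP scores weighted by genotype around a focal SNP.

    The window spans ``window_cm`` centimorgans centered on the focal SNP.
    Contributing sites are genotyped SNPs in the window whose GERP score is
    positive.  Per individual, load = sum(score * g) with g = dosage/2
    under the additive model and g = 1 only for homozygous alternative
    genotypes under the recessive model; missing genotypes contribute 0 and
    are excluded from that site's denominator when averaging.
    """
    if model not in ("additive", "recessive"):
        raise ValueError("model must be 'additive' or 'recessive'")
    where = np.flatnonzero(gm.site_ids == focal_site_id)
    if where.size != 1:
        raise KeyError(f"focal site {focal_site_id!r} not found exactly once")
    j0 = int(where[0])
    chrom = gm.sites["chrom"].iat[j0]
    cm0 = float(np.asarray(gmap.cm_at(chrom, float(gm.sites["pos"].iat[j0]))))
    on_chrom = gm.sites.index[gm.sites["chrom"] == chrom].to_numpy()
    cms = np.asarray(gmap.cm_at(chrom, gm.sites.loc[on_chrom, "pos"].to_numpy(dtype=float)))
    half = window_cm / 2.0
    in_window = on_chrom[(cms >= cm0 - half) & (cms <= cm0 + half)]
    scores = gerp.score_at(chrom, gm.sites.loc[in_window, "pos"].to_numpy())
    keep = in_window[np.nan_to_num(scores, nan=0.0) > 0]
    scores = scores[np.nan_to_num(scores, nan=0.0) > 0]
    if keep.size == 0:
        logger.debug("no GERP-positive site in window around %s", focal_site_id)
        return WindowLoad(focal_site_id, model, np.zeros(gm.n_samples), 0.0, 0)
    d = gm.dosages[:, keep].astype(float)
    miss = d == MISSING
    g = d / 2.0 if model == "additive" else (d == 2).astype(float)
    g[miss] = 0.0
    per_ind = g @ scores
    # site-wise mean over non-missing individuals, then summed with scores
    n_ok = (~miss).sum(axis=0)
    with np.errstate(invalid="ignore"):
        site_means = np.where(n_ok > 0, g.sum(axis=0) / np.maximum(n_ok, 1), 0.0)
    mean_load = float(site_means @ scores)
    return WindowLoad(focal_site_id, model, per_ind, mean_load, int(keep.size))


@dataclass
class LoadComparison:
    mean_outliers: float
    mean_controls: float
    p_value: float


def compare_load(outlier_loads: np.ndarray, control_loads: np.ndarray) -> LoadComparison:
    """Welch two-sided t-test on mean window load between SNP groups."""
    a = np.asarray(outlier_loads, dtype=float)
    b = np.asarray(control_loads, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 loads per group")
    if a.var() == 0 and b.var() == 0:
        p = 1.0 if a.mean() == b.mean() else float("nan")
    else:
        p = float(ttest_ind(a, b, equal_var=False).pvalue)
    return LoadComparison(float(a.mean()), float(b.mean()), p)
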