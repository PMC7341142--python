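"""Allele-frequency outlier tests for paired landrace / DH panels.

Two statistics distinguish drift from selection when the genotyped
landrace individuals are *not* the parents of the DH lines, so that the
two panels are independent samples from a shared ancestral population:

* the **aSFS test**: a grid maximum-likelihood estimate of the ancestral
  frequency from three chained binomial sampling events (LR genotyping,
  survival of a DH pool of ``n_H`` lines, DH genotyping), followed by a
  central confidence interval on the DH allele count; observed counts
  outside the interval are outliers;

* the **joint probability test**: the exact probability of the observed
  (LR, DH) allele counts under neutral sampling with a Beta(1/2, 1/2)
  prior on the unknown ancestral frequency, integrated out analytically;
  sites in the top tail of -log10(P) within an accession are outliers.

All binomial and beta terms are evaluated in log space via log-gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln, logsumexp, xlogy
from scipy.stats import binom

from dhdrift.genotype_io import SiteCounts


def _default_grid() -> np.ndarray:
    return np.linspace(0.01, 0.99, 100)


@dataclass
class ModelConfig:
    """Parameters of the three-stage sampling model.

    ``n_H`` is the size of the surviving DH pool between induction and
    genotyping (unobserved; 100 by default).  The grid holds candidate
    ancestral frequencies for the ML search.  ``ml_mode`` selects whether
    the surface is maximized jointly over (frequency, pool count) or the
    pool count is marginalized first.
    """

    n_H: int = 100
    grid: np.ndarray = field(default_factory=_default_grid)
    prior_alpha: float = 0.5
    prior_beta: float = 0.5
    interval_mass: float = 0.95
    outlier_fraction: float = 0.05
    ml_mode: str = "joint"  # "joint" | "marginal"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(self.grid) <= 0) or self.grid[0] <= 0 or self.grid[-1] >= 1:
            raise ValueError("grid must be strictly increasing within (0, 1)")
        if not (self.prior_alpha > 0 and self.prior_beta > 0):
            raise ValueError("prior parameters must be positive")
        if not (0 < self.interval_mass < 1 and 0 < self.outlier_fraction < 1):
            raise ValueError("interval mass and outlier fraction must lie in (0, 1)")
        if self.ml_mode not in ("joint", "marginal"):
            raise ValueError("ml_mode must be 'joint' or 'marginal'")


@dataclass
class LikelihoodSurface:
    """Per-site likelihood over (grid frequency j, surviving-pool count i)."""

    grid: np.ndarray
    log_I: np.ndarray  # (n_grid, n_H + 1)

    @property
    def I(self) -> np.ndarray:
        return np.exp(self.log_I)


@dataclass
class AncestralEstimate:
    """aSFS test output for one site."""

    site_id: str
    p_anc_hat: float
    p_anc: np.ndarray          # probability over DH allele counts s in {0..n_D}
    s_lo: int
    s_hi: int
    classification: str        # above | below | inside


@dataclass
class JointProbResult:
    """Joint probability of the observed (l, d) counts at one site."""

    site_id: str
    P: float
    neg_log10_P: float
    outlier: bool | None = None


# ---------------------------------------------------------------------------
# aSFS machinery


def likelihood_surface(site: SiteCounts, config: ModelConfig) -> LikelihoodSurface:
    """Product of the three binomial sampling likelihoods on the grid.

    Entry (j, i) = P(d | n_D, i/n_H) * P(i | n_H, grid_j) * P(l | n_L, grid_j),
    the likelihood that the ancestral frequency is grid_j and ``i`` of the
    ``n_H`` surviving DH lines carry the alternative allele.
    """
    if site.n_L < 1 or site.n_D < 1:
        raise ValueError("need at least one genotyped chromosome in each panel")
    n_H = config.n_H
    i = np.arange(n_H + 1)
    log_pd = binom.logpmf(site.d, site.n_D, i / n_H)               # (n_H+1,)
    log_ph = binom.logpmf(i[None, :], n_H, config.grid[:, None])   # (grid, n_H+1)
    log_pl = binom.logpmf(site.l, site.n_L, config.grid)           # (grid,)
    return LikelihoodSurface(config.grid, log_pl[:, None] + log_ph + log_pd[None, :])


def ml_ancestral_frequency(surface: LikelihoodSurface, ml_mode: str = "joint") -> float:
    """Grid frequency maximizing the surface (ties -> smaller frequency).

    ``joint`` takes the argmax over (frequency, pool count); ``marginal``
    sums the surface over pool counts first.
    """
    log_I = surface.log_I
    if np.all(np.isneginf(log_I)):
        raise FloatingPointError("likelihood surface underflowed to zero everywhere")
    if ml_mode == "joint":
        j = np.unravel_index(np.argmax(log_I), log_I.shape)[0]
    elif ml_mode == "marginal":
        j = int(np.argmax(logsumexp(log_I, axis=1)))
    else:
        raise ValueError("ml_mode must be 'joint' or 'marginal'")
    return float(surface.grid[j])


def dh_count_distribution(
    p_anc_hat: float, n_D: int, config: ModelConfig
) -> np.ndarray:
    """Distribution of the DH allele count s under the estimated ancestry.

    Mixture of binomials: P(s) = sum_i P(s | n_D, i/n_H) P(i | n_H, p_hat),
    marginalizing the unobserved surviving-pool count.
    """
    if not 0 < p_anc_hat < 1:
        raise ValueError("p_anc_hat must lie in (0, 1)")
    n_H = config.n_H
    i = np.arange(n_H + 1)
    w = binom.pmf(i, n_H, p_anc_hat)
    s = np.arange(n_D + 1)
    M = binom.pmf(s[:, None], n_D, (i / n_H)[None, :])
    return M @ w


def central_interval(p_anc: np.ndarray, mass: float = 0.95) -> tuple[int, int]:
    """Equal-tail central interval on a discrete mass vector.

    ``s_lo`` is the largest s with P(S < s) < (1-mass)/2 and ``s_hi`` the
    smallest s with P(S > s) < (1-mass)/2; discrete overshoot means the
    contained mass is always >= ``mass``.
    """
    p = np.asarray(p_anc, dtype=float)
    tail = (1.0 - mass) / 2.0
    below = np.concatenate([[0.0], np.cumsum(p)[:-1]])      # P(S < s)
    rev = np.cumsum(p[::-1])[::-1]                          # P(S >= s)
    above = np.concatenate([rev[1:], [0.0]])                # P(S > s)
    s_lo = int(np.flatnonzero(below < tail).max())
    s_hi = int(np.flatnonzero(above < tail).min())
    return s_lo, s_hi


def asfs_classify(site: SiteCounts, config: ModelConfig | None = None) -> AncestralEstimate:
    """Run the full aSFS test on one site.

    Estimates the ancestral frequency by grid ML, builds the DH-count
    distribution and its central interval, and classifies the observed DH
    count as above, below or inside the interval.
    """
    config = config or ModelConfig()
    surface = likelihood_surface(site, config)
    p_hat = ml_ancestral_frequency(surface, config.ml_mode)
    p_anc = dh_count_distribution(p_hat, site.n_D, config)
    s_lo, s_hi = central_interval(p_anc, config.interval_mass)
    if site.d < s_lo:
        cls = "below"
    elif site.d > s_hi:
        cls = "above"
    else:
        cls = "inside"
    return AncestralEstimate(site.site_id, p_hat, p_anc, s_lo, s_hi, cls)


def _central_interval_rows(P: np.ndarray, mass: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized equal-tail interval over rows of a mass matrix."""
    tail = (1.0 - mass) / 2.0
    below = np.concatenate([np.zeros((P.shape[0], 1)), np.cumsum(P, axis=1)[:, :-1]], axis=1)
    rev = np.cumsum(P[:, ::-1], axis=1)[:, ::-1]
    above = np.concatenate([rev[:, 1:], np.zeros((P.shape[0], 1))], axis=1)
    s_lo = (below < tail).sum(axis=1) - 1          # last index with below < tail
    s_hi = np.argmax(above < tail, axis=1)         # first index with above < tail
    return s_lo.astype(int), s_hi.astype(int)


def asfs_classify_panel(
    counts: pd.DataFrame, config: ModelConfig | None = None, chunk: int = 256
) -> pd.DataFrame:
    """Vectorized aSFS test over a site-counts table.

    Sites sharing (n_L, n_D) are processed together; the DH-count
    distribution is cached per (grid index, n_D) since the ML estimate can
    only take grid values.  Returns a frame with columns
    ``site_id, l, n_L, d, n_D, p_anc_hat, s_lo, s_hi, asfs_class``.
    """
    config = config or ModelConfig()
    n_H = config.n_H
    grid = config.grid
    i = np.arange(n_H + 1)
    log_ph = binom.logpmf(i[None, :], n_H, grid[:, None])  # (G, n_H+1)
    out = counts[["site_id", "l", "n_L", "d", "n_D"]].copy()
    p_hat_idx = np.empty(len(counts), dtype=int)

    for (n_L, n_D), grp in counts.groupby(["n_L", "n_D"], sort=False):
        if n_L < 1 or n_D < 1:
            raise ValueError("need at least one genotyped chromosome in each panel")
        idx = grp.index.to_numpy()
        l = grp["l"].to_numpy()
        d = grp["d"].to_numpy()
        log_pl = binom.logpmf(l[:, None], n_L, grid[None, :])          # (m, G)
        log_pd = binom.logpmf(d[:, None], n_D, (i / n_H)[None, :])     # (m, n_H+1)
        for start in range(0, len(idx), chunk):
            sl = slice(start, start + chunk)
            surf = (
                log_pl[sl][:, :, None] + log_ph[None, :, :] + log_pd[sl][:, None, :]
            )  # (chunk, G, n_H+1)
            if config.ml_mode == "joint":
                flat = surf.reshape(surf.shape[0], -1)
                j = np.argmax(flat, axis=1) // (n_H + 1)
            else:
                j = np.argmax(logsumexp(surf, axis=2), axis=1)
            p_hat_idx[idx[sl]] = j

    out["p_anc_hat"] = grid[p_hat_idx]
    s_lo = np.empty(len(counts), dtype=int)
    s_hi = np.empty(len(counts), dtype=int)
    for n_D, grp in counts.groupby("n_D", sort=False):
        idx = grp.index.to_numpy()
        W = binom.pmf(i[None, :], n_H, grid[:, None])                  # (G, n_H+1)
        s = np.arange(int(n_D) + 1)
        M = binom.pmf(s[:, None], int(n_D), (i / n_H)[None, :])        # (n_D+1, n_H+1)
        P_by_grid = W @ M.T                                            # (G, n_D+1)
        lo_g, hi_g = _central_interval_rows(P_by_grid, config.interval_mass)
        s_lo[idx] = lo_g[p_hat_idx[idx]]
        s_hi[idx] = hi_g[p_hat_idx[idx]]
    out["s_lo"] = s_lo
    out["s_hi"] = s_hi
    d = out["d"].to_numpy()
    out["asfs_class"] = np.where(
        d < s_lo, "below", np.where(d > s_hi, "above", "inside")
    )
    return out


def dh_count_intervals_at(
    p_true: np.ndarray, n_D: int, config: ModelConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Central intervals on the DH count built at given ancestral frequencies.

    Used for coverage checks: intervals are constructed at the *true*
    (known) ancestral frequency rather than the ML estimate.
    """
    config = config or ModelConfig()
    n_H = config.n_H
    i = np.arange(n_H + 1)
    W = binom.pmf(i[None, :], n_H, np.asarray(p_true)[:, None])   # (m, n_H+1)
    s = np.arange(n_D + 1)
    M = binom.pmf(s[:, None], n_D, (i / n_H)[None, :])            # (n_D+1, n_H+1)
    P = W @ M.T                                                   # (m, n_D+1)
    return _central_interval_rows(P, config.interval_mass)


# ---------------------------------------------------------------------------
# Joint probability test


def _log_joint_probability(
    l: np.ndarray, d: np.ndarray, n_L: int, n_D: int, config: ModelConfig
) -> np.ndarray:
    """log P of observing (l, d) under neutral three-stage sampling.

    The unknown ancestral frequency x ~ Beta(a, b) is integrated out
    analytically: the LR sample and the DH pool share x, giving a
    beta-binomial term over k = i + l successes in n = n_L + n_H draws,
    while the genotyped DH counts follow a binomial at the pool frequency
    i/n_H.  Evaluated entirely in log space; 0^0 = 1 at the i-boundaries.
    """
    a, b = config.prior_alpha, config.prior_beta
    n_H = config.n_H
    i = np.arange(n_H + 1)
    l = np.atleast_1d(np.asarray(l))
    d = np.atleast_1d(np.asarray(d))
    k = i[None, :] + l[:, None]                       # (m, n_H+1)
    n = n_L + n_H
    log_choose_i = gammaln(n_H + 1) - gammaln(i + 1) - gammaln(n_H - i + 1)
    terms = (
        log_choose_i[None, :]
        + betaln(k + a, n - k + b)
        - betaln(a, b)
        + xlogy(d[:, None], i[None, :] / n_H)
        + xlogy(n_D - d[:, None], 1.0 - i[None, :] / n_H)
    )
    log_sum = logsumexp(terms, axis=1)
    log_binoms = (
        gammaln(n_L + 1) - gammaln(l + 1) - gammaln(n_L - l + 1)
        + gammaln(n_D + 1) - gammaln(d + 1) - gammaln(n_D - d + 1)
    )
    return log_binoms + log_sum


def joint_probability(site: SiteCounts, config: ModelConfig | None = None) -> JointProbResult:
    """Joint probability of one site's observed (l, d) counts."""
    config = config or ModelConfig()
    logP = float(_log_joint_probability(site.l, site.d, site.n_L, site.n_D, config)[0])
    P = float(np.exp(logP))
    return JointProbResult(site.site_id, P, -logP / np.log(10.0))


def joint_probability_panel(
    counts: pd.DataFrame, config: ModelConfig | None = None
) -> pd.DataFrame:
    """Vectorized joint probability over a site-counts table.

    Adds columns ``P`` and ``neg_log10_P``; sites sharing (n_L, n_D) are
    batched.
    """
    config = config or ModelConfig()
    out = counts[["site_id", "l", "n_L", "d", "n_D"]].copy()
    logP = np.empty(len(counts))
    for (n_L, n_D), grp in counts.groupby(["n_L", "n_D"], sort=False):
        idx = grp.index.to_numpy()
        logP[idx] = _log_joint_probability(
            grp["l"].to_numpy(), grp["d"].to_numpy(), int(n_L), int(n_D), config
        )
    out["P"] = np.exp(logP)
    out["neg_log10_P"] = -logP / np.log(10.0)
    return out


def flag_joint_outliers(
    neg_log10_P: np.ndarray | pd.Series, fraction: float = 0.05
) -> np.ndarray:
    """Flag sites whose -log10(P) strictly exceeds the top-``fraction`` cut.

    The threshold is the nearest-rank (1 - fraction) empirical quantile
    within the accession; strict inequality means ties never inflate the
    flagged fraction above ``fraction``.
    """
    x = np.asarray(neg_log10_P, dtype=float)
    if x.size < 20:
        raise ValueError("need at least 20 sites to set an empirical threshold")
    srt = np.sort(x)
    rank = int(np.ceil((1.0 - fraction) * x.size))    # nearest-rank quantile
    threshold = srt[rank - 1]
    return x > threshold


def outlier_overlap(outlier_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Count outlier sites shared by exactly 1..A accessions."""
    from collections import Counter

    membership = Counter()
    for sites in outlier_sets.values():
        for sid in sites:
            membership[sid] += 1
    levels = Counter(membership.values())
    A = len(outlier_sets)
    return pd.DataFrame(
        {"sharing_level": np.arange(1, A + 1),
         "count": [levels.get(k, 0) for k in range(1, A + 1)]}
    )


def outlier_fate(site: SiteCounts, is_outlier: bool) -> str:
    """Fate of an outlier allele segregating in LR: lost, fixed or segregating.

    Non-outliers, and outliers not segregating in the LR sample, return
    "NA" (fates are defined relative to alleles present but unfixed in LR).
    """
    if not is_outlier or not (0 < site.l < site.n_L):
        return "NA"
    if site.d == 0:
        return "lost"
    if site.d == site.n_D:
        return "fixed"
    return "segregating"
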