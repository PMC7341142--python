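"""Simulated landrace / doubled-haploid accession pairs with ground truth.

The generator mirrors how paired LR/DH panels arise in practice as three
binomial sampling events from a shared ancestral population: (i) a set of
landrace individuals is genotyped (Hardy-Weinberg diploids at the
ancestral frequency), (ii) a pool of ``n_H`` DH lines is produced from
independently sampled gametes, with optional viability selection of
strength ``s`` against lines carrying the (always homozygous) alternative
allele, and (iii) a subset of surviving lines is genotyped.  Because a
line killed by selection is replaced by a fresh independent induction,
the surviving-line allele law has the closed form p(1-s)/(1-p*s); the
simulator draws from it directly, which is exactly equivalent to
rejection sampling (covered by a unit test against an explicit rejection
oracle).

All randomness flows from a single seed, so identical configurations
produce byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dhdrift.genotype_io import MISSING, GenotypeMatrix, SampleSheet, write_vcf


@dataclass
class SimulationConfig:
    """Study-design knobs for one simulated accession.

    Defaults reflect a typical European landrace conservation panel: a few
    dozen genotyped heterozygous landrace individuals, a DH library of 100
    surviving lines, and a genotyped subset of those lines.
    """

    n_sites: int = 1000
    sfs_model: str = "uniform"          # uniform | beta | neutral (density ~ 1/x)
    sfs_params: tuple[float, float] = (0.05, 0.95)
    n_H: int = 100                      # surviving DH pool size
    n_lr_individuals: int = 23          # genotyped LR diploids (46 chromosomes)
    n_dh_lines: int = 58                # genotyped DH lines drawn from the pool
    selection_s: float = 0.0            # viability cost of the homozygous alt allele
    selected_fraction: float = 0.0      # fraction of sites carrying selection_s
    lr_viability_selection: bool = True # recessive cost also culls LR homozygotes
    # haplotype-window mode
    n_windows: int = 20
    snps_per_window: int = 10
    n_founders: int = 4                 # founder haplotypes per window (K)
    dirichlet_concentration: float = 1.0
    # fixture geometry
    site_spacing_bp: int = 1000
    accession: str = "SIM1"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_sites, self.n_H, self.n_lr_individuals, self.n_dh_lines) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0.0 <= self.selection_s <= 1.0:
            raise ValueError("selection_s must lie in [0, 1]")
        if not 0.0 <= self.selected_fraction <= 1.0:
            raise ValueError("selected_fraction must lie in [0, 1]")
        if self.n_dh_lines > self.n_H:
            raise ValueError("cannot genotype more DH lines than the pool holds")


@dataclass
class SimulatedAccession:
    """Paired LR/DH panels plus the ground truth that produced them."""

    lr: GenotypeMatrix
    dh: GenotypeMatrix
    sheet: SampleSheet
    p_anc: np.ndarray                   # true ancestral frequency per site
    s: np.ndarray                       # true selection coefficient per site
    pool_counts: np.ndarray | None      # alt-allele count among the n_H survivors
    window_truth: pd.DataFrame | None = None  # founder haplotypes/frequencies if windowed


def sample_ancestral_frequencies(config: SimulationConfig) -> np.ndarray:
    """Draw ancestral site frequencies under the configured spectrum model."""
    rng = np.random.default_rng(config.seed)
    a, b = config.sfs_params
    if config.sfs_model == "uniform":
        if a == b:
            return np.full(config.n_sites, a)
        return rng.uniform(a, b, config.n_sites)
    if config.sfs_model == "beta":
        p = rng.beta(a, b, config.n_sites)
        return np.clip(p, 1e-9, 1 - 1e-9)
    if config.sfs_model == "neutral":
        # density proportional to 1/x on (a, b): inverse-CDF sampling
        lo, hi = max(a, 1e-6), b
        u = rng.random(config.n_sites)
        return lo * (hi / lo) ** u
    raise ValueError(f"unknown sfs_model {config.sfs_model!r}")


def _site_table(n_sites: int, spacing: int, chrom: str = "1") -> pd.DataFrame:
    pos = 1 + spacing * np.arange(n_sites)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "T",
            "site_id": [f"s{q:06d}" for q in range(n_sites)],
        }
    )


def surviving_pool_frequency(p: np.ndarray | float, s: np.ndarray | float) -> np.ndarray:
    """Allele frequency among surviving DH lines: p(1-s) / (1 - p*s)."""
    p = np.asarray(p, dtype=float)
    s = np.asarray(s, dtype=float)
    dead = (s >= 1.0) & (p >= 1.0)
    if np.any(dead):
        raise ValueError("s=1 with p_anc=1 leaves no possible survivor")
    return p * (1.0 - s) / (1.0 - p * s)


def simulate_accession(config: SimulationConfig) -> SimulatedAccession:
    """Simulate one LR/DH accession pair under the three-stage scheme.

    Sites are independent.  LR individuals are HWE diploids at the true
    ancestral frequency (phased, both gametes drawn independently); the DH
    pool holds ``n_H`` surviving homozygous lines whose allele law reflects
    viability selection; the genotyped DH panel is a without-replacement
    draw of ``n_dh_lines`` lines from that pool.  In selection mode the
    same recessive cost optionally culls homozygous-alt LR individuals
    (``lr_viability_selection``), so selected sites carry the heterozygote
    excess expected of recessive deleterious alleles in an outbred
    population.
    """
    rng = np.random.default_rng(config.seed)
    p = sample_ancestral_frequencies(config)

    s = np.zeros(config.n_sites)
    n_sel = int(round(config.selected_fraction * config.n_sites))
    if n_sel > 0:
        sel_idx = rng.choice(config.n_sites, size=n_sel, replace=False)
        s[sel_idx] = config.selection_s

    p_surv = surviving_pool_frequency(p, s)  # also rejects s=1 with p_anc=1

    # (i) LR genotyping: two independent gametes per individual
    h0 = (rng.random((config.n_lr_individuals, config.n_sites)) < p).astype(np.int8)
    h1 = (rng.random((config.n_lr_individuals, config.n_sites)) < p).astype(np.int8)
    if config.lr_viability_selection and np.any(s > 0):
        # The recessive allele was deleterious in the standing landrace too:
        # a homozygous-alt individual at a selected site is culled with
        # probability s and redrawn, leaving a heterozygote excess relative
        # to HWE.  Each fresh draw is tested exactly once.
        sel_cols = np.flatnonzero(s > 0)
        pending = np.ones((config.n_lr_individuals, len(sel_cols)), dtype=bool)
        while pending.any():
            hom = pending & (h0[:, sel_cols] == 1) & (h1[:, sel_cols] == 1)
            die = hom & (rng.random(hom.shape) < s[sel_cols][None, :])
            rows, cols = np.nonzero(die)
            h0[rows, sel_cols[cols]] = rng.random(len(rows)) < p[sel_cols[cols]]
            h1[rows, sel_cols[cols]] = rng.random(len(rows)) < p[sel_cols[cols]]
            pending = die
    lr_hap = np.stack([h0, h1], axis=2)
    lr_dos = (h0 + h1).astype(np.int16)

    # (ii) surviving DH pool: iid lines at the post-selection frequency
    pool = (rng.random((config.n_H, config.n_sites)) < p_surv).astype(np.int8)
    pool_counts = pool.sum(axis=0)

    # (iii) genotyped DH subsample: lines drawn without replacement
    chosen = rng.choice(config.n_H, size=config.n_dh_lines, replace=False)
    dh_dos = (2 * pool[chosen]).astype(np.int16)
    dh_hap = np.repeat(pool[chosen, :, None], 2, axis=2)

    sites = _site_table(config.n_sites, config.site_spacing_bp)
    lr_samples = [f"{config.accession}_LR_{i:03d}" for i in range(config.n_lr_individuals)]
    dh_samples = [f"{config.accession}_DH_{i:03d}" for i in range(config.n_dh_lines)]
    lr = GenotypeMatrix(lr_samples, sites, lr_dos, lr_hap)
    dh = GenotypeMatrix(dh_samples, sites.copy(), dh_dos, dh_hap)
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample": lr_samples + dh_samples,
                "accession": config.accession,
                "population": ["LR"] * len(lr_samples) + ["DH"] * len(dh_samples),
            }
        )
    )
    return SimulatedAccession(lr, dh, sheet, p, s, pool_counts)


def simulate_window_haplotypes(config: SimulationConfig) -> SimulatedAccession:
    """Simulate multi-SNP windows from K founder haplotypes per window.

    Each window carries ``snps_per_window`` SNPs spanning < 50 kb, with
    > 50 kb gaps between windows so physical tiling keeps them apart.
    Founder haplotypes are random binary strings with Dirichlet-distributed
    frequencies; each LR individual draws two founders, each DH line one.
    """
    if config.n_founders < 1:
        raise ValueError("need at least one founder haplotype")
    rng = np.random.default_rng(config.seed)
    W, L, K = config.n_windows, config.snps_per_window, config.n_founders
    n_sites = W * L

    span = 45_000
    step = span // max(L - 1, 1)
    pos = np.concatenate(
        [1 + w * 100_001 + step * np.arange(L) for w in range(W)]
    )
    sites = pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos,
            "ref": "A",
            "alt": "T",
            "site_id": [f"w{q // L:03d}_s{q % L:02d}" for q in range(n_sites)],
        }
    )

    founders = np.empty((W, K, L), dtype=np.int8)
    freqs = np.empty((W, K))
    lr_hap = np.empty((config.n_lr_individuals, n_sites, 2), dtype=np.int8)
    dh_allele = np.empty((config.n_dh_lines, n_sites), dtype=np.int8)
    truth_rows = []
    for w in range(W):
        founders[w] = rng.integers(0, 2, size=(K, L))
        freqs[w] = rng.dirichlet(np.full(K, config.dirichlet_concentration))
        sl = slice(w * L, (w + 1) * L)
        pick0 = rng.choice(K, size=config.n_lr_individuals, p=freqs[w])
        pick1 = rng.choice(K, size=config.n_lr_individuals, p=freqs[w])
        lr_hap[:, sl, 0] = founders[w][pick0]
        lr_hap[:, sl, 1] = founders[w][pick1]
        pick_dh = rng.choice(K, size=config.n_dh_lines, p=freqs[w])
        dh_allele[:, sl] = founders[w][pick_dh]
        for k in range(K):
            truth_rows.append(
                (w, k, "".join(map(str, founders[w, k])), float(freqs[w, k]))
            )

    lr_dos = lr_hap.sum(axis=2).astype(np.int16)
    dh_dos = (2 * dh_allele).astype(np.int16)
    dh_hap = np.repeat(dh_allele[:, :, None], 2, axis=2)

    lr_samples = [f"{config.accession}_LR_{i:03d}" for i in range(config.n_lr_individuals)]
    dh_samples = [f"{config.accession}_DH_{i:03d}" for i in range(config.n_dh_lines)]
    lr = GenotypeMatrix(lr_samples, sites, lr_dos, lr_hap)
    dh = GenotypeMatrix(dh_samples, sites.copy(), dh_dos, dh_hap)
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample": lr_samples + dh_samples,
                "accession": config.accession,
                "population": ["LR"] * len(lr_samples) + ["DH"] * len(dh_samples),
            }
        )
    )
    p_true = np.concatenate(
        [freqs[w] @ founders[w] for w in range(W)]
    )  # marginal per-SNP frequency of allele 1
    window_truth = pd.DataFrame(
        truth_rows, columns=["window", "founder", "haplotype", "frequency"]
    )
    return SimulatedAccession(
        lr, dh, sheet, p_true, np.zeros(n_sites), None, window_truth
    )


def write_fixture_set(
    sim: SimulatedAccession,
    out_dir: str | Path,
    *,
    cm_per_mbp: float = 1.0,
    gerp_positive_fraction: float = 0.5,
    gerp_scale: float = 2.0,
    gerp_seed: int = 7,
) -> dict[str, Path]:
    """Write a complete plain-text fixture: VCFs, sheet, map, GERP, truth.

    The genetic map is linear (``cm_per_mbp``); GERP scores at genotyped
    positions are a mixture of a point mass at 0 (non-constrained) and an
    exponential tail of positive scores (constrained), since only the sign
    and magnitude of positive scores enter load computations.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "lr_vcf": out / "lr.vcf",
        "dh_vcf": out / "dh.vcf",
        "samples": out / "samples.tsv",
        "map": out / "map.tsv",
        "gerp": out / "gerp.tsv",
        "truth": out / "truth.tsv",
    }
    write_vcf(sim.lr, paths["lr_vcf"])
    write_vcf(sim.dh, paths["dh_vcf"])
    sim.sheet.table.to_csv(paths["samples"], sep="\t", index=False)

    sites = sim.lr.sites
    anchors = []
    for chrom, grp in sites.groupby("chrom", sort=False):
        lo, hi = int(grp["pos"].min()), int(grp["pos"].max())
        hi = max(hi, lo + 1)
        anchors.append((chrom, lo, lo * 1e-6 * cm_per_mbp))
        anchors.append((chrom, hi + 1, (hi + 1) * 1e-6 * cm_per_mbp))
    pd.DataFrame(anchors, columns=["chrom", "pos", "cM"]).to_csv(
        paths["map"], sep="\t", index=False
    )

    rng = np.random.default_rng(gerp_seed)
    positive = rng.random(len(sites)) < gerp_positive_fraction
    scores = np.where(positive, rng.exponential(gerp_scale, len(sites)), 0.0)
    pd.DataFrame(
        {"chrom": sites["chrom"], "pos": sites["pos"], "score": np.round(scores, 6)}
    ).to_csv(paths["gerp"], sep="\t", index=False)

    pd.DataFrame(
        {"site_id": sites["site_id"], "p_anc": sim.p_anc, "s": sim.s}
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths
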