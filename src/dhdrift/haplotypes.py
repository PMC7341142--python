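"""Haplotype windows: diversity and the fate of major LR haplotypes.

SNPs are concatenated into non-overlapping windows (physical 50 kb tiles
or genetic 0.2 cM tiles), haplotype strings are counted per population
(each phased LR individual contributes two strings, each homozygous DH
line one), and Nei's sample-size-corrected haplotype diversity
H = N/(N-1) (1 - sum x_i^2) is computed per window.  The most abundant
LR haplotype is then classified by its fate in the DH population: lost,
fixed, or still segregating.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dhdrift.genotype_io import MISSING, GenotypeMatrix


@dataclass
class GeneticMap:
    """Piecewise-linear bp -> cM map with constant extrapolation at the ends."""

    anchors: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (pos, cM)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "GeneticMap":
        """Build from a table with columns ``chrom, pos, cM``."""
        anchors = {}
        for chrom, grp in table.groupby("chrom", sort=False):
            grp = grp.sort_values("pos")
            pos = grp["pos"].to_numpy(dtype=float)
            cm = grp["cM"].to_numpy(dtype=float)
            if len(pos) < 2:
                raise ValueError(f"map for {chrom} needs >= 2 anchors")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cM not monotone on {chrom}")
            anchors[str(chrom)] = (pos, cm)
        return cls(anchors)

    def cm_at(self, chrom: str, pos: np.ndarray | float) -> np.ndarray | float:
        if chrom not in self.anchors:
            raise KeyError(f"chromosome {chrom!r} absent from genetic map")
        xp, fp = self.anchors[chrom]
        return np.interp(pos, xp, fp)


@dataclass
class Window:
    """One tile of the genome in physical or genetic coordinates."""

    chrom: str
    start: float
    end: float
    unit: str                   # "bp" or "cM"
    site_index: np.ndarray      # positional indices into the site table

    @property
    def n_snps(self) -> int:
        return len(self.site_index)


@dataclass
class HaplotypeWindow:
    """Haplotype frequency tables and diversity for one window."""

    window: Window
    table: pd.DataFrame         # haplotype, count_lr, count_dh
    n_lr: int                   # retained LR haplotype strings
    n_dh: int
    h_lr: float | None
    h_dh: float | None
    major_haplotype: str | None
    fate: str                   # lost | fixed | segregating | NA


def make_physical_windows(sites: pd.DataFrame, window_size: int = 50_000) -> list[Window]:
    """Half-open physical tiles [k*w, (k+1)*w) anchored at coordinate 0."""
    windows = []
    for chrom, grp in sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        tile = grp["pos"].to_numpy() // window_size
        for t in np.unique(tile):
            windows.append(
                Window(str(chrom), float(t * window_size), float((t + 1) * window_size),
                       "bp", idx[tile == t])
            )
    return windows


def make_genetic_windows(
    sites: pd.DataFrame, gmap: GeneticMap, window_cm: float = 0.2
) -> list[Window]:
    """Tiles of ``window_cm`` centimorgans; SNP positions are interpolated."""
    windows = []
    for chrom, grp in sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        cm = np.asarray(gmap.cm_at(str(chrom), grp["pos"].to_numpy(dtype=float)))
        tile = np.floor(cm / window_cm).astype(int)
        for t in np.unique(tile):
            windows.append(
                Window(str(chrom), float(t * window_cm), float((t + 1) * window_cm),
                       "cM", idx[tile == t])
            )
    return windows


def filter_sparse_windows(
    windows: list[Window], min_snps: int = 6, enabled: bool = True
) -> list[Window]:
    """Drop windows with fewer than ``min_snps`` SNPs (no-op when disabled).

    The dense-array mode removes windows with <= 5 SNPs; sparse-panel
    genetic windows keep everything (``enabled=False``).
    """
    if not enabled:
        return list(windows)
    return [w for w in windows if w.n_snps >= min_snps]


def enumerate_haplotypes(gm: GenotypeMatrix, window: Window, population: str) -> Counter:
    """Count haplotype strings in one window for one population.

    LR individuals contribute both phased strings; DH lines contribute a
    single string (their two chromosomes are identical).  Any string with
    a missing allele is dropped entirely rather than counted partially.
    """
    idx = window.site_index
    strings: list[str] = []
    if population == "LR":
        if gm.haplotypes is None:
            raise ValueError("LR haplotype enumeration requires phased genotypes")
        h = gm.haplotypes[:, idx, :]
        for i in range(gm.n_samples):
            for k in (0, 1):
                alleles = h[i, :, k]
                if np.any(alleles < 0):
                    continue
                strings.append("".join("1" if a else "0" for a in alleles))
    elif population == "DH":
        d = gm.dosages[:, idx]
        for i in range(gm.n_samples):
            row = d[i]
            if np.any((row != 0) & (row != 2)):   # missing or residual het
                continue
            strings.append("".join("1" if a == 2 else "0" for a in row))
    else:
        raise ValueError("population must be 'LR' or 'DH'")
    return Counter(strings)


def haplotype_diversity(counts, N: int | None = None) -> float:
    """Nei's haplotype diversity H = N/(N-1) * (1 - sum x_i^2).

    ``counts`` may be absolute counts (frequencies are computed from their
    sum) or frequencies summing to one with the sample size ``N`` given
    separately.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if N is None:
        N = total
    if N < 2:
        raise ValueError("haplotype diversity requires N >= 2 sampled haplotypes")
    x = counts / total
    return float(N / (N - 1.0) * (1.0 - np.sum(x**2)))


def major_haplotype_fate(lr_counts: Counter, dh_counts: Counter) -> tuple[str, str]:
    """Most abundant LR haplotype and its fate in the DH population.

    Ties on the LR count break to the lexicographically smallest string.
    Fate is ``lost`` if the haplotype is absent from DH, ``fixed`` if it is
    the only retained DH haplotype, else ``segregating``; an empty DH table
    yields ``NA``.
    """
    if not lr_counts:
        raise ValueError("empty LR haplotype table")
    major = min(lr_counts, key=lambda h: (-lr_counts[h], h))
    n_dh = sum(dh_counts.values())
    if n_dh == 0:
        return major, "NA"
    c = dh_counts.get(major, 0)
    if c == 0:
        return major, "lost"
    if c == n_dh:
        return major, "fixed"
    return major, "segregating"


def window_haplotype_analysis(
    lr: GenotypeMatrix,
    dh: GenotypeMatrix,
    windows: list[Window],
    min_lr_haplotypes: int = 2,
) -> list[HaplotypeWindow]:
    """Per-window haplotype tables, Nei's H and major-haplotype fate.

    Diversity is reported (non-None) only for windows with at least
    ``min_lr_haplotypes`` distinct LR haplotypes and >= 2 retained strings
    in the population concerned.
    """
    results = []
    for w in windows:
        lr_counts = enumerate_haplotypes(lr, w, "LR")
        dh_counts = enumerate_haplotypes(dh, w, "DH")
        n_lr = sum(lr_counts.values())
        n_dh = sum(dh_counts.values())
        haps = sorted(set(lr_counts) | set(dh_counts))
        table = pd.DataFrame(
            {
                "haplotype": haps,
                "count_lr": [lr_counts.get(h, 0) for h in haps],
                "count_dh": [dh_counts.get(h, 0) for h in haps],
            }
        )
        eligible = len(lr_counts) >= min_lr_haplotypes and n_lr >= 2
        h_lr = haplotype_diversity(list(lr_counts.values())) if eligible else None
        h_dh = (
            haplotype_diversity(list(dh_counts.values()))
            if eligible and n_dh >= 2
            else None
        )
        if lr_counts:
            major, fate = major_haplotype_fate(lr_counts, dh_counts)
        else:
            major, fate = None, "NA"
        results.append(HaplotypeWindow(w, table, n_lr, n_dh, h_lr, h_dh, major, fate))
    return results


@dataclass
class FateSummary:
    """Genome-wide fate proportions and mean haplotype diversity."""

    proportions: dict[str, float]     # lost / fixed / segregating, summing to 1
    n_classified: int
    mean_h_lr: float
    mean_h_dh: float


def summarize_fates(windows: list[HaplotypeWindow]) -> FateSummary:
    """Fate proportions over classified windows and mean H per population."""
    classified = [w for w in windows if w.fate in ("lost", "fixed", "segregating")]
    if not classified:
        raise ValueError("no classified windows")
    n = len(classified)
    props = {
        fate: sum(1 for w in classified if w.fate == fate) / n
        for fate in ("lost", "fixed", "segregating")
    }
    h_lr = [w.h_lr for w in windows if w.h_lr is not None]
    h_dh = [w.h_dh for w in windows if w.h_dh is not None]
    return FateSummary(
        props,
        n,
        float(np.mean(h_lr)) if h_lr else float("nan"),
        float(np.mean(h_dh)) if h_dh else float("nan"),
    )


def haplotype_table_frame(windows: list[HaplotypeWindow], accession: str) -> pd.DataFrame:
    """Flat per-window summary suitable for TSV export."""
    rows = []
    for hw in windows:
        w = hw.window
        rows.append(
            (
                accession, w.chrom, w.start, w.end, w.n_snps,
                int((hw.table["count_lr"] > 0).sum()),
                int((hw.table["count_dh"] > 0).sum()),
                np.nan if hw.h_lr is None else hw.h_lr,
                np.nan if hw.h_dh is None else hw.h_dh,
                hw.fate,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "accession", "chrom", "window_start", "window_end", "n_snps",
            "n_hap_LR", "n_hap_DH", "H_LR", "H_DH", "major_fate",
        ],
    )
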