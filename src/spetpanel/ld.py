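"""Pairwise linkage disequilibrium, windowed pruning and decay curves.

LD between two sites is the squared Pearson correlation of genotype
dosages (composite LD) over the samples called at both sites; it needs
no phase and is invariant to swapping allele coding. Pruning uses a
sliding site window: within every window, whenever a pair exceeds the r²
threshold the lower-MAF member is dropped, and passes repeat until no
window contains an offending pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix
from .variant_qc import site_stats_frame


@dataclass
class LdConfig:
    r2_threshold: float = 0.3
    window_size: int = 50
    window_step: int = 5
    max_decay_dist: int = 100_000
    decay_bin: int = 1_000
    use_r: bool = False  # prune on |r| instead of r^2

    def __post_init__(self) -> None:
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in (0,1]")
        if self.window_step > self.window_size:
            raise ValueError("window_step must be <= window_size")


def genotype_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """r² of genotype dosages over pairwise-complete samples.

    Returns NaN when fewer than two shared calls exist or either vector
    is constant on the shared set.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = (g1 != MISSING) & (g2 != MISSING)
    x, y = g1[ok], g2[ok]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _pairwise_r2(codes: np.ndarray) -> np.ndarray:
    """r² matrix for a (samples x sites) block, pairwise-complete."""
    x = codes.astype(float)
    x[codes == MISSING] = np.nan
    m = (~np.isnan(x)).astype(float)
    xz = np.where(m > 0, x, 0.0)
    n = m.T @ m  # shared-call counts
    s = m.T @ xz
    ss = m.T @ (xz * xz)
    sxy = xz.T @ xz
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - s * s.T / n
        var_i = ss - s * s / n  # var of site i over samples shared with j
        var_j = ss.T - s.T * s.T / n
        r2 = (cov * cov) / (var_i * var_j)
    r2[n < 2] = np.nan
    return r2


def ld_prune(matrix: GenotypeMatrix, cfg: LdConfig | None = None) -> np.ndarray:
    """Indices of sites kept after windowed LD pruning.

    Within each window of ``window_size`` consecutive surviving sites
    (advanced by ``window_step``), for any pair above the threshold the
    lower-MAF site is dropped (ties drop the later position). Passes
    repeat until stable, so the kept set contains no offending pair
    within any window of consecutive kept sites. Deterministic.
    """
    cfg = cfg or LdConfig()
    maf = site_stats_frame(matrix)["maf"].to_numpy()
    keep = np.ones(matrix.n_sites, dtype=bool)
    thresh = cfg.r2_threshold if not cfg.use_r else cfg.r2_threshold**2
    changed = True
    while changed:
        changed = False
        alive = np.flatnonzero(keep)
        starts = range(0, max(1, alive.size), cfg.window_step)
        for s in starts:
            win = alive[s : s + cfg.window_size]
            win = win[keep[win]]
            if win.size < 2:
                continue
            r2 = _pairwise_r2(matrix.codes[:, win])
            iu, ju = np.triu_indices(win.size, k=1)
            over = (r2[iu, ju] > thresh) & np.isfinite(r2[iu, ju])
            for a, b in zip(iu[over], ju[over]):
                ia, ib = win[a], win[b]
                if not (keep[ia] and keep[ib]):
                    continue
                # drop the lower-MAF member; tie -> later position
                drop = ib if (maf[ia] > maf[ib] or np.isnan(maf[ib])) else (
                    ia if maf[ib] > maf[ia] else ib
                )
                keep[drop] = False
                changed = True
    return np.flatnonzero(keep)


def ld_decay(matrix: GenotypeMatrix, cfg: LdConfig | None = None) -> pd.DataFrame:
    """Mean r² by physical-distance bin over all within-chromosome pairs
    up to ``max_decay_dist``. Columns: bin_lo, bin_hi, mean_r2, n_pairs.
    """
    cfg = cfg or LdConfig()
    nb = int(np.ceil(cfg.max_decay_dist / cfg.decay_bin)) + 1
    sums = np.zeros(nb)
    counts = np.zeros(nb, dtype=int)
    sites = matrix.sites
    for _, grp in sites.groupby("chrom", sort=True):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        r2 = _pairwise_r2(matrix.codes[:, idx])
        iu, ju = np.triu_indices(idx.size, k=1)
        dist = np.abs(pos[ju] - pos[iu])
        ok = (dist <= cfg.max_decay_dist) & np.isfinite(r2[iu, ju])
        b = (dist[ok] // cfg.decay_bin).astype(int)
        np.add.at(sums, b, r2[iu, ju][ok])
        np.add.at(counts, b, 1)
    used = counts > 0
    return pd.DataFrame(
        {
            "bin_lo": np.arange(nb)[used] * cfg.decay_bin,
            "bin_hi": (np.arange(nb)[used] + 1) * cfg.decay_bin,
            "mean_r2": sums[used] / counts[used],
            "n_pairs": counts[used],
        }
    )
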