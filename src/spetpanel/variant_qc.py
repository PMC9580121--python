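"""Post-calling site filters and per-site statistics.

The hard-filter cascade mirrors the GATK-style expression
``QD < 2.0 || MQ < 40.0 || MQRankSum < -12.5`` followed by extraction of
high-confidence sites (mean depth >= 30, call rate >= 90%, at least one
non-reference allele observed). Comparisons are strict, exactly as in the
expression: a site sitting on a threshold passes. A site lacking an
annotation passes that specific rule by default (the semantics of the
expression's engine, where a missing value cannot satisfy ``<``);
``fail_if_absent=True`` inverts this.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix


@dataclass
class SiteStats:
    """Per-site summaries on non-missing calls.

    maf is folded (in [0, 0.5]); hexp is 2p(1-p) from allele counts;
    mean_depth is NaN where no depth annotation exists.
    """

    maf: float
    missingness: float
    hobs: float
    hexp: float
    mean_depth: float = float("nan")


@dataclass
class FilterConfig:
    """Thresholds of the hard-filter cascade (strict comparisons).

    ``max_missing`` is the maximum tolerated fraction of missing calls per
    site; the conventional "max-missing 0.90" phrasing (>= 90% called)
    corresponds to 0.10 here.
    """

    qd_min: float = 2.0
    mq_min: float = 40.0
    mqranksum_min: float = -12.5
    min_mean_dp: float = 30.0
    max_missing: float = 0.10
    require_nonref: bool = True
    maf_min: float = 0.05
    fail_if_absent: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must be in [0,1]")
        for name in ("qd_min", "mq_min", "mqranksum_min", "min_mean_dp", "maf_min"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def to_dict(self) -> dict:
        return asdict(self)


def compute_site_stats(
    genotypes: np.ndarray, mean_depth: float = float("nan")
) -> SiteStats:
    """Statistics for one genotype column (codes 0/1/2, -1 missing)."""
    g = np.asarray(genotypes)
    called = g[g != MISSING]
    if called.size == 0:
        raise ValueError("all calls missing; site stats undefined")
    n_het = int((called == 1).sum())
    n_homalt = int((called == 2).sum())
    p = (2 * n_homalt + n_het) / (2 * called.size)
    return SiteStats(
        maf=min(p, 1.0 - p),
        missingness=1.0 - called.size / g.size,
        hobs=n_het / called.size,
        hexp=2.0 * p * (1.0 - p),
        mean_depth=mean_depth,
    )


def site_stats_frame(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Vectorised per-site stats table (one row per site).

    Columns: maf, alt_freq, missingness, hobs, hexp, n_called, mean_depth.
    Sites with no non-missing call get NaN stats rather than an error.
    """
    codes = matrix.codes
    called = codes != MISSING
    n_called = called.sum(axis=0)
    n_het = (codes == 1).sum(axis=0)
    n_homalt = (codes == 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0, (2 * n_homalt + n_het) / (2 * n_called), np.nan)
        hobs = np.where(n_called > 0, n_het / n_called, np.nan)
    out = pd.DataFrame(
        {
            "maf": np.minimum(p, 1 - p),
            "alt_freq": p,
            "missingness": 1 - n_called / matrix.n_samples,
            "hobs": hobs,
            "hexp": 2 * p * (1 - p),
            "n_called": n_called,
        }
    )
    if matrix.site_annotations is not None and "mean_dp" in matrix.site_annotations:
        out["mean_depth"] = matrix.site_annotations["mean_dp"].to_numpy()
    else:
        out["mean_depth"] = np.nan
    return out


_RULES = ("QD", "MQ", "MQRankSum", "mean_depth", "missingness", "non_ref")


def apply_hard_filters(
    matrix: GenotypeMatrix, cfg: FilterConfig | None = None
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply the hard-filter cascade; return (kept matrix, per-rule counts).

    A removed site is attributed to the first failing rule in the order
    QD, MQ, MQRankSum, mean depth, missingness, non-ref; counts therefore
    sum to the number of removed sites.
    """
    cfg = cfg or FilterConfig()
    stats = site_stats_frame(matrix)
    ann = matrix.site_annotations
    n = matrix.n_sites

    def annot(col: str) -> np.ndarray:
        if ann is not None and col in ann:
            return ann[col].to_numpy(dtype=float)
        return np.full(n, np.nan)

    def strict_below(values: np.ndarray, thresh: float) -> np.ndarray:
        absent = np.isnan(values)
        fail = values < thresh
        return np.where(absent, cfg.fail_if_absent, fail)

    fails = [
        ("QD", strict_below(annot("QD"), cfg.qd_min)),
        ("MQ", strict_below(annot("MQ"), cfg.mq_min)),
        ("MQRankSum", strict_below(annot("MQRankSum"), cfg.mqranksum_min)),
        ("mean_depth", strict_below(stats["mean_depth"].to_numpy(), cfg.min_mean_dp)),
        ("missingness", stats["missingness"].to_numpy() > cfg.max_missing),
        (
            "non_ref",
            (
                ((matrix.codes == 1) | (matrix.codes == 2)).sum(axis=0) == 0
                if cfg.require_nonref
                else np.zeros(n, dtype=bool)
            ),
        ),
    ]
    removed_by = np.full(n, -1, dtype=int)
    for i, (_, mask) in enumerate(fails):
        mask = np.asarray(mask, dtype=bool)
        removed_by = np.where((removed_by == -1) & mask, i, removed_by)
    counts = {name: int((removed_by == i).sum()) for i, (name, _) in enumerate(fails)}
    kept = np.flatnonzero(removed_by == -1)
    return matrix.take_sites(kept), counts


def maf_filter(matrix: GenotypeMatrix, maf_min: float = 0.05) -> GenotypeMatrix:
    """Keep sites with folded MAF strictly greater than ``maf_min``.

    Monomorphic sites (maf 0) and all-missing sites are always removed.
    Idempotent by construction.
    """
    stats = site_stats_frame(matrix)
    keep = np.flatnonzero(stats["maf"].to_numpy() > maf_min)
    return matrix.take_sites(keep)
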