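"""Panel-level summaries: MAF spectra, ascertainment-bias comparison,
marker spacing and per-sample heterozygosity.

The ascertainment-bias check correlates the folded minor-allele-frequency
spectrum of the assayed panel against the whole-genome call set the panel
was designed from: a panel whose site selection did not distort the
spectrum shows a strong positive Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import MISSING, SITE_KEY, GenotypeMatrix
from .variant_qc import site_stats_frame

log = logging.getLogger(__name__)


@dataclass
class MafSpectrum:
    """Folded allele-frequency spectrum over [0, 0.5].

    Bins are half-open except the last (so maf = 0.5 lands in the final
    bin); monomorphic sites fall in the first bin. ``maf`` keeps the
    per-site values for downstream pairing.
    """

    edges: np.ndarray
    counts: np.ndarray
    maf: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        assert int(self.counts.sum()) == int(np.isfinite(self.maf).sum())


@dataclass
class SpectrumComparison:
    """Paired-site MAF comparison between two datasets."""

    keys: pd.Index
    maf_a: np.ndarray
    maf_b: np.ndarray
    pearson_r: float
    p_value: float
    n_shared: int
    mode: str = "per-site"


def maf_spectrum(matrix: GenotypeMatrix, bins: int = 50, label: str = "") -> MafSpectrum:
    """Histogram of folded MAF across sites (NaN-maf sites excluded)."""
    if matrix.n_sites == 0:
        raise ValueError("empty matrix")
    maf = site_stats_frame(matrix)["maf"].to_numpy()
    finite = maf[np.isfinite(maf)]
    counts, edges = np.histogram(finite, bins=bins, range=(0.0, 0.5))
    return MafSpectrum(edges=edges, counts=counts, maf=maf, label=label)


def spectrum_correlation(
    a: GenotypeMatrix, b: GenotypeMatrix, mode: str = "per-site", bins: int = 50
) -> SpectrumComparison:
    """Pearson correlation of MAF between two datasets.

    ``per-site`` (default): pair folded MAFs site-by-site across the
    sites shared by key (chrom, pos, ref, alt). ``binned``: correlate the
    two binned spectra (per-bin counts over shared binning) instead.
    Requires >= 3 shared sites.
    """
    sa = site_stats_frame(a).set_index(a.site_keys())["maf"]
    sb = site_stats_frame(b).set_index(b.site_keys())["maf"]
    shared = sa.index.intersection(sb.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared sites; need >= 3")
    va = sa.loc[shared].to_numpy()
    vb = sb.loc[shared].to_numpy()
    ok = np.isfinite(va) & np.isfinite(vb)
    va, vb = va[ok], vb[ok]
    if mode == "per-site":
        r, p = sps.pearsonr(va, vb)
    elif mode == "binned":
        ca, _ = np.histogram(va, bins=bins, range=(0.0, 0.5))
        cb, _ = np.histogram(vb, bins=bins, range=(0.0, 0.5))
        r, p = sps.pearsonr(ca, cb)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SpectrumComparison(
        keys=shared[ok],
        maf_a=va,
        maf_b=vb,
        pearson_r=float(r),
        p_value=float(p),
        n_shared=int(ok.sum()),
        mode=mode,
    )


def adjacent_spacing(sites: pd.DataFrame) -> dict:
    """Gaps (bp) between adjacent sites within each chromosome.

    Returns mean/median/min/max over all gaps plus the gap vector;
    chromosomes with fewer than two sites contribute no gaps.
    """
    gaps = []
    for _, grp in sites.groupby("chrom", sort=True):
        pos = np.sort(grp["pos"].to_numpy())
        if pos.size >= 2:
            gaps.append(np.diff(pos))
    allg = np.concatenate(gaps) if gaps else np.array([], dtype=int)
    if allg.size == 0:
        return {"n_gaps": 0, "mean": np.nan, "median": np.nan, "min": np.nan,
                "max": np.nan, "gaps": allg}
    return {
        "n_gaps": int(allg.size),
        "mean": float(allg.mean()),
        "median": float(np.median(allg)),
        "min": int(allg.min()),
        "max": int(allg.max()),
        "gaps": allg,
    }


def sample_heterozygosity(matrix: GenotypeMatrix) -> pd.Series:
    """Fraction of het calls among non-missing calls, per sample.

    Samples with no called genotype are flagged in the log and excluded
    from the returned Series.
    """
    called = (matrix.codes != MISSING).sum(axis=1)
    het = (matrix.codes == 1).sum(axis=1)
    ok = called > 0
    if not ok.all():
        bad = [s for s, o in zip(matrix.sample_ids, ok) if not o]
        log.warning("samples with no called genotypes excluded: %s", bad)
    vals = het[ok] / called[ok]
    idx = [s for s, o in zip(matrix.sample_ids, ok) if o]
    return pd.Series(vals, index=idx, name="heterozygosity")
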