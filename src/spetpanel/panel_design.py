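"""Target-SNP selection for a SPET probe panel.

A candidate target must (i) fit the assay budget, (ii) keep a minimum
distance to every other selected target (5 kb within CDS, 10 kb in
intergenic context by default), (iii) admit a probe window on both the
left and right border and carry flanking SNPs inside the enrichment
footprint (so accessory variants can be discovered), and (iv) have an
alt-allele frequency in [0.10, 0.90] without an excess of heterozygosity
(a paralog-collapse proxy).

Selection maximises the number of targets under the spacing constraint.
Because the gap required between two adjacent selected sites is the
maximum of their per-class gaps, a plain left-to-right greedy scan is not
count-optimal when classes mix (a long-gap site can block two short-gap
sites that are mutually compatible); an exact dynamic program over
position-sorted candidates is used instead, with suffix maxima per
context class keeping it O(n log n). When the achievable maximum exceeds
the budget, candidates are ranked globally by score and re-selected
greedily in rank order under the same spacing constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from .io_formats import (
    MISSING,
    AnnotationIndex,
    GenotypeMatrix,
    CONTEXT_INTERGENIC,
)
from .variant_qc import site_stats_frame

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class DesignConfig:
    """Panel-design parameters.

    Gaps are measured target-to-target in bp; ``probe_len`` bases
    immediately 5' and 3' of the target form the probe windows;
    ``footprint_len`` is the enrichment footprint within which flanking
    SNPs must lie and accessory SNPs are later classified.
    """

    budget: int = 25_000
    min_gap_cds: int = 5_000
    min_gap_intergenic: int = 10_000
    maf_range: tuple[float, float] = (0.10, 0.90)
    het_excess_max: float = 0.60
    probe_len: int = 40
    footprint_len: int = 150
    min_flanking_snps: int = 2
    max_probe_window_snps: int | None = None

    def __post_init__(self) -> None:
        if isinstance(self.maf_range, list):
            self.maf_range = tuple(self.maf_range)
        if not (0 < self.min_gap_cds <= self.min_gap_intergenic):
            raise ValueError("need 0 < min_gap_cds <= min_gap_intergenic")
        if not (0 < self.probe_len < self.footprint_len):
            raise ValueError("need 0 < probe_len < footprint_len")
        if self.budget <= 0:
            raise ValueError("budget must be positive")

    def gap_for(self, context: str) -> int:
        return self.min_gap_intergenic if context == CONTEXT_INTERGENIC else self.min_gap_cds

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        return d


@dataclass
class PanelDesign:
    """Selected targets (DataFrame, one row per target) plus the config
    they were selected under."""

    targets: pd.DataFrame
    config: DesignConfig = field(default_factory=DesignConfig)

    def __len__(self) -> int:
        return len(self.targets)

    def config_dict(self) -> dict:
        return self.config.to_dict()

    def positions(self) -> dict[str, np.ndarray]:
        return {
            str(c): g["pos"].to_numpy()
            for c, g in self.targets.groupby("chrom", sort=True)
        }


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------

REASON_ELIGIBLE = "eligible"
REASON_MAF = "maf_range"
REASON_HET = "het_excess"
REASON_WINDOW = "probe_window"
REASON_FLANK = "flanking_snps"
REASON_WINDOW_SNPS = "probe_window_snps"


def eligibility_filter(
    matrix: GenotypeMatrix,
    fasta,
    cfg: DesignConfig,
    annotation: AnnotationIndex | None = None,
) -> pd.DataFrame:
    """Evaluate every site; return a candidate table with first-fail reasons.

    ``fasta`` is a mapping chrom -> sequence (or a ``pyfaidx.Fasta``).
    Columns: chrom, pos, ref, alt, context, alt_freq, hobs, n_flanking,
    reason (``eligible`` or the first failed rule in the order
    maf_range, het_excess, probe_window, probe_window_snps, flanking_snps),
    score (|alt_freq - 0.5|, lower = more informative), genic.
    """
    stats = site_stats_frame(matrix)
    sites = matrix.sites
    n = len(sites)
    alt_freq = stats["alt_freq"].to_numpy()
    hobs = stats["hobs"].to_numpy()

    seqs = {}
    for chrom in sites["chrom"].unique():
        seq = fasta[chrom]
        seqs[chrom] = str(seq[:]) if not isinstance(seq, str) else seq

    contexts = np.empty(n, dtype=object)
    for i, (chrom, pos) in enumerate(zip(sites["chrom"], sites["pos"])):
        if annotation is not None:
            contexts[i], _, _ = annotation.context(chrom, int(pos))
        else:
            contexts[i] = CONTEXT_INTERGENIC

    pos_by_chrom = {
        str(c): g["pos"].to_numpy() for c, g in sites.groupby("chrom", sort=False)
    }

    reasons = np.empty(n, dtype=object)
    n_flank = np.zeros(n, dtype=int)
    win_snps = np.zeros(n, dtype=int)
    lo, hi = cfg.maf_range
    for i, row in enumerate(sites.itertuples(index=False)):
        chrom, pos = row.chrom, int(row.pos)
        seq = seqs[chrom]
        if pos > len(seq):
            raise ValueError(f"site {chrom}:{pos} beyond reference length {len(seq)}")
        positions = pos_by_chrom[str(chrom)]
        near = positions[
            (np.abs(positions - pos) <= cfg.footprint_len) & (positions != pos)
        ]
        n_flank[i] = near.size
        win_snps[i] = int(
            np.count_nonzero(
                (np.abs(positions - pos) <= cfg.probe_len) & (positions != pos)
            )
        )
        if not (lo <= alt_freq[i] <= hi):
            reasons[i] = REASON_MAF
            continue
        if hobs[i] > cfg.het_excess_max:
            reasons[i] = REASON_HET
            continue
        p0 = pos - 1  # 0-based site index
        left = seq[p0 - cfg.probe_len : p0] if p0 - cfg.probe_len >= 0 else ""
        right = seq[p0 + 1 : p0 + 1 + cfg.probe_len]
        if (
            len(left) < cfg.probe_len
            or len(right) < cfg.probe_len
            or "N" in left.upper()
            or "N" in right.upper()
        ):
            reasons[i] = REASON_WINDOW
            continue
        if cfg.max_probe_window_snps is not None and win_snps[i] > cfg.max_probe_window_snps:
            reasons[i] = REASON_WINDOW_SNPS
            continue
        if n_flank[i] < cfg.min_flanking_snps:
            reasons[i] = REASON_FLANK
            continue
        reasons[i] = REASON_ELIGIBLE

    out = sites[["chrom", "pos", "ref", "alt"]].copy()
    out["context"] = contexts
    out["alt_freq"] = alt_freq
    out["hobs"] = hobs
    out["n_flanking"] = n_flank
    out["probe_window_snps"] = win_snps
    out["reason"] = reasons
    out["score"] = np.abs(alt_freq - 0.5)
    out["genic"] = out["context"] != CONTEXT_INTERGENIC
    return out


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def _max_count_selection(pos: np.ndarray, gap: np.ndarray) -> list[int]:
    """Exact maximum-cardinality subset of position-sorted candidates such
    that every adjacent selected pair (i, j) satisfies
    pos[j] - pos[i] >= max(gap[i], gap[j]).

    Dynamic program from the right: f[i] = best count of a valid selection
    whose leftmost member is i. Successors j need
    pos[j] >= pos[i] + max(gap[i], gap[j]); splitting on whether
    gap[j] <= gap[i] or not gives, for each distinct gap class, a
    contiguous suffix of that class — handled with per-class suffix
    maxima. Reconstruction prefers the earliest feasible position, making
    the output deterministic and lexicographically minimal among optima.
    """
    n = pos.size
    if n == 0:
        return []
    classes = np.unique(gap)
    by_class = {g: np.flatnonzero(gap == g) for g in classes}
    f = np.zeros(n, dtype=int)
    # suffix_best[g][k] = max f over members of class g with index >= idxs[k]
    suffix_best: dict[float, np.ndarray] = {g: np.zeros(by_class[g].size + 1, dtype=int) for g in classes}
    for i in range(n - 1, -1, -1):
        best_next = 0
        for g in classes:
            idxs = by_class[g]
            # successor in class g must satisfy pos[j] >= pos[i] + max(gap[i], g)
            need = pos[i] + max(gap[i], g)
            k = np.searchsorted(pos[idxs], need, side="left")
            best_next = max(best_next, suffix_best[g][k])
        f[i] = 1 + best_next
        # fold i into its class suffix maxima
        idxs = by_class[gap[i]]
        k = int(np.searchsorted(idxs, i))
        sb = suffix_best[gap[i]]
        sb[k] = max(f[i], sb[k + 1])
    total = int(f.max())
    # reconstruct: earliest index achieving the running target
    sel: list[int] = []
    target = total
    i = 0
    last = -1
    while target > 0:
        while True:
            if f[i] == target and (
                last < 0 or pos[i] - pos[last] >= max(gap[i], gap[last])
            ):
                break
            i += 1
        sel.append(i)
        last = i
        target -= 1
        i += 1
    return sel


def _greedy_by_rank(
    cand: pd.DataFrame, cfg: DesignConfig, budget: int
) -> list[int]:
    """Accept candidates in score-rank order while spacing permits, up to
    the budget. Returns row positions into ``cand``."""
    order = np.lexsort(
        (
            cand["alt"].to_numpy(),
            cand["ref"].to_numpy(),
            cand["pos"].to_numpy(),
            (~cand["genic"].to_numpy()).astype(int),
            cand["score"].to_numpy(),
        )
    )
    import bisect

    accepted: dict[str, list[tuple[int, int]]] = {}  # chrom -> sorted (pos, gap)
    chosen: list[int] = []
    chroms = cand["chrom"].to_numpy()
    poss = cand["pos"].to_numpy()
    gaps = np.array([cfg.gap_for(c) for c in cand["context"]])
    for i in order:
        if len(chosen) >= budget:
            break
        lst = accepted.setdefault(str(chroms[i]), [])
        p, g = int(poss[i]), int(gaps[i])
        k = bisect.bisect_left(lst, (p, g))
        ok = True
        if k > 0:
            lp, lg = lst[k - 1]
            if p - lp < max(g, lg):
                ok = False
        if ok and k < len(lst):
            rp, rg = lst[k]
            if rp - p < max(g, rg):
                ok = False
        if ok:
            lst.insert(k, (p, g))
            chosen.append(i)
    return sorted(chosen)


def select_targets(candidates: pd.DataFrame, cfg: DesignConfig) -> PanelDesign:
    """Select a maximum-count, budget-capped target set under spacing.

    ``candidates`` is an eligibility table (only rows with reason
    ``eligible`` are considered), sorted by (chrom, pos). Deterministic:
    position ties are broken by (ref, alt)."""
    cand = candidates[candidates["reason"] == REASON_ELIGIBLE].copy()
    if cand.empty:
        raise ValueError("no eligible candidates to select from")
    cand = cand.sort_values(
        ["chrom", "pos", "ref", "alt"], kind="mergesort"
    ).reset_index(drop=True)

    picked: list[int] = []
    for chrom, grp in cand.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        gap = np.array([cfg.gap_for(c) for c in grp["context"]], dtype=np.int64)
        sel = _max_count_selection(pos, gap)
        picked.extend(grp.index[sel])
    if len(picked) > cfg.budget:
        picked = [cand.index[i] for i in _greedy_by_rank(cand, cfg, cfg.budget)]
    chosen = cand.loc[sorted(picked)].reset_index(drop=True)

    probe = cfg.probe_len
    p0 = chosen["pos"].to_numpy() - 1
    out = chosen[
        ["chrom", "pos", "ref", "alt", "context", "n_flanking", "score"]
    ].copy()
    out["left_start"] = p0 - probe
    out["left_end"] = p0
    out["right_start"] = p0 + 1
    out["right_end"] = p0 + 1 + probe
    return PanelDesign(targets=out.reset_index(drop=True), config=cfg)


def extract_probe_sequences(panel: PanelDesign, fasta) -> pd.DataFrame:
    """Probe sequences for every target: left probe is the ``probe_len``
    bases immediately 5' of the site (+ strand); right probe is the
    reverse complement of the bases immediately 3' (so both read toward
    the target). Uppercase; raises on ambiguous bases."""
    rows = []
    for row in panel.targets.itertuples(index=False):
        seq = fasta[row.chrom]
        seq = str(seq[:]) if not isinstance(seq, str) else seq
        left = seq[row.left_start : row.left_end].upper()
        right = reverse_complement(seq[row.right_start : row.right_end]).upper()
        for side, probe in (("left", left), ("right", right)):
            if "N" in probe:
                raise ValueError(
                    f"ambiguous base in {side} probe window at {row.chrom}:{row.pos}"
                )
            rows.append(
                {
                    "id": f"{row.chrom}:{row.pos}:{row.ref}>{row.alt}_{side[0].upper()}",
                    "chrom": row.chrom,
                    "pos": row.pos,
                    "side": side,
                    "strand": "+",
                    "sequence": probe,
                }
            )
    return pd.DataFrame(rows)


def classify_called_sites(
    called_sites: pd.DataFrame, panel: PanelDesign, cfg: DesignConfig | None = None
) -> pd.Series:
    """Label each called site ``target`` (matches a designed position),
    ``accessory`` (within the enrichment footprint of some target) or
    ``unassigned``."""
    cfg = cfg or panel.config
    tpos = panel.positions()
    labels = []
    for row in called_sites.itertuples(index=False):
        pos_arr = tpos.get(str(row.chrom))
        if pos_arr is None or pos_arr.size == 0:
            labels.append("unassigned")
            continue
        d = np.abs(pos_arr - int(row.pos))
        if (d == 0).any():
            labels.append("target")
        elif (d <= cfg.footprint_len).any():
            labels.append("accessory")
        else:
            labels.append("unassigned")
    return pd.Series(labels, index=called_sites.index, name="class")
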