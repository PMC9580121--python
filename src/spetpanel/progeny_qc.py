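"""F1-cross marker QC: pseudo-testcross classification, Mendelian-
inconsistency genotyping-error estimation, segregation distortion and
identical-locus collapsing.

Error-rate estimation
---------------------
At a marker where both parents are called, an offspring call is
*inconsistent* when it cannot be produced by one gamete from each parent.
Not every genotyping error produces an inconsistency: at an hk x hk
marker (both parents het) all three offspring genotypes are producible,
so no error is ever detected there, while at a monomorphic hom x hom
marker every deviant call is an error. The raw inconsistency rate is
therefore an underestimate of the underlying per-call error rate. The
estimator divides the raw rate by the *detectable fraction* — the
probability, enumerated exactly per cross class under an explicit error
model, that an error produces an inconsistency — weighted by the number
of checked calls in each class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import MISSING, GenotypeMatrix

# cross (CP) configuration codes
LMXLL = "lmxll"  # het x hom: polymorphic in the seed parent only
NNXNP = "nnxnp"  # hom x het: polymorphic in the pollen parent only
HKXHK = "hkxhk"  # het x het
AAXBB = "aaxbb"  # hom-ref x hom-alt (or vice versa): all offspring het
MONOMORPHIC = "monomorphic"  # identical hom x hom
MISSING_PARENT = "missing_parent"

CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"
UNCHECKED = "unchecked"

ERROR_MODELS = ("uniform-swap", "allelic-dropout")


@dataclass
class CrossDataset:
    """Two parents plus an offspring genotype matrix over one site index.

    ``parent1`` is the seed parent (lm x ll carrier), ``parent2`` the
    pollen parent (nn x np carrier). ``codes`` holds the per-marker CP
    configuration, always derivable from the parent genotypes.
    """

    parent1: np.ndarray
    parent2: np.ndarray
    offspring: GenotypeMatrix
    codes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.parent1 = np.asarray(self.parent1, dtype=np.int8)
        self.parent2 = np.asarray(self.parent2, dtype=np.int8)
        n = self.offspring.n_sites
        if self.parent1.shape != (n,) or self.parent2.shape != (n,):
            raise ValueError("parent genotype vectors must match the site index")
        expected = classify_cp(self.parent1, self.parent2)
        if self.codes is None:
            self.codes = expected
        elif not np.array_equal(np.asarray(self.codes), expected):
            raise ValueError("CP codes inconsistent with parent genotypes")


# ---------------------------------------------------------------------------
# Gamete logic
# ---------------------------------------------------------------------------

def _gametes(g: int) -> tuple[int, ...]:
    """Alleles transmissible by an unphased genotype code."""
    return {0: (0,), 1: (0, 1), 2: (1,)}[g]


def producible_offspring(g_p1: int, g_p2: int) -> frozenset[int]:
    """Offspring genotype codes producible from one gamete of each parent."""
    return frozenset(a + b for a in _gametes(g_p1) for b in _gametes(g_p2))


def classify_cp_marker(g_p1: int, g_p2: int) -> str:
    """CP configuration from the two parental genotype codes."""
    if g_p1 == MISSING or g_p2 == MISSING:
        return MISSING_PARENT
    het1, het2 = g_p1 == 1, g_p2 == 1
    if het1 and het2:
        return HKXHK
    if het1:
        return LMXLL
    if het2:
        return NNXNP
    if g_p1 == g_p2:
        return MONOMORPHIC
    return AAXBB


def classify_cp(g_p1: np.ndarray, g_p2: np.ndarray) -> np.ndarray:
    """Vectorised :func:`classify_cp_marker`."""
    return np.array(
        [classify_cp_marker(int(a), int(b)) for a, b in zip(g_p1, g_p2)],
        dtype=object,
    )


def mendelian_check(g_p1: int, g_p2: int, g_off: int) -> str:
    """``consistent`` / ``inconsistent`` / ``unchecked`` for one trio call."""
    if MISSING in (g_p1, g_p2, g_off):
        return UNCHECKED
    return CONSISTENT if g_off in producible_offspring(g_p1, g_p2) else INCONSISTENT


def _consistency_table() -> np.ndarray:
    """Bool table t[g1, g2, goff] = offspring producible."""
    t = np.zeros((3, 3, 3), dtype=bool)
    for a in range(3):
        for b in range(3):
            for o in producible_offspring(a, b):
                t[a, b, o] = True
    return t


_CONSISTENT_TABLE = _consistency_table()


# ---------------------------------------------------------------------------
# Detectability
# ---------------------------------------------------------------------------

def _offspring_distribution(g_p1: int, g_p2: int) -> dict[int, float]:
    """Mendelian expected offspring genotype frequencies (unphased)."""
    dist: dict[int, float] = {}
    gam1, gam2 = _gametes(g_p1), _gametes(g_p2)
    w = 1.0 / (len(gam1) * len(gam2))
    for a in gam1:
        for b in gam2:
            dist[a + b] = dist.get(a + b, 0.0) + w
    return dist


def _error_outcomes(true_g: int, model: str) -> list[tuple[int, float]]:
    """Possible observed genotypes (and probabilities) when the error
    process hits a call whose true genotype is ``true_g``.

    uniform-swap: replaced by one of the two other codes, equiprobably.
    allelic-dropout: a het is read as either hom equiprobably; a hit on a
    true homozygote leaves the call unchanged (no observable error).
    """
    if model == "uniform-swap":
        others = [g for g in (0, 1, 2) if g != true_g]
        return [(g, 0.5) for g in others]
    if model == "allelic-dropout":
        if true_g == 1:
            return [(0, 0.5), (2, 0.5)]
        return [(true_g, 1.0)]
    raise ValueError(f"unknown error model {model!r}; expected one of {ERROR_MODELS}")


_REPRESENTATIVE = {
    MONOMORPHIC: (0, 0),
    AAXBB: (0, 2),
    LMXLL: (1, 0),
    NNXNP: (0, 1),
    HKXHK: (1, 1),
}


def detectable_fraction(code: str, error_model: str = "uniform-swap") -> float:
    """Probability that a call hit by the error process becomes
    Mendelian-inconsistent, for a marker of the given CP class.

    Exact enumeration: true offspring genotypes at Mendelian expected
    frequencies, error outcomes per the model, flagged iff the observed
    genotype is not producible. Symmetric under allele relabelling, so
    one representative parent pair per class suffices.
    """
    if code == MISSING_PARENT:
        raise ValueError("missing-parent markers are never checked")
    g1, g2 = _REPRESENTATIVE[code]
    producible = producible_offspring(g1, g2)
    total = 0.0
    for true_g, p_g in _offspring_distribution(g1, g2).items():
        for obs, p_obs in _error_outcomes(int(true_g), error_model):
            if obs not in producible:
                total += p_g * p_obs
    return total


# ---------------------------------------------------------------------------
# Error-rate estimation
# ---------------------------------------------------------------------------

@dataclass
class ErrorEstimate:
    """Mendelian-inconsistency error estimate for one cross.

    ``raw_rate`` is inconsistent/checked calls; ``adjusted_rate`` divides
    by the checked-call-weighted mean detectable fraction (undefined,
    NaN, when that fraction is 0). ``singleton_fraction`` is the share of
    inconsistent sites whose inconsistency comes from exactly one
    offspring.
    """

    n_calls_checked: int
    n_inconsistent: int
    raw_rate: float
    detectable_fraction: float
    adjusted_rate: float
    singleton_fraction: float
    error_model: str
    per_code_checked: dict[str, int] = field(default_factory=dict)


def estimate_error_rate(
    cross: CrossDataset, error_model: str = "uniform-swap"
) -> ErrorEstimate:
    """Estimate the per-call genotyping-error rate from Mendelian
    inconsistencies over all checkable (site, offspring) calls —
    segregating and monomorphic markers alike.
    """
    if error_model not in ERROR_MODELS:
        raise ValueError(f"unknown error model {error_model!r}")
    p1, p2 = cross.parent1, cross.parent2
    off = cross.offspring.codes  # (n_off, n_sites)
    parents_ok = (p1 != MISSING) & (p2 != MISSING)
    checked = (off != MISSING) & parents_ok[None, :]
    if not checked.any():
        raise ValueError("no checkable calls (parents or offspring all missing)")

    safe_p1 = np.where(parents_ok, p1, 0)
    safe_p2 = np.where(parents_ok, p2, 0)
    safe_off = np.where(off == MISSING, 0, off)
    consistent = _CONSISTENT_TABLE[safe_p1[None, :], safe_p2[None, :], safe_off]
    inconsistent = checked & ~consistent

    n_checked = int(checked.sum())
    n_inc = int(inconsistent.sum())
    raw = n_inc / n_checked

    checked_per_site = checked.sum(axis=0)
    codes = cross.codes
    det_by_code = {
        c: detectable_fraction(c, error_model)
        for c in (MONOMORPHIC, AAXBB, LMXLL, NNXNP, HKXHK)
    }
    weights = np.zeros(len(codes))
    per_code_checked: dict[str, int] = {}
    for c, d in det_by_code.items():
        mask = codes == c
        weights[mask] = d
        per_code_checked[c] = int(checked_per_site[mask].sum())
    det = float((weights * checked_per_site).sum() / n_checked)

    inc_per_site = inconsistent.sum(axis=0)
    inc_sites = inc_per_site > 0
    singleton = (
        float((inc_per_site == 1).sum() / inc_sites.sum()) if inc_sites.any() else 0.0
    )
    adjusted = raw / det if det > 0 else float("nan")
    return ErrorEstimate(
        n_calls_checked=n_checked,
        n_inconsistent=n_inc,
        raw_rate=raw,
        detectable_fraction=det,
        adjusted_rate=adjusted,
        singleton_fraction=singleton,
        error_model=error_model,
        per_code_checked=per_code_checked,
    )


# ---------------------------------------------------------------------------
# Segregation distortion & identical loci
# ---------------------------------------------------------------------------

def segregation_distortion(
    code: str, genotype_counts, alpha: float = 0.05
) -> tuple[float, int, float, bool]:
    """Chi-square goodness-of-fit against the expected 1:1 split of a
    single-parent-heterozygous marker.

    ``genotype_counts`` is the (n_homref, n_het, n_homalt) tally of
    non-missing offspring calls; the two producible classes for the code
    are tested (lm x ll and nn x np with a hom-ref parent: hom-ref vs
    het). Returns (chi2, df, p, distorted at p <= alpha).
    """
    if code not in (LMXLL, NNXNP):
        raise ValueError(f"1:1 distortion test applies to lmxll/nnxnp, not {code}")
    counts = np.asarray(genotype_counts, dtype=float)
    if counts.shape == (3,):
        # producible classes: the two largest-support adjacent classes
        # (hom-ref, het) or (het, hom-alt); pick by which hom class is used
        observed = (
            counts[[0, 1]] if counts[0] >= counts[2] else counts[[1, 2]]
        )
    elif counts.shape == (2,):
        observed = counts
    else:
        raise ValueError("expected 2 producible-class counts or 3 genotype counts")
    if observed.sum() == 0:
        raise ValueError("no non-missing offspring calls")
    chi2, p = sps.chisquare(observed)
    return float(chi2), 1, float(p), bool(p <= alpha)


def distortion_scan(cross: CrossDataset, alpha: float = 0.05) -> pd.DataFrame:
    """Per-marker 1:1 distortion test for all lm x ll / nn x np markers."""
    rows = []
    off = cross.offspring.codes
    for j, code in enumerate(cross.codes):
        if code not in (LMXLL, NNXNP):
            continue
        hom_parent = cross.parent2[j] if code == LMXLL else cross.parent1[j]
        classes = (0, 1) if hom_parent == 0 else (1, 2)
        col = off[:, j]
        obs = [int((col == c).sum()) for c in classes]
        if sum(obs) == 0:
            continue
        chi2, df, p, flag = segregation_distortion(code, obs, alpha=alpha)
        rows.append(
            {
                "site_index": j,
                "code": code,
                "n_class1": obs[0],
                "n_class2": obs[1],
                "chi2": chi2,
                "p": p,
                "distorted": flag,
            }
        )
    return pd.DataFrame(rows)


def pairwise_similarity(g1: np.ndarray, g2: np.ndarray) -> float:
    """Fraction of identical genotypes over pairwise-complete samples."""
    ok = (g1 != MISSING) & (g2 != MISSING)
    if not ok.any():
        return float("nan")
    return float((g1[ok] == g2[ok]).mean())


def collapse_identical(
    matrix: GenotypeMatrix, similarity_threshold: float = 0.95
) -> tuple[np.ndarray, list[list[int]]]:
    """Group near-identical loci (similarity strictly above the
    threshold, single linkage) and keep one representative per group:
    least missing, ties broken by lowest position.

    Returns (kept site indices sorted, groups as lists of site indices).
    """
    n = matrix.n_sites
    if n < 2:
        return np.arange(n), [[i] for i in range(n)]
    codes = matrix.codes
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    # restrict pair search within chromosomes? identical loci can occur
    # anywhere on the assay; compare all pairs.
    for i in range(n):
        gi = codes[:, i]
        for j in range(i + 1, n):
            s = pairwise_similarity(gi, codes[:, j])
            if np.isfinite(s) and s > similarity_threshold:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[rb] = ra
    groups_map: dict[int, list[int]] = {}
    for i in range(n):
        groups_map.setdefault(find(i), []).append(i)
    missing = (codes == MISSING).sum(axis=0)
    pos = matrix.sites["pos"].to_numpy()
    kept = []
    groups = []
    for members in groups_map.values():
        members.sort()
        best = min(members, key=lambda k: (missing[k], pos[k]))
        kept.append(best)
        groups.append(members)
    order = np.argsort([g[0] for g in groups])
    return np.array(sorted(kept)), [groups[k] for k in order]


def export_joinmap_cp(cross: CrossDataset, path: str, name: str = "cross") -> int:
    """Write the mapping-usable markers (lm x ll, nn x np) as a
    JoinMap-style CP locus file. Returns the number of exported loci."""
    off = cross.offspring.codes
    lines = []
    geno_code = {
        LMXLL: {0: "ll", 1: "lm", MISSING: "--", 2: "--"},
        NNXNP: {0: "nn", 1: "np", MISSING: "--", 2: "--"},
    }
    seg = {LMXLL: "<lmxll>", NNXNP: "<nnxnp>"}
    for j, code in enumerate(cross.codes):
        if code not in (LMXLL, NNXNP):
            continue
        site = cross.offspring.sites.iloc[j]
        # orient codes so the hom parent's allele is the reference state
        hom_parent = cross.parent2[j] if code == LMXLL else cross.parent1[j]
        col = off[:, j]
        if hom_parent == 2:  # relabel so hom class maps to ll/nn
            col = np.where(col == MISSING, MISSING, 2 - col)
        calls = " ".join(geno_code[code].get(int(c), "--") for c in col)
        lines.append(f"{site.chrom}_{site.pos} {seg[code]} {calls}")
    with open(path, "w") as fh:
        fh.write(f"name = {name}\n")
        fh.write("popt = CP\n")
        fh.write(f"nloc = {len(lines)}\n")
        fh.write(f"nind = {cross.offspring.n_samples}\n\n")
        fh.write("\n".join(lines) + "\n")
    return len(lines)
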