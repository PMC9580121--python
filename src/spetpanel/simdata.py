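"""Seeded synthetic-data generator for every input the toolkit consumes.

Emulates the data shapes of a targeted-genotyping study on a small
outbreeding tree genome: a random reference with gene models, founder
genotypes under Hardy-Weinberg with a tunable allele-frequency spectrum
and inbreeding coefficient, F1 progenies from phased parents with
Haldane (no-interference) recombination, and injected genotyping error
and missingness with a recorded truth mask. All randomness flows from a
single seed through spawned child generators; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix
from .progeny_qc import CrossDataset


@dataclass
class SimConfig:
    """Study-shaped defaults at desk scale.

    Allele frequencies are drawn from a symmetric Beta(1.5, 1.5) clipped
    to [0.01, 0.99] (folded-MAF mean ~ 0.3, matching a diversity panel
    where most assayed sites are common); missingness defaults to 1e-4
    (the assay's near-zero missing-data regime); one chromosome is 100 cM.
    """

    n_chrom: int = 2
    chrom_len_bp: int = 500_000
    n_sites: int = 2_000
    af_dist: str = "beta"  # "beta" or "uniform"
    af_params: tuple[float, float] = (1.5, 1.5)
    af_bounds: tuple[float, float] = (0.01, 0.99)
    n_samples: int = 128
    inbreeding_f: float = 0.0
    cm_per_chrom: float = 100.0
    genic_fraction: float = 0.4
    error_rate: float = 0.0
    error_model: str = "uniform-swap"
    missing_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0,1)")
        if not 0.0 <= self.inbreeding_f < 1.0:
            raise ValueError("inbreeding_f must be in [0,1)")
        if self.af_dist not in ("beta", "uniform"):
            raise ValueError("af_dist must be 'beta' or 'uniform'")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named random stream."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stream + 1)[stream])


# ---------------------------------------------------------------------------
# Reference + annotation
# ---------------------------------------------------------------------------

def simulate_reference(cfg: SimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Random reference sequences plus gene models.

    Returns (chrom -> sequence, features DataFrame with GFF3-style
    1-based inclusive coordinates: chrom, type, start, end, id, parent).
    Genes are non-overlapping, each 5'UTR + 3 exons/2 introns + 3'UTR,
    placed to cover ~``genic_fraction`` of the genome.
    """
    if cfg.genic_fraction > 1:
        raise ValueError("genic_fraction must be <= 1")
    rng = cfg.rng(0)
    seqs: dict[str, str] = {}
    feats: list[dict] = []
    bases = np.array(list("ACGT"))
    gene_n = 0
    for chrom in cfg.chrom_names():
        seqs[chrom] = "".join(rng.choice(bases, size=cfg.chrom_len_bp))
        target_genic = cfg.genic_fraction * cfg.chrom_len_bp
        covered = 0
        cursor = 1  # 1-based
        # mean intergenic gap keeps pace with the genic target:
        # gap ~= gene_len * (1 - f) / f so realised fraction ~= f
        gap_factor = (1 - cfg.genic_fraction) / max(cfg.genic_fraction, 1e-9)
        last_glen = 1_650  # expected gene length under the draws below
        while covered < target_genic and cursor < cfg.chrom_len_bp - 3_000:
            gap = max(50, int(last_glen * gap_factor * rng.uniform(0.6, 1.4)))
            utr5 = int(rng.integers(50, 200))
            utr3 = int(rng.integers(50, 300))
            exons = [int(rng.integers(100, 400)) for _ in range(3)]
            introns = [int(rng.integers(100, 500)) for _ in range(2)]
            glen = utr5 + utr3 + sum(exons) + sum(introns)
            start = cursor + gap
            end = start + glen - 1
            if end > cfg.chrom_len_bp:
                break
            gene_n += 1
            gid = f"gene{gene_n}"
            feats.append(dict(chrom=chrom, type="gene", start=start, end=end,
                              id=gid, parent=""))
            feats.append(dict(chrom=chrom, type="mRNA", start=start, end=end,
                              id=f"{gid}.t1", parent=gid))
            p = start
            feats.append(dict(chrom=chrom, type="five_prime_UTR", start=p,
                              end=p + utr5 - 1, id=f"{gid}.u5", parent=f"{gid}.t1"))
            # first exon spans the 5'UTR plus the first CDS block
            blocks = []
            p += utr5
            for k, (ex, intr) in enumerate(zip(exons, introns + [0])):
                blocks.append((p, p + ex - 1, k))
                p += ex + intr
            feats.append(dict(chrom=chrom, type="exon", start=start,
                              end=blocks[0][1], id=f"{gid}.e1", parent=f"{gid}.t1"))
            for k, (s, e, _) in enumerate(blocks):
                feats.append(dict(chrom=chrom, type="CDS", start=s, end=e,
                                  id=f"{gid}.c{k + 1}", parent=f"{gid}.t1"))
                if k > 0:
                    feats.append(dict(chrom=chrom, type="exon", start=s,
                                      end=e if k < len(blocks) - 1 else end,
                                      id=f"{gid}.e{k + 1}", parent=f"{gid}.t1"))
            feats.append(dict(chrom=chrom, type="three_prime_UTR",
                              start=blocks[-1][1] + 1, end=end,
                              id=f"{gid}.u3", parent=f"{gid}.t1"))
            covered += glen
            last_glen = glen
            cursor = end + 1
    return seqs, pd.DataFrame(feats)


def write_gff3(features: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in features.itertuples(index=False):
            attrs = f"ID={row.id}"
            if row.parent:
                attrs += f";Parent={row.parent}"
            fh.write(
                f"{row.chrom}\tspetpanel-sim\t{row.type}\t{row.start}\t{row.end}"
                f"\t.\t+\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Founders
# ---------------------------------------------------------------------------

def simulate_founders(
    cfg: SimConfig, reference: dict[str, str] | None = None
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Phased founder genotypes under inbreeding-adjusted Hardy-Weinberg.

    Per-site alt frequency q is drawn from the configured distribution;
    genotype probabilities are (p^2 + Fpq, 2pq(1-F), q^2 + Fpq). Het
    phase order is randomised. Returns (matrix, true alt frequencies).
    """
    rng = cfg.rng(1)
    per_chrom = _split_sites(cfg.n_sites, cfg.n_chrom)
    rows = []
    for chrom, k in zip(cfg.chrom_names(), per_chrom):
        hi = cfg.chrom_len_bp - 100
        pos = np.sort(rng.choice(np.arange(100, hi), size=k, replace=False))
        for p in pos:
            if reference is not None:
                ref = reference[chrom][p - 1].upper()
                if ref not in "ACGT":
                    ref = "A"
            else:
                ref = str(rng.choice(list("ACGT")))
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            rows.append((chrom, int(p), ref, alt))
    sites = (
        pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
        .sort_values(["chrom", "pos"], kind="mergesort")  # lexicographic, as stored
        .reset_index(drop=True)
    )

    n_sites = len(sites)
    lo, hi_b = cfg.af_bounds
    if cfg.af_dist == "beta":
        a, b = cfg.af_params
        q = np.clip(rng.beta(a, b, size=n_sites), lo, hi_b)
    else:
        q = rng.uniform(lo, hi_b, size=n_sites)

    f = cfg.inbreeding_f
    p_ = 1 - q
    probs = np.stack(
        [p_ * p_ + f * p_ * q, 2 * p_ * q * (1 - f), q * q + f * p_ * q], axis=1
    )
    u = rng.random((cfg.n_samples, n_sites))
    cum = np.cumsum(probs, axis=1)[None, :, :]
    codes = (u[:, :, None] > cum).sum(axis=2).astype(np.int8)

    haps = np.zeros((cfg.n_samples, n_sites, 2), dtype=np.int8)
    haps[codes == 2] = 1
    het = codes == 1
    first = rng.integers(0, 2, size=het.sum()).astype(np.int8)
    hh = np.zeros((int(het.sum()), 2), dtype=np.int8)
    hh[:, 0] = first
    hh[:, 1] = 1 - first
    haps[het] = hh

    sample_ids = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    return (
        GenotypeMatrix(sample_ids=sample_ids, sites=sites, codes=codes, haplotypes=haps),
        q,
    )


def _split_sites(n_sites: int, n_chrom: int) -> list[int]:
    base = n_sites // n_chrom
    out = [base] * n_chrom
    for i in range(n_sites - base * n_chrom):
        out[i] += 1
    return out


# ---------------------------------------------------------------------------
# F1 cross
# ---------------------------------------------------------------------------

def genetic_positions(sites: pd.DataFrame, cfg: SimConfig) -> np.ndarray:
    """Linear bp -> cM map: pos/chrom_len * cm_per_chrom per chromosome."""
    return sites["pos"].to_numpy() / cfg.chrom_len_bp * cfg.cm_per_chrom


def _gamete(
    haps: np.ndarray, cm: np.ndarray, chrom_bounds: list[tuple[int, int]],
    rng: np.random.Generator,
) -> np.ndarray:
    """One meiosis over all chromosomes: Haldane crossover process
    (Poisson count on the cM length, uniform positions, no interference).

    ``haps``: (n_sites, 2) parental haplotypes; ``cm``: site positions in
    cM (restarting per chromosome); returns the transmitted allele per
    site.
    """
    out = np.empty(haps.shape[0], dtype=np.int8)
    for lo, hi in chrom_bounds:
        seg = cm[lo:hi]
        span = float(seg.max() - seg.min()) if hi > lo else 0.0
        n_xo = rng.poisson(span / 100.0)
        xo = np.sort(rng.uniform(seg.min(), seg.max(), size=n_xo)) if n_xo else np.empty(0)
        phase0 = int(rng.integers(0, 2))
        phase = (phase0 + np.searchsorted(xo, seg, side="right")) % 2
        out[lo:hi] = haps[np.arange(lo, hi), phase]
    return out


def simulate_f1(
    founders: GenotypeMatrix,
    parent1: str,
    parent2: str,
    n_offspring: int,
    cfg: SimConfig,
    seed: int | None = None,
) -> CrossDataset:
    """F1 progeny of two phased founders by independent simulated meioses."""
    if founders.haplotypes is None:
        raise ValueError("founders must be phased to simulate gametes")
    rng = np.random.default_rng(cfg.seed + 101 if seed is None else seed)
    h1 = founders.haplotypes[founders.sample_ids.index(parent1)]
    h2 = founders.haplotypes[founders.sample_ids.index(parent2)]
    cm = genetic_positions(founders.sites, cfg)
    bounds = []
    chroms = founders.sites["chrom"].to_numpy()
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            bounds.append((start, i))
            start = i
    n_sites = founders.n_sites
    codes = np.empty((n_offspring, n_sites), dtype=np.int8)
    haps = np.empty((n_offspring, n_sites, 2), dtype=np.int8)
    for k in range(n_offspring):
        g1 = _gamete(h1, cm, bounds, rng)
        g2 = _gamete(h2, cm, bounds, rng)
        haps[k, :, 0] = g1
        haps[k, :, 1] = g2
        codes[k] = g1 + g2
    offspring = GenotypeMatrix(
        sample_ids=[f"F1_{k + 1:03d}" for k in range(n_offspring)],
        sites=founders.sites.copy(),
        codes=codes,
        haplotypes=haps,
    )
    return CrossDataset(
        parent1=founders.sample_genotypes(parent1),
        parent2=founders.sample_genotypes(parent2),
        offspring=offspring,
    )


# ---------------------------------------------------------------------------
# Error / missingness injection
# ---------------------------------------------------------------------------

def inject_errors_and_missing(
    matrix: GenotypeMatrix,
    error_rate: float,
    model: str = "uniform-swap",
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, dict[str, np.ndarray]]:
    """Perturb calls: each is hit by the error process independently with
    ``error_rate`` (uniform-swap: replaced by one of the two other codes;
    allelic-dropout: a het becomes a random hom, homs are unaffected),
    then masked missing independently with ``missing_rate``.

    Returns (perturbed matrix, truth masks: ``hit`` = error process drew
    the call, ``changed`` = genotype actually altered, ``masked`` = set
    to missing). Phase information is dropped from the output.
    """
    rng = np.random.default_rng(seed)
    codes = matrix.codes.copy()
    called = codes != MISSING
    hit = (rng.random(codes.shape) < error_rate) & called
    if model == "uniform-swap":
        shift = rng.integers(1, 3, size=codes.shape)
        new = (codes.astype(np.int16) + shift) % 3
        codes = np.where(hit, new, codes).astype(np.int8)
        changed = hit
    elif model == "allelic-dropout":
        hom = rng.integers(0, 2, size=codes.shape) * 2
        changed = hit & (codes == 1)
        codes = np.where(changed, hom, codes).astype(np.int8)
    else:
        raise ValueError(f"unknown error model {model!r}")
    masked = (rng.random(codes.shape) < missing_rate) & called
    codes[masked] = MISSING
    out = GenotypeMatrix(
        sample_ids=list(matrix.sample_ids),
        sites=matrix.sites.copy(),
        codes=codes,
        site_annotations=matrix.site_annotations,
    )
    return out, {"hit": hit, "changed": changed, "masked": masked}


def kosambi_to_haldane_cm(d_kosambi: float) -> float:
    """Convert a Kosambi map distance (cM) to the Haldane scale via the
    shared recombination fraction. Utility only; simulation is Haldane."""
    r = 0.5 * np.tanh(2 * d_kosambi / 100.0)
    return float(-50.0 * np.log(1.0 - 2.0 * r))


def haldane_recombination_fraction(d_cm: float) -> float:
    """Haldane map function: r = (1 - exp(-2d/100)) / 2."""
    return float(0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0)))
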