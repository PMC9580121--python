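"""Standard-format I/O and the shared coordinate conventions.

Conventions
-----------
* Internal coordinates are **0-based half-open**; all VCF-facing positions
  are **1-based** (the ``pos`` column of a :class:`GenotypeMatrix` and of
  panel TSVs is 1-based, matching the VCF they came from); BED output is
  0-based half-open.
* Genotypes are coded ``0`` (hom-ref), ``1`` (het), ``2`` (hom-alt) and
  ``-1`` (missing).
* Only simple biallelic SNPs are represented; multiallelic or indel VCF
  records are skipped and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: genotype code for a missing call
MISSING = -1

SITE_KEY = ["chrom", "pos", "ref", "alt"]

_BASES = frozenset("ACGT")


class VcfFormatError(ValueError):
    """Raised when a VCF cannot be parsed into biallelic-SNP genotypes."""


@dataclass
class VariantSite:
    """One biallelic SNP: position, alleles, per-sample genotype codes.

    ``pos`` is 1-based (VCF convention). ``annotations`` may carry caller
    statistics (QD, MQ, MQRankSum, mean DP across samples).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: np.ndarray
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"alleles must be single bases: {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid genotype codes: {self.genotypes[bad]}")


@dataclass
class GenotypeMatrix:
    """Samples x sites genotype codes with an explicit missing code.

    ``sites`` is a DataFrame with at least ``chrom, pos, ref, alt`` columns,
    sorted by (chrom, pos) with no duplicate (chrom, pos). ``codes`` has
    shape (n_samples, n_sites). ``haplotypes`` (optional, shape
    (n_samples, n_sites, 2), alleles 0/1, -1 missing) carries phase for
    simulator round-trips. ``site_annotations`` (optional, same row order
    as ``sites``) carries caller statistics.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    codes: np.ndarray
    haplotypes: np.ndarray | None = None
    site_annotations: pd.DataFrame | None = None
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError(
                f"codes shape {self.codes.shape} != "
                f"({len(self.sample_ids)} samples, {len(self.sites)} sites)"
            )
        self.sites = self.sites.reset_index(drop=True)
        key = self.sites[["chrom", "pos"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(f"duplicate site {dup.chrom}:{dup.pos}")
        order = self.sites.sort_values(["chrom", "pos"], kind="mergesort")
        if not order.index.equals(self.sites.index):
            raise ValueError("sites must be sorted by (chrom, pos)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    def site_keys(self) -> pd.Index:
        return pd.MultiIndex.from_frame(self.sites[SITE_KEY])

    def take_sites(self, idx) -> "GenotypeMatrix":
        """New matrix restricted to site indices ``idx`` (order-preserving)."""
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            codes=self.codes[:, idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, idx],
            site_annotations=None
            if self.site_annotations is None
            else self.site_annotations.iloc[idx].reset_index(drop=True),
        )

    def take_samples(self, names: list[str]) -> "GenotypeMatrix":
        pos = [self.sample_ids.index(n) for n in names]
        return GenotypeMatrix(
            sample_ids=list(names),
            sites=self.sites.copy(),
            codes=self.codes[pos],
            haplotypes=None if self.haplotypes is None else self.haplotypes[pos],
            site_annotations=self.site_annotations,
        )

    def sample_genotypes(self, name: str) -> np.ndarray:
        return self.codes[self.sample_ids.index(name)]

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.sites[SITE_KEY].equals(other.sites[SITE_KEY])
            and np.array_equal(self.codes, other.codes)
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str, sample_subset: list[str] | None = None) -> GenotypeMatrix:
    """Read a VCF 4.x (plain or gzipped) into a :class:`GenotypeMatrix`.

    Multiallelic and indel records are skipped (count in ``n_skipped``).
    Phase is retained when every genotype in the file is phased.
    INFO QD/MQ/MQRankSum and the per-sample DP mean populate
    ``site_annotations`` (NaN where absent).
    """
    import cyvcf2

    try:
        vcf = cyvcf2.VCF(path)
    except Exception as exc:  # htslib raises bare exceptions
        raise VcfFormatError(f"{path}: cannot open as VCF ({exc})") from exc

    all_samples = list(vcf.samples)
    if sample_subset is not None:
        keep = [s for s in sample_subset if s in all_samples]
        if not keep:
            raise ValueError(
                f"{path}: none of the requested samples present "
                f"(file has {len(all_samples)})"
            )
        vcf.set_samples(keep)
        samples = list(vcf.samples)
    else:
        samples = all_samples

    rows, codes, haps, annot = [], [], [], []
    n_skipped = 0
    phased_ok = True
    try:
        for rec in vcf:
            if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
                n_skipped += 1
                continue
            if rec.REF not in _BASES or rec.ALT[0] not in _BASES:
                n_skipped += 1
                continue
            gt = np.asarray(rec.genotype.array(), dtype=np.int16)
            a0, a1, ph = gt[:, 0], gt[:, 1], gt[:, 2]
            miss = (a0 < 0) | (a1 < 0)
            code = np.where(miss, MISSING, a0 + a1).astype(np.int8)
            codes.append(code)
            hap = np.stack([a0, a1], axis=1).astype(np.int8)
            hap[miss] = MISSING
            haps.append(hap)
            if not np.all(ph[~miss]):
                phased_ok = False
            rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
            try:
                dp = rec.format("DP")
            except KeyError:
                dp = None
            if dp is not None:
                dp = np.asarray(dp, dtype=float).ravel()
                mean_dp = float(np.nanmean(np.where(dp < 0, np.nan, dp)))
            else:
                info_dp = rec.INFO.get("DP")
                mean_dp = float(info_dp) / len(samples) if info_dp is not None else np.nan
            annot.append(
                (
                    _info_float(rec, "QD"),
                    _info_float(rec, "MQ"),
                    _info_float(rec, "MQRankSum"),
                    mean_dp,
                )
            )
    except VcfFormatError:
        raise
    except Exception as exc:
        raise VcfFormatError(f"{path}: malformed VCF record ({exc})") from exc

    if n_skipped:
        log.info("%s: skipped %d multiallelic/indel records", path, n_skipped)
    sites = pd.DataFrame(rows, columns=SITE_KEY)
    n = len(sites)
    mat = GenotypeMatrix(
        sample_ids=samples,
        sites=sites,
        codes=np.array(codes, dtype=np.int8).T.reshape(len(samples), n),
        haplotypes=(
            np.array(haps, dtype=np.int8).transpose(1, 0, 2).reshape(len(samples), n, 2)
            if phased_ok and n
            else None
        ),
        site_annotations=pd.DataFrame(
            annot, columns=["QD", "MQ", "MQRankSum", "mean_dp"]
        ),
        n_skipped=n_skipped,
    )
    return mat


def _info_float(rec, key: str) -> float:
    v = rec.INFO.get(key)
    return float(v) if v is not None else np.nan


def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write a matrix as plain-text VCF 4.2.

    Genotypes are phased (``|``) when the matrix carries haplotypes,
    unphased (``/``) otherwise. QD/MQ/MQRankSum/mean depth annotations are
    emitted as INFO fields when present.
    """
    ann = matrix.site_annotations
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=spetpanel\n')
        for chrom in matrix.sites["chrom"].unique():
            end = int(matrix.sites.loc[matrix.sites.chrom == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={end + 1000}>\n")
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Qual by depth">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write(
            '##INFO=<ID=MQRankSum,Number=1,Type=Float,'
            'Description="Mapping quality rank sum">\n'
        )
        fh.write('##INFO=<ID=MDP,Number=1,Type=Float,Description="Mean sample depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        phased = matrix.haplotypes is not None
        sep = "|" if phased else "/"
        unphased_gt = {0: f"0{sep}0", 1: f"0{sep}1", 2: f"1{sep}1", MISSING: "./."}
        for j, row in enumerate(matrix.sites.itertuples(index=False)):
            info_parts = []
            if ann is not None:
                for key, col in (
                    ("QD", "QD"),
                    ("MQ", "MQ"),
                    ("MQRankSum", "MQRankSum"),
                    ("MDP", "mean_dp"),
                ):
                    v = ann.iloc[j][col]
                    if pd.notna(v):
                        info_parts.append(f"{key}={v:g}")
            info = ";".join(info_parts) or "."
            if phased:
                col = matrix.haplotypes[:, j]
                gts = [
                    "./." if a[0] == MISSING else f"{a[0]}|{a[1]}" for a in col
                ]
            else:
                gts = [unphased_gt[int(c)] for c in matrix.codes[:, j]]
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t{info}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Gene-annotation index
# ---------------------------------------------------------------------------

CONTEXT_UTR = "UTR"
CONTEXT_EXON = "exon"
CONTEXT_INTRON = "intron"
CONTEXT_INTERGENIC = "intergenic"

_UTR_TYPES = {"five_prime_UTR", "three_prime_UTR", "UTR"}


class AnnotationIndex:
    """Per-chromosome interval trees over gene / exon / CDS / UTR features.

    Intervals are stored 0-based half-open. Queries take 1-based positions
    (the VCF convention used throughout the public API). Context precedence
    when features overlap is UTR > exon/CDS > intron > intergenic, so the
    UTR portion of a terminal exon is reported as UTR; precedence is a
    constructor option (``utr_over_cds=False`` folds UTRs into exons).
    """

    def __init__(self, utr_over_cds: bool = True):
        from intervaltree import IntervalTree
        from collections import defaultdict

        self._gene = defaultdict(IntervalTree)
        self._exon = defaultdict(IntervalTree)
        self._utr = defaultdict(IntervalTree)
        self.utr_over_cds = utr_over_cds
        self._warned: set[str] = set()

    @classmethod
    def from_gff3(cls, path: str, utr_over_cds: bool = True) -> "AnnotationIndex":
        import gffutils

        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        idx = cls(utr_over_cds=utr_over_cds)
        for feat in db.all_features():
            idx.add_feature(
                feat.seqid, feat.featuretype, feat.start, feat.end, feat.id
            )
        return idx

    def add_feature(
        self, chrom: str, ftype: str, start_1based: int, end_1based: int, fid: str = ""
    ) -> None:
        """Add one GFF3-style feature (1-based inclusive coordinates)."""
        lo, hi = start_1based - 1, end_1based  # to 0-based half-open
        if hi <= lo:
            return
        if ftype == "gene":
            self._gene[chrom][lo:hi] = fid
        elif ftype in ("exon", "CDS"):
            self._exon[chrom][lo:hi] = fid
        elif ftype in _UTR_TYPES:
            self._utr[chrom][lo:hi] = fid

    def context(self, chrom: str, pos: int) -> tuple[str, bool, str | None]:
        """Classify a 1-based position: (context, genic flag, gene id)."""
        if chrom not in self._gene and chrom not in self._exon:
            if chrom not in self._warned:
                log.warning("chromosome %s absent from annotation; intergenic", chrom)
                self._warned.add(chrom)
            return CONTEXT_INTERGENIC, False, None
        p = pos - 1
        genes = self._gene[chrom][p] if chrom in self._gene else set()
        gene_id = min((iv.data for iv in genes), default=None)
        in_utr = chrom in self._utr and bool(self._utr[chrom][p])
        in_exon = chrom in self._exon and bool(self._exon[chrom][p])
        if self.utr_over_cds and in_utr:
            return CONTEXT_UTR, True, gene_id
        if in_exon:
            return CONTEXT_EXON, True, gene_id
        if in_utr:
            return CONTEXT_UTR, True, gene_id
        if genes:
            return CONTEXT_INTRON, True, gene_id
        return CONTEXT_INTERGENIC, False, None


def annotate_context(
    site: VariantSite | tuple[str, int], index: AnnotationIndex
) -> tuple[str, bool, str | None]:
    """Context class for a site: (context in {UTR, exon, intron, intergenic},
    genic flag, gene id or None)."""
    if isinstance(site, VariantSite):
        return index.context(site.chrom, site.pos)
    chrom, pos = site
    return index.context(chrom, pos)


# ---------------------------------------------------------------------------
# Panel files
# ---------------------------------------------------------------------------

PANEL_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "context",
    "left_start",
    "left_end",
    "right_start",
    "right_end",
    "n_flanking",
    "score",
]


def write_panel(panel, path_tsv: str, path_bed: str | None = None) -> None:
    """Write a panel design as TSV (+ optional BED of probe windows).

    TSV ``pos`` is 1-based; window bounds and the BED are 0-based
    half-open (stated in the header comment). Raises if the panel is
    empty or a window underruns its chromosome start.
    """
    import json

    df = panel.targets
    if df.empty:
        raise ValueError("refusing to write an empty panel")
    if (df["left_start"] < 0).any():
        bad = df[df.left_start < 0].iloc[0]
        raise ValueError(f"probe window out of bounds at {bad.chrom}:{bad.pos}")
    with open(path_tsv, "w") as fh:
        fh.write("# spetpanel target panel; pos 1-based; windows 0-based half-open\n")
        fh.write("#config=" + json.dumps(panel.config_dict()) + "\n")
        df.to_csv(fh, sep="\t", index=False, columns=PANEL_COLUMNS,
                  float_format="%.17g")
    if path_bed is not None:
        with open(path_bed, "w") as fh:
            for row in df.itertuples(index=False):
                name = f"{row.chrom}:{row.pos}:{row.ref}>{row.alt}"
                fh.write(
                    f"{row.chrom}\t{row.left_start}\t{row.left_end}\t{name}_L\n"
                    f"{row.chrom}\t{row.right_start}\t{row.right_end}\t{name}_R\n"
                )


def read_panel(path_tsv: str):
    """Inverse of :func:`write_panel` (TSV part)."""
    import json

    from .panel_design import DesignConfig, PanelDesign

    cfg = None
    with open(path_tsv) as fh:
        for line in fh:
            if line.startswith("#config="):
                cfg = DesignConfig(**json.loads(line[len("#config=") :]))
            if not line.startswith("#"):
                break
    df = pd.read_csv(path_tsv, sep="\t", comment="#")
    if cfg is None:
        cfg = DesignConfig()
    return PanelDesign(targets=df.reset_index(drop=True), config=cfg)


def vcf_pos_to_bed_interval(pos: int) -> tuple[int, int]:
    """1-based VCF position -> 0-based half-open single-base BED interval."""
    return pos - 1, pos


def bed_interval_to_vcf_pos(start: int, end: int) -> int:
    """Single-base BED interval -> 1-based VCF position."""
    if end != start + 1:
        raise ValueError("not a single-base interval")
    return start + 1


def write_fasta(sequences: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
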