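"""Genotype containers, I/O, quality control and imputation.

Genotypes are held as sample × marker dosage matrices on the 0/1/2
minor-allele-count coding that the downstream distance, PCA and
whole-genome-regression stages consume: 0 = homozygous for the major
allele, 1 = heterozygous, 2 = homozygous for the minor allele.  Missing
calls are ``NaN``.  The minor/major orientation is a property of the
analysis cohort, so it is recomputed whenever cohorts are merged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("soygp")

MISSING = np.nan


@dataclass
class GenotypeMatrix:
    """Sample × marker dosage matrix with a marker map.

    Attributes
    ----------
    sample_ids, marker_ids : arrays of unique labels.
    chrom, pos : marker map (1-based positions, non-decreasing per chrom).
    dosage : float array (n_samples, n_markers), values in {0, 1, 2, NaN}.
    ref, alt : allele labels per marker; ``dosage`` counts copies of the
        allele flagged in ``counts_alt`` (True → ALT copies).
    coding : "minor" once orientation has been fixed to the cohort minor
        allele, "alt" for raw ALT-count matrices.
    imputed : True after missing cells have been filled.
    """

    sample_ids: np.ndarray
    marker_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None
    counts_alt: np.ndarray | None = None
    coding: str = "alt"
    imputed: bool = False
    missing_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.float64)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        if self.dosage.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise ValueError("dosage shape does not match ids")
        obs = self.dosage[~np.isnan(self.dosage)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all() and not self.imputed:
            raise ValueError("dosages must be in {0,1,2} or missing")
        if self.ref is None:
            self.ref = np.array(["A"] * self.n_markers, dtype=object)
        if self.alt is None:
            self.alt = np.array(["B"] * self.n_markers, dtype=object)
        if self.counts_alt is None:
            self.counts_alt = np.ones(self.n_markers, dtype=bool)
        # map must be sorted within chromosome
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not non-decreasing on chrom {c}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def subset(self, samples=None, markers=None) -> "GenotypeMatrix":
        """Row/column subset by id lists (order preserved as given)."""
        si = slice(None) if samples is None else self.sample_index(samples)
        if markers is None:
            mi = slice(None)
        else:
            mlookup = {m: j for j, m in enumerate(self.marker_ids)}
            mi = np.array([mlookup[m] for m in markers], dtype=np.intp)
        return replace(
            self,
            sample_ids=self.sample_ids[si],
            marker_ids=self.marker_ids[mi],
            chrom=self.chrom[mi],
            pos=self.pos[mi],
            dosage=self.dosage[si][:, mi],
            ref=self.ref[mi],
            alt=self.alt[mi],
            counts_alt=self.counts_alt[mi],
            missing_mask=None,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.sample_ids, columns=self.marker_ids)


# ---------------------------------------------------------------------------
# allele frequencies and orientation


def allele_frequencies(g: GenotypeMatrix, subset=None) -> np.ndarray:
    """Per-marker frequency of the counted allele: mean dosage / 2.

    Computed over non-missing calls of ``subset`` (all samples if None).
    """
    X = g.dosage if subset is None else g.dosage[g.sample_index(subset)]
    if X.shape[0] == 0:
        raise ValueError("empty sample subset")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        p = np.nanmean(X, axis=0) / 2.0
    return p


def recode_minor(g: GenotypeMatrix) -> GenotypeMatrix:
    """Orient dosages so they count the cohort minor allele.

    Markers whose counted-allele frequency exceeds 0.5 are complemented
    (dosage → 2 − dosage).  At an exact tie the alphabetically first
    allele keeps the major (reference) role, so the orientation is
    deterministic regardless of input orientation.
    """
    p = allele_frequencies(g)
    counted = np.where(g.counts_alt, g.alt, g.ref)
    other = np.where(g.counts_alt, g.ref, g.alt)
    flip = p > 0.5
    tie = np.isclose(p, 0.5)
    # on a tie the counted allele must be the alphabetically last one
    flip = np.where(tie, counted < other, flip)
    X = g.dosage.copy()
    X[:, flip] = 2.0 - X[:, flip]
    counts_alt = g.counts_alt ^ flip
    return replace(g, dosage=X, counts_alt=counts_alt, coding="minor")


# ---------------------------------------------------------------------------
# I/O

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write biallelic SNPs with GT fields to an uncompressed VCF v4.2."""
    alt_dosage = np.where(g.counts_alt, g.dosage, 2.0 - g.dosage)
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, g.sample_ids))
            + "\n"
        )
        for j in range(g.n_markers):
            calls = [
                "./." if np.isnan(d) else gt_map[d] for d in alt_dosage[:, j]
            ]
            fh.write(
                f"{g.chrom[j]}\t{g.pos[j]}\t{g.marker_ids[j]}\t{g.ref[j]}\t"
                f"{g.alt[j]}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def write_tsv(g: GenotypeMatrix, path) -> None:
    """Dosage matrix as TSV: samples in rows, marker ids as header, NA missing."""
    g.to_frame().to_csv(path, sep="\t", index_label="sample", na_rep="NA")


def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Load genotypes and orient to the minor-allele coding of the cohort.

    VCF: biallelic SNP records only — multiallelic records are dropped with
    a logged count; half-missing calls become missing.  TSV: plain dosage
    matrix; a synthetic map (single chromosome, index positions) and
    placeholder alleles are attached.
    """
    if format == "vcf":
        g = _read_vcf(path)
    elif format == "tsv":
        g = _read_tsv(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if g.n_samples == 0:
        raise ValueError("no samples in genotype file")
    return recode_minor(g)


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    mids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_multi += 1
            continue
        alleles = np.array([[a, b] for a, b, *_ in v.genotypes], dtype=np.int64)
        d = alleles.sum(axis=1).astype(float)
        d[(alleles < 0).any(axis=1)] = MISSING  # incl. half-missing "./1"
        rows.append(d)
        mids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
    if n_multi:
        logger.info("dropped %d non-biallelic-SNP records", n_multi)
    if not mids:
        raise ValueError("no biallelic SNP records in VCF")
    return GenotypeMatrix(
        sample_ids=samples,
        marker_ids=np.array(mids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss),
        dosage=np.vstack(rows).T,
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        counts_alt=np.ones(len(mids), dtype=bool),
        coding="alt",
    )


def _read_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    X = df.to_numpy(dtype=float)
    obs = X[~np.isnan(X)]
    continuous = obs.size > 0 and not np.isin(obs, (0.0, 1.0, 2.0)).all()
    return GenotypeMatrix(
        sample_ids=df.index.to_numpy(dtype=object),
        marker_ids=df.columns.to_numpy(dtype=object),
        chrom=np.array(["1"] * df.shape[1], dtype=object),
        pos=np.arange(1, df.shape[1] + 1),
        dosage=X,
        coding="alt",
        imputed=continuous,  # mean-imputed matrices round-trip through TSV
    )


# ---------------------------------------------------------------------------
# merging and QC


def merge_cohorts(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Stack two cohorts on their shared markers (matched by marker id).

    Sample ids must be disjoint.  Marker maps and allele pairs must agree
    at shared markers; both inputs are converted to a common physical
    orientation before stacking, then the minor-allele convention is
    recomputed on the merged cohort.
    """
    overlap = set(a.sample_ids) & set(b.sample_ids)
    if overlap:
        raise ValueError(f"sample ids not disjoint: {sorted(overlap)[:5]} ...")
    shared = [m for m in a.marker_ids if m in set(b.marker_ids)]
    if not shared:
        raise ValueError("no shared markers between cohorts")
    ga, gb = a.subset(markers=shared), b.subset(markers=shared)
    if not (np.array_equal(ga.chrom, gb.chrom) and np.array_equal(ga.pos, gb.pos)):
        raise ValueError("marker map mismatch at shared markers")
    same = (ga.ref == gb.ref) & (ga.alt == gb.alt)
    swapped = (ga.ref == gb.alt) & (ga.alt == gb.ref)
    if not np.all(same | swapped):
        bad = ga.marker_ids[~(same | swapped)][:5]
        raise ValueError(f"allele mismatch at shared markers, e.g. {list(bad)}")

    def alt_oriented(g):
        X = np.where(g.counts_alt, g.dosage, 2.0 - g.dosage)
        return X

    Xa = alt_oriented(ga)
    Xb = alt_oriented(gb)
    Xb[:, swapped] = 2.0 - Xb[:, swapped]  # express b on a's REF/ALT
    merged = GenotypeMatrix(
        sample_ids=np.concatenate([ga.sample_ids, gb.sample_ids]),
        marker_ids=ga.marker_ids,
        chrom=ga.chrom,
        pos=ga.pos,
        dosage=np.vstack([Xa, Xb]),
        ref=ga.ref,
        alt=ga.alt,
        counts_alt=np.ones(len(shared), dtype=bool),
        coding="alt",
    )
    return recode_minor(merged)


@dataclass
class QCConfig:
    """Marker QC thresholds: drop MAF < maf_min or missing fraction > missing_max."""

    maf_min: float = 0.05
    missing_max: float = 0.10

    def __post_init__(self) -> None:
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0 <= self.missing_max <= 1:
            raise ValueError("missing_max must be in [0, 1]")


def filter_markers(g: GenotypeMatrix, qc: QCConfig | None = None):
    """Keep markers with MAF ≥ maf_min and missing fraction ≤ missing_max.

    MAF is computed on non-missing calls.  Returns the filtered matrix and
    a report dict with per-criterion removal counts.  Boundary convention:
    a marker at exactly MAF = maf_min or missingness = missing_max is kept.
    """
    qc = qc or QCConfig()
    miss_frac = np.isnan(g.dosage).mean(axis=0)
    p = allele_frequencies(g)
    maf = np.minimum(p, 1.0 - p)
    maf = np.where(np.isnan(maf), 0.0, maf)  # fully missing → fails MAF too
    fail_maf = maf < qc.maf_min
    fail_miss = miss_frac > qc.missing_max
    keep = ~(fail_maf | fail_miss)
    report = {
        "n_input": int(g.n_markers),
        "removed_maf": int(fail_maf.sum()),
        "removed_missing": int(fail_miss.sum()),
        "removed_total": int((~keep).sum()),
        "n_retained": int(keep.sum()),
        "maf_min": qc.maf_min,
        "missing_max": qc.missing_max,
    }
    if report["n_retained"] == 0:
        raise ValueError("QC removed every marker")
    logger.info(
        "QC: retained %(n_retained)d/%(n_input)d markers "
        "(%(removed_maf)d failed MAF, %(removed_missing)d failed missingness)",
        report,
    )
    return g.subset(markers=list(g.marker_ids[keep])), report


def impute_missing(g: GenotypeMatrix, method: str = "marker_mean") -> GenotypeMatrix:
    """Fill missing cells per marker; observed cells are untouched.

    marker_mean gives continuous dosages (the regression models consume
    them directly); marker_mode stays on {0,1,2}.
    """
    mask = np.isnan(g.dosage)
    if not mask.any():
        return replace(g, imputed=True, missing_mask=mask)
    if np.any(mask.all(axis=0)):
        raise ValueError("marker with no observed calls cannot be imputed")
    X = g.dosage.copy()
    if method == "marker_mean":
        fill = np.nanmean(g.dosage, axis=0)
    elif method == "marker_mode":
        fill = np.zeros(g.n_markers)
        for j in np.where(mask.any(axis=0))[0]:
            col = g.dosage[:, j]
            vals, counts = np.unique(col[~np.isnan(col)], return_counts=True)
            fill[j] = vals[np.argmax(counts)]
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    X[mask] = np.broadcast_to(fill, X.shape)[mask]
    return replace(g, dosage=X, imputed=True, missing_mask=mask)
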