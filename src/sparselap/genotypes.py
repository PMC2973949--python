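"""Genotype containers, readers/writers, QC, imputation, and normalization.

Genotypes are coded on the dosage-like scale {0, 0.5, 1}: 0 = homozygous
reference, 0.5 = heterozygous, 1 = homozygous alternate. Missing calls are
``numpy.nan``; text writers emit ``NA``. Samples are rows, markers columns.

The normalization here is the EIGENSTRAT-style one used throughout
population-structure PCA: each marker column is mean-centered and divided by
sqrt(p(1-p)) with p a posterior (pseudocount-shrunk) allele-frequency
estimate, so that drifted markers are placed on a common variance scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyResultError, InputError

logger = logging.getLogger(__name__)

#: Missing-genotype sentinel (NaN; writers emit "NA").
MISSING = np.nan

_VALID_CODES = (0.0, 0.5, 1.0)


def _check_genotype_values(g: np.ndarray) -> None:
    finite = g[~np.isnan(g)]
    if finite.size and not np.isin(finite, _VALID_CODES).all():
        bad = finite[~np.isin(finite, _VALID_CODES)]
        raise InputError(
            f"genotypes must lie in {{0, 0.5, 1}} or be missing; found {bad[:5]!r}"
        )


@dataclass
class GenotypeMatrix:
    """An n-samples x m-markers genotype matrix with metadata.

    Parameters
    ----------
    genotypes
        Float array of shape (n, m) with entries in {0, 0.5, 1} or NaN.
    sample_ids
        Unique sample identifiers, length n.
    markers
        DataFrame with one row per marker and columns ``id``, ``chrom``,
        ``pos`` (1-based; strictly increasing within a chromosome) and
        optionally ``ref``/``alt``.
    """

    genotypes: np.ndarray
    sample_ids: list[str]
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise InputError("genotypes must be a 2-D array")
        n, m = self.genotypes.shape
        if n < 2 or m < 1:
            raise InputError(f"need at least 2 samples and 1 marker, got {n}x{m}")
        _check_genotype_values(self.genotypes)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != n:
            raise InputError("sample_ids length does not match genotype rows")
        if len(set(self.sample_ids)) != n:
            raise InputError("sample_ids must be unique")
        if not isinstance(self.markers, pd.DataFrame):
            self.markers = pd.DataFrame(self.markers)
        if len(self.markers) != m:
            raise InputError("markers table length does not match genotype columns")
        for col in ("id", "chrom", "pos"):
            if col not in self.markers.columns:
                raise InputError(f"markers table lacks required column {col!r}")
        if self.markers["id"].duplicated().any():
            raise InputError("marker ids must be unique")
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def marker_ids(self) -> list[str]:
        return self.markers["id"].astype(str).tolist()

    def missing_rate(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return np.isnan(self.genotypes).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Per-marker alternate-allele frequency from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.genotypes, axis=0)

    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency (folded to <= 0.5)."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset_markers(self, indices) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            self.genotypes[:, idx],
            list(self.sample_ids),
            self.markers.iloc[idx].reset_index(drop=True),
        )

    def subset_samples(self, indices) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            self.genotypes[idx, :],
            [self.sample_ids[i] for i in idx],
            self.markers.copy(),
        )


@dataclass
class NormalizedMatrix:
    """Mean-centered, posterior-frequency-scaled genotype matrix X.

    ``X[:, j] = (g_j - mean_j) / sqrt(p_j (1 - p_j))`` over the markers that
    survived normalization (non-constant columns), whose original indices are
    in ``kept_marker_indices``.
    """

    X: np.ndarray
    posterior_freqs: np.ndarray
    kept_marker_indices: np.ndarray
    sample_ids: list[str]
    marker_ids: list[str]
    provenance: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_markers(self) -> int:
        return self.X.shape[1]


def default_marker_table(ids, chrom: str = "1") -> pd.DataFrame:
    """Synthesize a marker table for ids lacking genomic coordinates."""
    ids = list(ids)
    return pd.DataFrame(
        {"id": ids, "chrom": chrom, "pos": np.arange(1, len(ids) + 1)}
    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def load_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes from a VCF (plain or bgzipped) or the package TSV dialect.

    ``format`` is inferred from the file suffix when omitted. VCF sites that
    are multiallelic or not SNPs are skipped (a count is logged); diploid
    calls map ref/ref -> 0, het -> 0.5, alt/alt -> 1, no-call -> missing.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"genotype file not found: {path}")
    if format is None:
        name = path.name.lower()
        format = "vcf" if (".vcf" in name or name.endswith(".bcf")) else "tsv"
    if format == "vcf":
        return _load_vcf(path)
    if format == "tsv":
        return read_genotype_tsv(path)
    raise InputError(f"unknown genotype format {format!r}")


def _load_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise InputError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows, meta, n_skipped = [], [], 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        gt = np.asarray(var.gt_types, dtype=float)  # 0,1,2 dosage; 3 unknown
        gt[gt == 3] = np.nan
        rows.append(gt / 2.0)
        meta.append(
            (var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM), int(var.POS),
             var.REF, var.ALT[0])
        )
    if n_skipped:
        logger.info("skipped %d multiallelic/non-SNP sites in %s", n_skipped, path)
    if not rows:
        raise EmptyResultError(f"no usable biallelic SNPs in {path}")
    markers = pd.DataFrame(meta, columns=["id", "chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(np.array(rows).T, samples, markers)


def read_genotype_tsv(path, markers_path=None) -> GenotypeMatrix:
    """Read the package TSV dialect: header = marker ids, first column =
    sample id, cells in {0, 0.5, 1, NA}. An optional sidecar table supplies
    ``id``/``chrom``/``pos`` metadata."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read genotype TSV {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise EmptyResultError(f"no marker columns in {path}")
    if markers_path is not None:
        markers = pd.read_csv(markers_path, sep="\t", dtype={"chrom": str})
        markers = (markers.set_index("id").reindex(df.columns)
                   .rename_axis("id").reset_index())
    else:
        markers = default_marker_table(df.columns)
    return GenotypeMatrix(df.to_numpy(dtype=float), list(df.index.astype(str)), markers)


def write_genotype_tsv(G: GenotypeMatrix, path, markers_path=None) -> None:
    df = pd.DataFrame(G.genotypes, index=G.sample_ids, columns=G.marker_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%g")
    if markers_path is not None:
        G.markers.to_csv(markers_path, sep="\t", index=False)


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 file. Values outside {0, 0.5, 1} (e.g. after
    mean imputation) cannot be represented and raise an error."""
    _check_genotype_values(G.genotypes)
    gt_map = {0.0: "0/0", 0.5: "0/1", 1.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sparselap\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.sample_ids) + "\n")
        ref = G.markers["ref"] if "ref" in G.markers else ["A"] * G.n_markers
        alt = G.markers["alt"] if "alt" in G.markers else ["G"] * G.n_markers
        for j in range(G.n_markers):
            row = G.markers.iloc[j]
            calls = "\t".join(
                "./." if np.isnan(g) else gt_map[g] for g in G.genotypes[:, j]
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['id']}\t"
                f"{list(ref)[j]}\t{list(alt)[j]}\t.\t.\t.\tGT\t{calls}\n"
            )


# ---------------------------------------------------------------------------
# QC / imputation / normalization
# ---------------------------------------------------------------------------

def qc_report(G: GenotypeMatrix, maf_min: float = 0.01,
              miss_max: float = 0.10) -> pd.DataFrame:
    """Per-marker QC table: id, maf, missing_rate, kept flag.

    A marker is kept iff MAF > ``maf_min`` (strict) and missing rate <
    ``miss_max`` (strict), the conventional array-QC thresholds.
    """
    if not (0 <= maf_min < 0.5):
        raise InputError(f"maf_min must be in [0, 0.5), got {maf_min}")
    if not (0 < miss_max <= 1):
        raise InputError(f"miss_max must be in (0, 1], got {miss_max}")
    miss = G.missing_rate()
    with np.errstate(invalid="ignore"):
        maf = G.maf()
    maf = np.where(np.isnan(maf), 0.0, maf)  # all-missing marker: MAF 0
    kept = (maf > maf_min) & (miss < miss_max)
    return pd.DataFrame(
        {"id": G.marker_ids, "maf": maf, "missing_rate": miss, "kept": kept}
    )


def qc_filter(G: GenotypeMatrix, maf_min: float = 0.01, miss_max: float = 0.10):
    """Drop markers failing MAF/missingness QC.

    Returns ``(filtered, report)`` where ``report`` is the `qc_report` table.
    Marker order is preserved.
    """
    report = qc_report(G, maf_min=maf_min, miss_max=miss_max)
    keep = np.flatnonzero(report["kept"].to_numpy())
    if keep.size == 0:
        raise EmptyResultError(
            f"QC removed all {G.n_markers} markers "
            f"(maf_min={maf_min}, miss_max={miss_max})"
        )
    return G.subset_markers(keep), report


def impute_missing(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls by the marker's mean non-missing genotype.

    Imputed values generally fall outside {0, 0.5, 1}; downstream numeric
    code accepts them, the VCF writer does not.
    """
    g = G.genotypes
    if not np.isnan(g).any():
        return G
    n_nonmiss = (~np.isnan(g)).sum(axis=0)
    if (n_nonmiss == 0).any():
        bad = [G.marker_ids[j] for j in np.flatnonzero(n_nonmiss == 0)[:5]]
        raise InputError(
            f"markers with zero non-missing calls (e.g. {bad}); run qc_filter first"
        )
    filled = g.copy()
    col_means = np.nanmean(g, axis=0)
    rr, cc = np.nonzero(np.isnan(g))
    filled[rr, cc] = col_means[cc]
    out = GenotypeMatrix.__new__(GenotypeMatrix)
    # bypass __post_init__'s {0,0.5,1} check: imputed dosages are continuous
    out.genotypes = filled
    out.sample_ids = list(G.sample_ids)
    out.markers = G.markers.copy()
    return out


def posterior_allele_freq(genotypes: np.ndarray, axis: int = 0) -> np.ndarray:
    """Posterior allele-frequency estimate p = (1 + sum 2g) / (2 + 2 n).

    The +1/+2 pseudocounts shrink the estimate strictly inside (0, 1), so the
    sqrt(p(1-p)) normalization scale never vanishes, even for markers
    monomorphic in the sample. Missing entries are excluded.
    """
    g = np.asarray(genotypes, dtype=float)
    n = (~np.isnan(g)).sum(axis=axis)
    if np.any(n == 0):
        raise InputError("posterior_allele_freq requires >= 1 non-missing call")
    s = np.nansum(2.0 * g, axis=axis)
    return (1.0 + s) / (2.0 + 2.0 * n)


def normalize(G: GenotypeMatrix, provenance: dict | None = None) -> NormalizedMatrix:
    """Center each marker and scale by sqrt(p(1-p)) of its posterior frequency.

    Missing entries are excluded from the mean and the frequency estimate and
    enter X as 0 (i.e. at the marker mean). Markers constant across samples
    carry no information and are dropped; their absence is visible in
    ``kept_marker_indices``.
    """
    g = G.genotypes
    with np.errstate(invalid="ignore"):
        means = np.nanmean(g, axis=0)
    freqs = posterior_allele_freq(g, axis=0)
    centered = g - means
    centered = np.where(np.isnan(centered), 0.0, centered)
    with np.errstate(invalid="ignore"):
        nonconst = np.nanmax(g, axis=0) > np.nanmin(g, axis=0)
    keep = np.flatnonzero(nonconst)
    if keep.size == 0:
        raise EmptyResultError("all markers are constant; nothing to normalize")
    scale = np.sqrt(freqs * (1.0 - freqs))
    X = centered[:, keep] / scale[keep]
    prov = dict(provenance or {})
    prov["n_dropped_constant"] = int(G.n_markers - keep.size)
    return NormalizedMatrix(
        X=X,
        posterior_freqs=freqs[keep],
        kept_marker_indices=keep,
        sample_ids=list(G.sample_ids),
        marker_ids=[G.marker_ids[j] for j in keep],
        provenance=prov,
    )


def prepare(G: GenotypeMatrix, qc: bool = True, maf_min: float = 0.01,
            miss_max: float = 0.10) -> tuple[GenotypeMatrix, NormalizedMatrix]:
    """QC -> impute -> normalize convenience pipeline.

    Returns the (optionally QC-filtered, imputed) genotype matrix and its
    normalized form.
    """
    report = None
    if qc:
        G, report = qc_filter(G, maf_min=maf_min, miss_max=miss_max)
    Gi = impute_missing(G)
    prov = {"qc": qc, "maf_min": maf_min, "miss_max": miss_max}
    if report is not None:
        prov["n_qc_removed"] = int((~report["kept"]).sum())
    return Gi, normalize(Gi, provenance=prov)
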