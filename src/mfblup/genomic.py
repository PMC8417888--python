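"""Genotype quality control and genomic relationship matrices.

Gene content is coded 0/1/2 copies of the reference allele with ``MISSING``
(5) for no-calls, the dialect used by animal-breeding solvers.  Two genomic
relationship matrices are supported:

* ``G``   — VanRaden, centred at observed allele frequencies of the current
  genotyped population and scaled by ``2 sum p_j (1 - p_j)``;
* ``G05`` — centred at allele frequency 0.5 (coding -1/0/1) and scaled by
  ``m / 2``, the compatible companion of the metafounder-modified pedigree
  matrix A22(Gamma).

Raw matrices are blended with the matching pedigree submatrix
(``alpha G_raw + (1 - alpha) A22``) to guarantee invertibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = 5

#: chromosome classes: autosome, sex chromosome, unknown position
AUTOSOME, SEX, UNKNOWN_POS = "A", "X", "U"


class GenomicError(ValueError):
    pass


@dataclass
class MarkerMatrix:
    """Gene-content matrix with per-marker metadata.

    ``geno`` is animals x markers, values in {0, 1, 2, MISSING} (integer) or
    real-valued after frequency imputation.  ``chrom_class`` is one of
    'A' (autosome), 'X' (sex chromosome), 'U' (unknown position).
    """

    geno: np.ndarray
    animal_ids: np.ndarray
    marker_ids: np.ndarray | None = None
    chrom_class: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.geno = np.asarray(self.geno)
        n, m = self.geno.shape
        self.animal_ids = np.asarray(self.animal_ids)
        if self.marker_ids is None:
            self.marker_ids = np.array([f"M{j + 1}" for j in range(m)])
        if self.chrom_class is None:
            self.chrom_class = np.full(m, AUTOSOME)

    @property
    def n_animals(self) -> int:
        return self.geno.shape[0]

    @property
    def n_markers(self) -> int:
        return self.geno.shape[1]

    def observed(self) -> np.ndarray:
        return self.geno != MISSING

    def call_rate(self) -> np.ndarray:
        return self.observed().mean(axis=0)

    def allele_frequency(self) -> np.ndarray:
        """Observed reference-allele frequency per marker (missing excluded)."""
        obs = self.observed()
        cnt = np.where(obs, self.geno, 0).sum(axis=0)
        denom = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(denom > 0, cnt / denom, np.nan)

    def het_frequency(self) -> np.ndarray:
        obs = self.observed()
        with np.errstate(invalid="ignore"):
            return np.where(obs.sum(axis=0) > 0,
                            ((self.geno == 1) & obs).sum(axis=0) / obs.sum(axis=0),
                            np.nan)


@dataclass
class QCReport:
    removed_position: int = 0
    removed_call_rate: int = 0
    removed_maf: int = 0
    removed_hwe: int = 0
    n_in: int = 0
    n_out: int = 0

    @property
    def total_removed(self) -> int:
        return (self.removed_position + self.removed_call_rate
                + self.removed_maf + self.removed_hwe)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"criterion": ["position/sex", "call_rate", "maf", "hwe",
                           "markers_in", "markers_out"],
             "count": [self.removed_position, self.removed_call_rate,
                       self.removed_maf, self.removed_hwe,
                       self.n_in, self.n_out]})


def qc_markers(markers: MarkerMatrix, maf_min: float = 0.05,
               call_rate_min: float = 0.90,
               hwe_max: float = 0.15) -> tuple[MarkerMatrix, QCReport]:
    """Marker quality control, applied in a fixed order.

    Removes, in order: markers with unknown position or on sex chromosomes;
    call rate < 0.90; minor allele frequency < 0.05; absolute difference
    between observed and expected (2p(1-p)) heterozygote frequency > 0.15.
    """
    report = QCReport(n_in=markers.n_markers)
    keep = markers.chrom_class == AUTOSOME
    report.removed_position = int((~keep).sum())

    cr = markers.call_rate()
    drop = keep & (cr < call_rate_min)
    report.removed_call_rate = int(drop.sum())
    keep &= ~drop

    p = markers.allele_frequency()
    maf = np.minimum(p, 1.0 - p)
    drop = keep & ~(maf >= maf_min)
    report.removed_maf = int(drop.sum())
    keep &= ~drop

    het = markers.het_frequency()
    dev = np.abs(het - 2.0 * p * (1.0 - p))
    drop = keep & (dev > hwe_max)
    report.removed_hwe = int(drop.sum())
    keep &= ~drop

    report.n_out = int(keep.sum())
    if report.n_out == 0:
        raise GenomicError("all markers removed by QC")
    out = MarkerMatrix(markers.geno[:, keep], markers.animal_ids,
                       markers.marker_ids[keep], markers.chrom_class[keep])
    return out, report


def impute_missing_within_matrix(markers: MarkerMatrix) -> tuple[MarkerMatrix, int]:
    """Replace missing gene contents by twice the observed allele frequency.

    Markers where every genotype is missing are removed with a warning-level
    count folded into the report of the caller.  Column means are preserved.
    """
    geno = markers.geno.astype(float)
    obs = markers.observed()
    p = markers.allele_frequency()
    all_missing = ~obs.any(axis=0)
    n_imputed = int((~obs).sum() - all_missing.sum() * markers.n_animals)
    fill = np.broadcast_to(2.0 * p, geno.shape)
    geno = np.where(obs, geno, fill)
    if all_missing.any():
        keep = ~all_missing
        out = MarkerMatrix(geno[:, keep], markers.animal_ids,
                           markers.marker_ids[keep], markers.chrom_class[keep])
    else:
        out = MarkerMatrix(geno, markers.animal_ids, markers.marker_ids,
                           markers.chrom_class)
    return out, n_imputed


@dataclass
class GenomicMatrix:
    """Symmetric animal x animal genomic relationship matrix."""

    values: np.ndarray
    animal_ids: np.ndarray
    tag: str = "raw"                 # raw | blended
    centering: str = "observed"      # observed | half
    alpha: float = 1.0


def _raw_G(Z: np.ndarray, denom: float) -> np.ndarray:
    if denom <= 0:
        raise GenomicError("zero scaling denominator (monomorphic markers?)")
    return (Z @ Z.T) / denom


def build_G(markers: MarkerMatrix, alpha: float = 0.95,
            A22: np.ndarray | None = None) -> GenomicMatrix:
    """VanRaden genomic relationship matrix centred at observed frequencies.

    ``Z = M - 2p``; ``G_raw = Z Z' / (2 sum p_j (1 - p_j))``; blended
    ``alpha G_raw + (1 - alpha) A22`` (requires ``A22`` unless alpha = 1).
    """
    M = markers.geno.astype(float)
    if np.any(M == MISSING):
        raise GenomicError("impute missing genotypes before building G")
    p = M.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise GenomicError("fewer than 2 polymorphic markers")
    Z = M - 2.0 * p
    raw = _raw_G(Z, 2.0 * np.sum(p * (1.0 - p)))
    return _blend(raw, markers.animal_ids, alpha, A22, centering="observed")


def build_G05(markers: MarkerMatrix, alpha: float = 0.95,
              A22_gamma: np.ndarray | None = None) -> GenomicMatrix:
    """Genomic relationship matrix centred at allele frequency 0.5.

    ``Z = M - 1``; ``G05_raw = Z Z' / (m / 2)``; blended against the
    metafounder-compatible pedigree submatrix A22(Gamma).
    """
    M = markers.geno.astype(float)
    if np.any(M == MISSING):
        raise GenomicError("impute missing genotypes before building G05")
    m = markers.n_markers
    if m == 0:
        raise GenomicError("no markers")
    raw = _raw_G(M - 1.0, m / 2.0)
    return _blend(raw, markers.animal_ids, alpha, A22_gamma, centering="half")


def _blend(raw: np.ndarray, ids: np.ndarray, alpha: float,
           A22: np.ndarray | None, centering: str) -> GenomicMatrix:
    if alpha == 1.0:
        return GenomicMatrix(raw, ids, tag="raw", centering=centering, alpha=1.0)
    if A22 is None:
        raise GenomicError("blending requires the pedigree submatrix")
    if A22.shape != raw.shape:
        raise GenomicError("A22 dimension mismatch")
    values = alpha * raw + (1.0 - alpha) * A22
    return GenomicMatrix(values, ids, tag="blended", centering=centering,
                         alpha=alpha)


def matrix_summary(matrices: dict[str, np.ndarray],
                   pairs: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Descriptive statistics of diagonal and off-diagonal elements.

    For each named matrix: mean/min/max/variance of the diagonal and of the
    off-diagonal elements.  For each requested pair: element-wise Pearson
    correlation between corresponding diagonal elements and between
    corresponding off-diagonal elements.
    """
    shapes = {m.shape for m in matrices.values()}
    if len(shapes) > 1:
        raise GenomicError("matrix dimension mismatch")
    rows = []
    tri = None
    for name, mat in matrices.items():
        d = np.diag(mat)
        if tri is None:
            tri = np.triu_indices(mat.shape[0], k=1)
        o = mat[tri]
        for part, x in (("diagonal", d), ("offdiagonal", o)):
            rows.append({"matrix": name, "part": part, "mean": x.mean(),
                         "min": x.min(), "max": x.max(),
                         "variance": x.var(ddof=1) if x.size > 1 else 0.0})
    for a, b in pairs or []:
        ma, mb = matrices[a], matrices[b]
        for part, xa, xb in (("diagonal", np.diag(ma), np.diag(mb)),
                             ("offdiagonal", ma[tri], mb[tri])):
            r = (np.corrcoef(xa, xb)[0, 1]
                 if xa.std() > 0 and xb.std() > 0 else np.nan)
            rows.append({"matrix": f"{a}~{b}", "part": part,
                         "correlation": r})
    return pd.DataFrame(rows)
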