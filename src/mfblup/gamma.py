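"""Estimation of the metafounder relationship matrix Gamma.

Base-population allele frequencies are estimated per marker by generalized
least squares from gene content regressed on breed fractions, with the
pedigree relationships among genotyped animals (A22) as the error
covariance.  Gamma is then eight times the covariance, across markers, of
the estimated base-frequency columns.  A diagonal entry below one signals
excess base heterozygosity; a positive off-diagonal signals overlapping
ancestral populations.

The metafounder model also requires the additive variance components to be
re-expressed on the metafounder base, handled by
:func:`scale_variance_components`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg as la

from .pedigree import GammaMatrix


@dataclass
class BaseFrequencyEstimate:
    """Per-marker estimated base-population allele frequencies.

    ``freqs`` is markers x k.  Raw (unclipped) estimates are retained; use
    :meth:`clipped` for reporting.
    """

    freqs: np.ndarray
    labels: list[str]
    dropped: list[str]

    def clipped(self) -> np.ndarray:
        return np.clip(self.freqs, 0.0, 1.0)


def gls_base_frequencies(gene_content: np.ndarray, Q_breed: np.ndarray,
                         A22: np.ndarray | None = None,
                         labels: list[str] | None = None,
                         ) -> BaseFrequencyEstimate:
    """GLS estimate of base-population allele frequencies.

    Per marker j the model is ``m_j = 2 Q p_j + e`` with ``Var(e)
    proportional to A22``; the estimator is
    ``p_hat_j = 0.5 (Q' A22^-1 Q)^-1 Q' A22^-1 m_j``.  Passing ``A22=None``
    uses the identity weight (ordinary least squares).

    A breed column with no representation among the genotyped animals makes
    the normal equations singular; such columns are dropped with a warning.
    """
    M = np.asarray(gene_content, dtype=float)
    Q = np.asarray(Q_breed, dtype=float)
    if labels is None:
        labels = [f"P{j + 1}" for j in range(Q.shape[1])]
    present = (np.abs(Q) > 0).any(axis=0)
    dropped = [lab for lab, ok in zip(labels, present) if not ok]
    if dropped:
        warnings.warn(f"breeds absent from genotyped animals dropped: {dropped}")
        Q = Q[:, present]
        labels = [lab for lab, ok in zip(labels, present) if ok]
    if A22 is None:
        WQ, WM = Q, M
    else:
        cho = la.cho_factor(A22)
        WQ = la.cho_solve(cho, Q)
        WM = la.cho_solve(cho, M)
    lhs = Q.T @ WQ
    try:
        sol = la.solve(lhs, Q.T @ WM, assume_a="pos")
    except la.LinAlgError:
        # rank-deficient composition design (e.g. only composites with
        # proportional fractions genotyped): fall back to the minimum-norm
        # least-squares solution
        warnings.warn("rank-deficient GLS design; using the minimum-norm "
                      "solution")
        sol = np.linalg.lstsq(lhs, Q.T @ WM, rcond=None)[0]
    return BaseFrequencyEstimate(0.5 * sol.T, list(labels), dropped)


def estimate_gamma(base_freqs: BaseFrequencyEstimate | np.ndarray,
                   centering: str = "mean") -> GammaMatrix:
    """Gamma = 8 x covariance across markers of the base-frequency columns.

    ``centering='mean'`` (default) centres each column at its own
    across-marker mean, which is invariant to reference-allele
    ascertainment; ``centering='half'`` centres at 0.5.
    """
    if isinstance(base_freqs, BaseFrequencyEstimate):
        P = base_freqs.freqs
        labels = base_freqs.labels
    else:
        P = np.asarray(base_freqs, dtype=float)
        labels = [f"MF{j + 1}" for j in range(P.shape[1])]
    m = P.shape[0]
    if m < 2:
        raise ValueError("at least 2 markers are required to estimate gamma")
    if centering == "mean":
        Z = P - P.mean(axis=0)
        cov = (Z.T @ Z) / (m - 1)
    elif centering == "half":
        Z = P - 0.5
        cov = (Z.T @ Z) / m
    else:
        raise ValueError("centering must be 'mean' or 'half'")
    return GammaMatrix(8.0 * cov, labels=list(labels))


def map_gamma_to_groups(gamma4: GammaMatrix,
                        fractions: np.ndarray,
                        labels: list[str]) -> GammaMatrix:
    """Expand a 4-breed Gamma to composite groups via their breed fractions.

    For groups g, h with breed-fraction vectors f_g, f_h the relationship is
    the quadratic form ``gamma(g, h) = f_g' Gamma4 f_h`` — the fallback when
    a group has no genotyped animals of its own.
    """
    F = np.asarray(fractions, dtype=float)
    if F.ndim != 2 or F.shape[1] != gamma4.k:
        raise ValueError("fraction vectors must be groups x breeds")
    if np.isnan(F).any():
        raise ValueError("undefined group fraction vector")
    vals = F @ gamma4.values @ F.T
    return GammaMatrix(vals, labels=list(labels))


def gamma_scaling_constant(gamma: GammaMatrix | np.ndarray) -> float:
    """k = 1 + mean(diag Gamma) / 2 - mean(Gamma)."""
    G = gamma.values if isinstance(gamma, GammaMatrix) else np.asarray(gamma)
    return float(1.0 + np.mean(np.diag(G)) / 2.0 - np.mean(G))


def scale_variance_components(additive: np.ndarray | float,
                              gamma: GammaMatrix | np.ndarray,
                              ) -> tuple[np.ndarray | float, float]:
    """Re-express additive (co)variances on the metafounder base.

    Divides every additive (co)variance by ``k = 1 + mean(diag Gamma)/2 -
    mean(Gamma)``; non-additive components are left untouched by the caller.
    Returns the scaled components and k.
    """
    k = gamma_scaling_constant(gamma)
    if k <= 0:
        raise ValueError(f"non-positive scaling constant k = {k:.4f}")
    if np.isscalar(additive):
        return additive / k, k
    return np.asarray(additive, dtype=float) / k, k
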