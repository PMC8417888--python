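"""LR-method validation: whole/partial datasets and the four estimators.

The linear-regression (LR) method compares predictions for a validation
cohort from a *reduced* dataset (their phenotypes, and those of their
contemporaries, removed) against predictions from the *complete* dataset:

* accuracy   ``rho_cr  = sqrt( cov(u_c, u_r) / ((1 - Fbar) sigma_u^2) )``
* stability  ``cor_cr  = cor(u_c, u_r)``
* dispersion ``b1`` from the regression ``u_c = b0 + b1 u_r``
  (b1 < 1 means inflation of the early proofs)
* bias       ``mu_cr   = mean(u_r) - mean(u_c)`` (expectation 0 when
  unbiased)

The square root in the accuracy follows the LR literature's definition of
accuracy as a correlation; the ratio itself is flagged in the metadata and
can be reported instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree


class ValidationError(ValueError):
    pass


@dataclass
class ValidationSplit:
    """Validation cohort and the reduced phenotype table."""

    validation_ids: np.ndarray
    reduced: pd.DataFrame
    complete: pd.DataFrame
    removed_records: dict[str, int] = field(default_factory=dict)


def make_split(phen: pd.DataFrame, ped: Pedigree, genotyped: np.ndarray,
               trait_names: list[str],
               birth_gen: int | None = None) -> ValidationSplit:
    """Build the reduced dataset for LR validation.

    The validation set is the genotyped animals born in the configured
    window (default: the latest birth period among genotyped animals with
    records).  Their records are removed per trait, together with all
    records sharing a contemporary group with a validation record.
    """
    if ped.birth_gen is None:
        raise ValidationError("pedigree has no birth periods")
    genotyped = np.asarray(genotyped, dtype=np.int64)
    in_phen = phen["animal"].isin(genotyped).to_numpy()
    if birth_gen is None:
        cand = phen.loc[in_phen, "animal"].to_numpy()
        if cand.size == 0:
            raise ValidationError("no genotyped animals with records")
        birth_gen = int(ped.birth_gen[cand].max())
    val_mask = in_phen & (ped.birth_gen[phen["animal"].to_numpy()] == birth_gen)
    validation = phen.loc[val_mask, "animal"].to_numpy()
    if validation.size == 0:
        raise ValidationError("empty validation set for the birth window")
    reduced = phen.copy()
    removed = {}
    for t in trait_names:
        y, cg = f"y_{t}", f"cg_{t}"
        obs = reduced[y].notna()
        val_cgs = set(reduced.loc[val_mask & obs.to_numpy(), cg])
        drop = obs.to_numpy() & (val_mask
                                 | reduced[cg].isin(val_cgs).to_numpy())
        reduced.loc[drop, y] = np.nan
        removed[t] = int(drop.sum())
    return ValidationSplit(validation_ids=validation, reduced=reduced,
                           complete=phen, removed_records=removed)


@dataclass
class LRStatistics:
    accuracy: float
    stability: float
    slope: float
    slope_se: float
    bias: float
    bias_se: float
    accuracy_ratio: float       # the unrooted ratio, for reference
    n: int

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "stability": self.stability,
                "slope": self.slope, "slope_se": self.slope_se,
                "bias": self.bias, "bias_se": self.bias_se, "n": self.n}


def lr_statistics(u_complete: np.ndarray, u_reduced: np.ndarray,
                  f_bar: float, sigma2_u: float) -> LRStatistics:
    """The four LR estimators over one validation cohort.

    ``f_bar`` is the cohort's mean inbreeding (on the metafounder scale for
    MF models, with the correspondingly scaled ``sigma2_u``).
    """
    uc = np.asarray(u_complete, dtype=float)
    ur = np.asarray(u_reduced, dtype=float)
    if uc.shape != ur.shape:
        raise ValidationError("complete/reduced vectors differ in length")
    n = uc.size
    if n < 3:
        raise ValidationError("validation cohort too small")
    if sigma2_u <= 0:
        raise ValidationError("sigma2_u must be positive")
    var_r = ur.var(ddof=1)
    if var_r == 0:
        raise ValidationError("reduced predictions have zero variance: "
                              "slope undefined")
    cov = float(np.cov(uc, ur, ddof=1)[0, 1])
    ratio = cov / ((1.0 - f_bar) * sigma2_u)
    accuracy = float(np.sqrt(max(0.0, ratio)))
    stability = float(np.corrcoef(uc, ur)[0, 1])
    b1 = cov / var_r
    resid = uc - uc.mean() - b1 * (ur - ur.mean())
    s2 = float(resid @ resid) / (n - 2)
    slope_se = float(np.sqrt(s2 / ((n - 1) * var_r)))
    bias = float(ur.mean() - uc.mean())
    d = ur - uc
    bias_se = float(d.std(ddof=1) / np.sqrt(n))
    return LRStatistics(accuracy=accuracy, stability=stability,
                        slope=float(b1), slope_se=slope_se, bias=bias,
                        bias_se=bias_se, accuracy_ratio=float(ratio), n=n)


def model_correlations(gebvs: dict[str, np.ndarray],
                       validation_ids: np.ndarray | None = None,
                       ) -> pd.DataFrame:
    """Pairwise Pearson correlations between (G)EBV vectors of models.

    Returns a long-format table; a constant vector yields NaN against all
    others.
    """
    names = list(gebvs)
    vecs = {}
    for m in names:
        v = np.asarray(gebvs[m], dtype=float)
        vecs[m] = v if validation_ids is None else v[validation_ids]
    rows = []
    for i, a in enumerate(names):
        for b in names[i:]:
            va, vb = vecs[a], vecs[b]
            if va.std() == 0 or vb.std() == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(va, vb)[0, 1])
            rows.append({"model_a": a, "model_b": b, "correlation": r})
    return pd.DataFrame(rows)


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long-format correlations to a symmetric matrix."""
    names = sorted(set(table["model_a"]) | set(table["model_b"]))
    M = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for _, r in table.iterrows():
        M.loc[r["model_a"], r["model_b"]] = r["correlation"]
        M.loc[r["model_b"], r["model_a"]] = r["correlation"]
    return M
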