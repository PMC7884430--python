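"""Replicate-ensemble covariance auto-validation of fitted lnP models.

Without ground truth, the only handle on a fit's trustworthiness is the
consistency of independent replicate solutions.  Each pair of replicate lnP
vectors is scored by its Pearson correlation R_ij = C_ij / sqrt(C_ii C_jj);
the arithmetic mean of the full m x m matrix is the R-hat-matrix score.  On
simulated data the analogous mean correlation of each replicate against the
known lnP profile (R-hat-reference) is available, and the two track each
other closely -- which is what makes R-hat-matrix a usable proxy for
accuracy on real data.

Per-residue diagnostics come from leave-one-out: dR-hat(r) = R-hat(all) -
R-hat(without r).  Omitting an accurately fitted residue lowers replicate
agreement (positive dR-hat); omitting an outlier raises it (negative
dR-hat).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .forward_model import ProtectionVector
from .hx_io import ValidationError
from .optimizer import ReplicateEnsemble

__all__ = [
    "ValidationMatrix",
    "ResidueValidation",
    "ValidationReport",
    "ReferenceEvaluation",
    "pairwise_r",
    "r_hat_reference",
    "delta_r_matrix",
    "classify",
    "residue_histograms",
    "evaluate_against_reference",
]

log = logging.getLogger(__name__)

BIN_HIGH = 0.7   # R-hat above this: high expected accuracy
BIN_FAIR = 0.5   # [0.5, 0.7]: fair; below 0.5: low


@dataclass
class ValidationMatrix:
    """Pairwise replicate correlation matrix and its mean (R-hat-matrix)."""

    matrix: np.ndarray
    r_hat: float
    include_diagonal: bool = True
    n_missing: int = 0


@dataclass
class ResidueValidation:
    """Per-residue leave-one-out scores and replicate lnP histograms."""

    delta_r: dict[int, float]
    histograms: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


@dataclass
class ValidationReport:
    """Bundle of everything the auto-validation stage produces."""

    matrix: ValidationMatrix
    classification: str
    delta_r: dict[int, float]
    histograms: dict[int, tuple[np.ndarray, np.ndarray]]
    collapse: dict[int, bool]
    advisory: str | None = None


def _lnp_matrix(
    ensemble: ReplicateEnsemble | np.ndarray,
    residues: Sequence[int] | None = None,
) -> np.ndarray:
    """For an ensemble, ``residues`` selects a subset of its columns; for a
    raw matrix it only labels the columns (and must cover them all)."""
    if isinstance(ensemble, ReplicateEnsemble):
        lnp = ensemble.lnp
        if residues is not None:
            idx = [ensemble.residues.index(r) for r in residues]
            lnp = lnp[:, idx]
    else:
        lnp = np.atleast_2d(np.asarray(ensemble, dtype=float))
        if residues is not None and len(residues) != lnp.shape[1]:
            raise ValidationError(
                "residue labels must match the matrix column count"
            )
    return lnp


def pairwise_r(
    ensemble: ReplicateEnsemble | np.ndarray,
    residues: Sequence[int] | None = None,
    include_diagonal: bool = True,
) -> ValidationMatrix:
    """Pearson correlation between every replicate pair's lnP vectors.

    ``residues`` optionally restricts the evaluation to a subset (the
    standalone R-evaluator behaviour).  R-hat-matrix is the arithmetic mean
    of all m^2 entries; with ``include_diagonal=False`` the m unit diagonal
    entries are left out.  Replicates with zero variance across residues
    yield undefined correlations; those entries are recorded as NaN and
    excluded from the mean with a warning.
    """
    lnp = _lnp_matrix(ensemble, residues)
    m, n = lnp.shape
    if m < 2:
        raise ValidationError("pairwise correlation needs >= 2 replicates")
    if n < 2:
        raise ValidationError("pairwise correlation needs >= 2 residues")
    sd = lnp.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(lnp)
    mat = (mat + mat.T) / 2.0  # exact symmetry (corrcoef divides sequentially)
    np.clip(mat, -1.0, 1.0, out=mat)
    mat[degenerate, :] = np.nan
    mat[:, degenerate] = np.nan
    valid = ~degenerate
    diag = np.diag_indices(m)
    mat[diag] = np.where(valid, 1.0, np.nan)
    n_missing = int(np.isnan(mat).sum())
    if n_missing:
        log.warning(
            "%d replicate(s) have zero lnP variance; %d matrix entries "
            "excluded from R-hat", int(degenerate.sum()), n_missing,
        )
    if not include_diagonal:
        work = mat.copy()
        work[diag] = np.nan
        r_hat = float(np.nanmean(work))
    else:
        r_hat = float(np.nanmean(mat))
    return ValidationMatrix(
        matrix=mat, r_hat=r_hat,
        include_diagonal=include_diagonal, n_missing=n_missing,
    )


def r_hat_reference(
    ensemble: ReplicateEnsemble | np.ndarray,
    reference: ProtectionVector | np.ndarray,
    residues: Sequence[int] | None = None,
) -> float:
    """Mean Pearson correlation of each replicate with the reference lnP.

    Only meaningful for simulation studies where the true profile is known.
    """
    lnp = _lnp_matrix(ensemble, residues)
    if isinstance(reference, ProtectionVector):
        res = (
            residues
            if residues is not None
            else (ensemble.residues if isinstance(ensemble, ReplicateEnsemble) else None)
        )
        if res is None:
            raise ValidationError("residue ordering required to align the reference")
        ref = np.array([reference[r] for r in res], dtype=float)
    else:
        ref = np.asarray(reference, dtype=float)
    if ref.shape != (lnp.shape[1],):
        raise ValidationError("reference length must match residue count")
    if ref.std() == 0:
        raise ValidationError("reference profile has zero variance")
    sd = lnp.std(axis=1)
    valid = sd > 0
    if not valid.any():
        raise ValidationError("all replicates have zero lnP variance")
    if not valid.all():
        log.warning("%d replicate(s) excluded from R-hat-reference", int((~valid).sum()))
    centred = lnp[valid] - lnp[valid].mean(axis=1, keepdims=True)
    ref_c = ref - ref.mean()
    rs = (centred @ ref_c) / (
        np.sqrt((centred * centred).sum(axis=1)) * np.sqrt((ref_c * ref_c).sum())
    )
    return float(rs.mean())


def delta_r_matrix(
    ensemble: ReplicateEnsemble | np.ndarray,
    residues: Sequence[int] | None = None,
    include_diagonal: bool = True,
) -> ResidueValidation:
    """Leave-one-out change in R-hat-matrix for every residue.

    dR-hat(r) = R-hat(all residues) - R-hat(all residues except r);
    positive values mark residues whose presence supports replicate
    agreement (accurate), negative values mark likely outliers.
    """
    lnp = _lnp_matrix(ensemble, residues)
    if residues is None:
        residues = (
            ensemble.residues
            if isinstance(ensemble, ReplicateEnsemble)
            else tuple(range(lnp.shape[1]))
        )
    n = lnp.shape[1]
    if n < 3:
        raise ValidationError(
            "leave-one-out dR-hat needs >= 3 residues (omission must leave >= 2)"
        )
    full = pairwise_r(lnp, include_diagonal=include_diagonal).r_hat
    delta: dict[int, float] = {}
    for j, r in enumerate(residues):
        sub = np.delete(lnp, j, axis=1)
        delta[r] = full - pairwise_r(sub, include_diagonal=include_diagonal).r_hat
    return ResidueValidation(delta_r=delta)


def classify(r_hat: float) -> str:
    """Accuracy bin for an R-hat-matrix score: high (>0.7), fair (0.5-0.7),
    low (<0.5).  Exactly 0.7 falls in ``fair`` (the open-interval reading)."""
    if not (-1.0 - 1e-12 <= r_hat <= 1.0 + 1e-12):
        raise ValidationError(f"R-hat {r_hat} outside [-1, 1]")
    if r_hat > BIN_HIGH:
        return "high"
    if r_hat >= BIN_FAIR:
        return "fair"
    return "low"


def residue_histograms(
    ensemble: ReplicateEnsemble | np.ndarray,
    bin_width: float = 1.0,
    residues: Sequence[int] | None = None,
) -> ResidueValidation:
    """Per-residue histograms of replicate lnP with bins on integer-aligned
    edges (width 1 lnP by default).  Counts per residue sum to the replicate
    count."""
    lnp = _lnp_matrix(ensemble, residues)
    if residues is None:
        residues = (
            ensemble.residues
            if isinstance(ensemble, ReplicateEnsemble)
            else tuple(range(lnp.shape[1]))
        )
    hists: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for j, r in enumerate(residues):
        v = lnp[:, j]
        lo = np.floor(v.min() / bin_width) * bin_width
        hi = np.ceil(v.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        counts, edges = np.histogram(v, bins=edges)
        hists[r] = (counts, edges)
    return ResidueValidation(delta_r={}, histograms=hists)


@dataclass
class ReferenceEvaluation:
    """Residue-level scoring of an ensemble against known lnP."""

    rmse: dict[int, float]          # per-residue RMSE of replicate lnP vs truth
    median_error: dict[int, float]  # median lnP - truth
    delta_r: dict[int, float]
    roc_auc: float | None           # RMSE as classifier of sign(dR-hat)
    enrichment_within_1: float | None  # % excess of |err|<1 in positive pool
    outlier_excess_gt_2: float | None  # negative pool |err|>2 rate as % of positive

    def pooled(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        res = sorted(self.rmse)
        return (
            np.array([self.rmse[r] for r in res]),
            np.array([self.median_error[r] for r in res]),
            np.array([self.delta_r[r] for r in res]),
        )


def _enrichments(
    median_err: np.ndarray, delta: np.ndarray
) -> tuple[float | None, float | None]:
    pos = delta > 0
    neg = delta < 0
    if pos.sum() == 0 or neg.sum() == 0:
        return None, None
    acc_pos = np.mean(np.abs(median_err[pos]) < 1.0)
    acc_neg = np.mean(np.abs(median_err[neg]) < 1.0)
    enrich = None if acc_neg == 0 else 100.0 * (acc_pos / acc_neg - 1.0)
    out_pos = np.mean(np.abs(median_err[pos]) > 2.0)
    out_neg = np.mean(np.abs(median_err[neg]) > 2.0)
    excess = None if out_pos == 0 else 100.0 * (out_neg / out_pos)
    return enrich, excess


def evaluate_against_reference(
    ensemble: ReplicateEnsemble,
    reference: ProtectionVector | Mapping[int, float],
    include_diagonal: bool = True,
) -> ReferenceEvaluation:
    """Score an ensemble against the known lnP profile (simulation studies).

    Computes per-residue RMSE of replicate lnP vs truth and the median
    error, the leave-one-out dR-hat of each residue, the ROC AUC of RMSE as
    a classifier of sign(dR-hat), and the accuracy/outlier enrichment of the
    positive vs negative dR-hat pools.  With only one dR-hat sign present
    the AUC and enrichments are reported as missing (None).
    """
    from sklearn.metrics import roc_auc_score

    ref_map = reference.as_dict() if isinstance(reference, ProtectionVector) else dict(reference)
    res = ensemble.residues
    truth = np.array([ref_map[r] for r in res], dtype=float)
    err = ensemble.lnp - truth[None, :]
    rmse = np.sqrt(np.mean(err * err, axis=0))
    med_err = np.median(ensemble.lnp, axis=0) - truth
    delta = delta_r_matrix(ensemble, include_diagonal=include_diagonal).delta_r
    delta_v = np.array([delta[r] for r in res])

    labels = (delta_v < 0).astype(int)  # positive class: suspected outlier
    if labels.min() == labels.max():
        auc = None
    else:
        auc = float(roc_auc_score(labels, rmse))
    enrich, excess = _enrichments(med_err, delta_v)
    return ReferenceEvaluation(
        rmse={r: float(v) for r, v in zip(res, rmse)},
        median_error={r: float(v) for r, v in zip(res, med_err)},
        delta_r={r: float(delta[r]) for r in res},
        roc_auc=auc,
        enrichment_within_1=enrich,
        outlier_excess_gt_2=excess,
    )
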