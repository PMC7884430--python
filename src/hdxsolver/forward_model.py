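"""Deterministic exchange physics: residue rates -> peptide uptake.

A residue exchanging with first-order rate k_obs (min^-1) carries deuterium
fraction 1 - exp(-k_obs * t) after labelling time t.  A peptide's relative
fractional uptake (RFU) is the arithmetic mean of those per-residue uptakes
over its exchange-competent residues (everything except prolines and the
back-exchanging N-terminal residue).  Protection is quantified as
PF = k_ch / k_obs, reported throughout as lnP = ln(k_ch) - ln(k_obs).

Exponentials are evaluated with expm1 so uptake near zero (strongly
protected residues at short times) stays well resolved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .hx_io import Dataset, HDXError, IntrinsicRateTable, Peptide

__all__ = [
    "ResidueProfile",
    "RateVector",
    "ProtectionVector",
    "PeptideSystem",
    "peptide_rfu",
    "model_rfu_table",
    "lnp_from_kobs",
    "kobs_from_lnp",
]

KOBS_LOWER_BOUND = 1e-18  # min^-1; weak lower bound for extreme protection


@dataclass(frozen=True)
class ResidueProfile:
    """An ordered residue -> value mapping (rates or lnP)."""

    residues: tuple[int, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float)
        )
        if len(self.residues) != len(self.values):
            raise ValueError("residues and values length mismatch")

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.residues, self.values.tolist()))

    def __getitem__(self, residue: int) -> float:
        try:
            return float(self.values[self.residues.index(residue)])
        except ValueError as exc:
            raise KeyError(residue) from exc

    def subset(self, residues: Sequence[int]) -> "ResidueProfile":
        idx = [self.residues.index(r) for r in residues]
        return ResidueProfile(tuple(residues), self.values[idx])


# Semantic aliases: k_obs in min^-1 vs dimensionless lnP.
RateVector = ResidueProfile
ProtectionVector = ResidueProfile


def _rates_for(
    rates: Mapping[int, float] | ResidueProfile, residues: Sequence[int]
) -> np.ndarray:
    if isinstance(rates, ResidueProfile):
        rates = rates.as_dict()
    try:
        return np.array([rates[r] for r in residues], dtype=float)
    except KeyError as exc:
        raise HDXError(f"no rate supplied for residue {exc.args[0]}") from exc


def peptide_rfu(
    rates: Mapping[int, float] | ResidueProfile,
    peptide: Peptide,
    t: float | np.ndarray,
    n_term_exclusion: int = 1,
) -> float | np.ndarray:
    """Model RFU of one peptide at time(s) ``t`` (minutes).

    Mean of ``1 - exp(-k_obs * t)`` over the peptide's exchange-competent
    residues.  Raises for peptides with no competent residue.
    """
    comp = peptide.competent_residues(n_term_exclusion)
    if not comp:
        raise HDXError(
            f"peptide {peptide.id} ({peptide.start}-{peptide.end}) has no "
            "exchange-competent residues"
        )
    k = _rates_for(rates, comp)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("labelling time must be non-negative")
    uptake = -np.expm1(-np.multiply.outer(k, t_arr))
    out = uptake.mean(axis=0)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def model_rfu_table(
    rates: Mapping[int, float] | ResidueProfile, dataset: Dataset
) -> np.ndarray:
    """Peptide x timepoint model-RFU matrix for a whole dataset."""
    t = np.asarray(dataset.timepoints, dtype=float)
    return np.vstack(
        [peptide_rfu(rates, p, t, dataset.n_term_exclusion) for p in dataset.peptides]
    )


def lnp_from_kobs(
    kobs: RateVector, kch: IntrinsicRateTable
) -> ProtectionVector:
    """lnP = ln(k_ch) - ln(k_obs) per residue (exact log-ratio transform)."""
    if np.any(kobs.values <= 0):
        raise HDXError("k_obs must be positive to form lnP")
    kch_v = np.array([kch.rate(r) for r in kobs.residues], dtype=float)
    if np.any(~np.isfinite(kch_v)) or np.any(kch_v <= 0):
        raise HDXError("k_ch missing or non-positive for a requested residue")
    return ProtectionVector(kobs.residues, np.log(kch_v) - np.log(kobs.values))


def kobs_from_lnp(
    lnp: ProtectionVector, kch: IntrinsicRateTable
) -> RateVector:
    """Inverse of :func:`lnp_from_kobs`: k_obs = k_ch * exp(-lnP)."""
    kch_v = np.array([kch.rate(r) for r in lnp.residues], dtype=float)
    if np.any(~np.isfinite(kch_v)) or np.any(kch_v <= 0):
        raise HDXError("k_ch missing or non-positive for a requested residue")
    return RateVector(lnp.residues, kch_v * np.exp(-lnp.values))


class PeptideSystem:
    """Vectorised forward model and misfit for one dataset.

    Precomputes the peptide/residue membership weights so that model RFU,
    the mean-squared-error objective and its gradient are single matrix
    expressions in the k_obs vector (ordered as ``dataset.competent_residues``).
    """

    def __init__(self, dataset: Dataset):
        self.dataset = dataset
        self.residues: tuple[int, ...] = dataset.competent_residues
        if not self.residues:
            raise HDXError("dataset has no exchange-competent residues")
        index = {r: j for j, r in enumerate(self.residues)}
        n_pep = len(dataset.peptides)
        self.t = np.asarray(dataset.timepoints, dtype=float)
        self.weights = np.zeros((n_pep, len(self.residues)))
        for i, p in enumerate(dataset.peptides):
            comp = dataset.peptide_competent(p)
            if not comp:
                raise HDXError(
                    f"peptide {p.id} ({p.start}-{p.end}) has no "
                    "exchange-competent residues"
                )
            for r in comp:
                self.weights[i, index[r]] = 1.0 / len(comp)
        self.exp_rfu = np.asarray([p.rfu for p in dataset.peptides], dtype=float)
        self._n_obs = self.exp_rfu.size

    def rfu(self, kobs: np.ndarray) -> np.ndarray:
        """Model peptide x timepoint RFU for a competent-residue rate vector."""
        uptake = -np.expm1(-np.outer(kobs, self.t))  # residue x time
        return self.weights @ uptake

    def mse(self, kobs: np.ndarray) -> float:
        resid = self.rfu(kobs) - self.exp_rfu
        return float(np.sum(resid * resid) / self._n_obs)

    def mse_grad(self, kobs: np.ndarray) -> np.ndarray:
        """Analytic gradient of :meth:`mse` with respect to each k_obs."""
        decay = np.exp(-np.outer(kobs, self.t))          # residue x time
        resid = self.weights @ (1.0 - decay) - self.exp_rfu  # peptide x time
        back = self.weights.T @ resid                    # residue x time
        return (2.0 / self._n_obs) * np.sum(back * decay * self.t, axis=1)
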