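"""Replicated bound-constrained SQP fitting of residue exchange rates.

The engine minimises the mean squared error between model and experimental
peptide RFU over all peptide/timepoint pairs, with one k_obs variable per
exchange-competent residue bounded to [1e-18, k_ch] min^-1.  Each replicate
starts from an independent random initial guess (exponentially distributed
k_obs) and is driven by a managed optimisation loop: sequential quadratic
programming (SLSQP) cycles interleaved with exact single-rate refits and
neighbour rate-swap proposals, which escape the compensation minima this
misfit surface is riddled with.  The replicate ensemble of fitted lnP
vectors is then aggregated -- the median is the recommended central
tendency -- and feeds the covariance auto-validation statistics in
:mod:`hdxsolver.autovalidation`.

Because data rarely pin every residue, different replicates can settle in
different local minima; that dispersion is not a nuisance but the signal the
auto-validation matrix reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import math

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .forward_model import KOBS_LOWER_BOUND, PeptideSystem, ProtectionVector
from .hx_io import Dataset, HDXError, IntrinsicRateTable, ValidationError
from .intrinsic_rates import kch_for_dataset

__all__ = [
    "OptimizerSettings",
    "ReplicateEnsemble",
    "objective_mse",
    "initial_guess",
    "optimize_replicate",
    "run_ensemble",
    "aggregate",
    "flag_collapse",
]

log = logging.getLogger(__name__)

COLLAPSE_IQR = 20.0  # lnP; broad interquartile ranges flag data collapse


@dataclass
class OptimizerSettings:
    """Tunable settings of the replicate SQP engine.

    ``replicates`` defaults to 50 (production); evaluation runs use 10.
    ``tolerance`` is the SQP precision goal, ``init_scale`` the scale
    (min^-1) of the exponential distribution used for initial k_obs.
    """

    replicates: int = 50
    max_iterations: int = 1000
    tolerance: float = 1e-6
    base_seed: int = 0
    init_scale: float = 1.0
    lower_bound: float = KOBS_LOWER_BOUND
    equality_constraint: bool = False   # add h(x) = MSE as an equality constraint
    log_parameterised: bool = False     # optimise ln(k_obs) instead of k_obs
    polish: bool = True                 # coordinate sweeps + swap proposals between SQP cycles
    swap_width: int = 3                 # neighbour distance tried by swap proposals

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValidationError(
                "at least 2 replicates are required (matrix statistics need pairs)"
            )
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")

    def replicate_seed(self, replicate_index: int) -> int:
        return int(self.base_seed) + int(replicate_index)

    def to_dict(self) -> dict:
        return {
            "replicates": self.replicates,
            "max_iterations": self.max_iterations,
            "tolerance": self.tolerance,
            "base_seed": self.base_seed,
            "init_scale": self.init_scale,
            "lower_bound": self.lower_bound,
            "equality_constraint": self.equality_constraint,
            "log_parameterised": self.log_parameterised,
            "polish": self.polish,
            "swap_width": self.swap_width,
        }


@dataclass
class ReplicateEnsemble:
    """Replicate x residue matrices of fitted rates and lnP, plus records."""

    residues: tuple[int, ...]
    lnp: np.ndarray            # replicate x residue
    kobs: np.ndarray           # replicate x residue, min^-1
    kch: np.ndarray            # residue-aligned upper bounds, min^-1
    seeds: tuple[int, ...]
    objective: np.ndarray      # final MSE per replicate
    converged: np.ndarray      # bool per replicate
    settings: OptimizerSettings | None = None

    def __post_init__(self) -> None:
        self.lnp = np.atleast_2d(np.asarray(self.lnp, dtype=float))
        if self.lnp.shape[1] != len(self.residues):
            raise ValidationError("lnp column count must match residues")

    @property
    def n_replicates(self) -> int:
        return int(self.lnp.shape[0])

    def settings_dict(self) -> dict:
        return self.settings.to_dict() if self.settings is not None else {}


def objective_mse(kobs: np.ndarray, dataset: Dataset) -> float:
    """MSE between model and experimental RFU over all peptide/timepoints.

    ``kobs`` is ordered as ``dataset.competent_residues``.
    """
    return PeptideSystem(dataset).mse(np.asarray(kobs, dtype=float))


def initial_guess(
    settings: OptimizerSettings, replicate_index: int, kch: np.ndarray
) -> np.ndarray:
    """Exponentially distributed starting k_obs, clipped into the bounds.

    Deterministic given ``(base_seed, replicate_index)``; each replicate
    gets an independent stream via seed = base_seed + replicate_index.
    """
    rng = np.random.default_rng(settings.replicate_seed(replicate_index))
    kch = np.asarray(kch, dtype=float)
    draw = rng.exponential(scale=settings.init_scale, size=kch.shape)
    # keep strictly interior so no replicate starts pinned to a bound
    return np.clip(draw, settings.lower_bound * 10.0, kch * (1.0 - 1e-9))


def _sqp_step(
    system: PeptideSystem,
    x: np.ndarray,
    kch: np.ndarray,
    settings: OptimizerSettings,
    maxiter: int,
) -> tuple[np.ndarray, int, float, bool]:
    """One SLSQP call; variables are scaled to the unit box u = k_obs / k_ch
    (or ln k_obs with ``log_parameterised``) so the quasi-Newton model is
    well conditioned across rate decades."""
    lb = settings.lower_bound
    constraints: tuple = ()
    if settings.log_parameterised:
        def fun(u: np.ndarray) -> float:
            return system.mse(np.exp(u))

        def jac(u: np.ndarray) -> np.ndarray:
            k = np.exp(u)
            return system.mse_grad(k) * k

        if settings.equality_constraint:
            constraints = ({"type": "eq", "fun": fun, "jac": jac},)
        res = minimize(
            fun, np.log(x), jac=jac, method="SLSQP",
            bounds=[(np.log(lb), np.log(k)) for k in kch],
            constraints=constraints,
            options={"maxiter": maxiter, "ftol": settings.tolerance},
        )
        out = np.exp(res.x)
    else:
        def fun(u: np.ndarray) -> float:
            return system.mse(u * kch)

        def jac(u: np.ndarray) -> np.ndarray:
            return system.mse_grad(u * kch) * kch

        if settings.equality_constraint:
            constraints = ({"type": "eq", "fun": fun, "jac": jac},)
        res = minimize(
            fun, x / kch, jac=jac, method="SLSQP",
            bounds=[(lb / k, 1.0) for k in kch],
            constraints=constraints,
            options={"maxiter": maxiter, "ftol": settings.tolerance},
        )
        out = res.x * kch
    out = np.clip(out, lb, kch)
    return out, max(int(res.nit), 1), float(system.mse(out)), bool(res.success)


def _sweep_pass(
    system: PeptideSystem, x: np.ndarray, kch: np.ndarray, lb: float
) -> tuple[np.ndarray, float]:
    """Exact bounded 1-D refit of each rate in turn (others fixed)."""
    x = x.copy()
    base = system.mse(x)
    for j in range(len(x)):
        def f1(u: float) -> float:
            xx = x.copy()
            xx[j] = math.exp(u)
            return system.mse(xx)

        r = minimize_scalar(
            f1, bounds=(math.log(lb), math.log(kch[j])), method="bounded",
            options={"xatol": 1e-3},
        )
        if r.fun < base:
            x[j] = math.exp(r.x)
            base = float(r.fun)
    return x, base


def _swap_pass(
    system: PeptideSystem, x: np.ndarray, kch: np.ndarray, width: int
) -> tuple[np.ndarray, float]:
    """Try exchanging the rates of nearby residue pairs.

    Residues sharing most of their peptides can settle with swapped rates --
    a local minimum no gradient or single-coordinate move escapes.  A
    feasible swap that lowers the misfit is accepted greedily.
    """
    x = x.copy()
    base = system.mse(x)
    n = len(x)
    for j in range(n):
        for d in range(1, width + 1):
            if j + d >= n:
                break
            if x[j + d] > kch[j] or x[j] > kch[j + d]:
                continue
            xx = x.copy()
            xx[j], xx[j + d] = x[j + d], x[j]
            f = system.mse(xx)
            if f < base:
                x = xx
                base = f
    return x, base


def optimize_replicate(
    dataset: Dataset | PeptideSystem,
    kch: np.ndarray,
    settings: OptimizerSettings,
    replicate_index: int,
) -> tuple[np.ndarray, float, bool]:
    """One managed SQP minimisation from the replicate's random start.

    SLSQP runs are interleaved (when ``settings.polish``) with exact 1-D
    coordinate refits and neighbour rate-swap proposals, all sharing the
    ``max_iterations`` SQP budget; the loop stops once a full cycle improves
    the MSE by less than ``tolerance``.  Returns ``(kobs, final_mse,
    converged)``; failures are flagged, never silently dropped, and the
    returned rates always honour the [lower_bound, k_ch] box.
    """
    system = dataset if isinstance(dataset, PeptideSystem) else PeptideSystem(dataset)
    kch = np.asarray(kch, dtype=float)
    if np.any(kch <= settings.lower_bound):
        raise ValidationError("k_ch at or below the lower k_obs bound")
    x = initial_guess(settings, replicate_index, kch)
    best = x
    best_f = system.mse(x)

    remaining = settings.max_iterations
    prev = np.inf
    converged = False
    while remaining > 0:
        x, nit, fun, ok = _sqp_step(system, x, kch, settings, remaining)
        remaining -= nit
        if fun < best_f:
            best, best_f = x, fun
        if not settings.polish:
            converged = ok
            break
        x, f_sw = _sweep_pass(system, x, kch, settings.lower_bound)
        x, f_cycle = _swap_pass(system, x, kch, settings.swap_width)
        if f_cycle < best_f:
            best, best_f = x, f_cycle
        if prev - f_cycle < settings.tolerance:
            converged = ok
            break
        prev = f_cycle
    return best, float(best_f), bool(converged)


def run_ensemble(
    dataset: Dataset,
    kch: IntrinsicRateTable | np.ndarray,
    settings: OptimizerSettings | None = None,
) -> ReplicateEnsemble:
    """Run the full replicate scheme on one dataset.

    ``kch`` may be an :class:`IntrinsicRateTable` (aligned internally) or a
    vector already ordered as ``dataset.competent_residues``.  Reproducible
    given ``settings.base_seed``.
    """
    settings = settings or OptimizerSettings()
    if not dataset.peptides:
        raise ValidationError("dataset has no peptides")
    system = PeptideSystem(dataset)
    if isinstance(kch, IntrinsicRateTable):
        kch_v = kch_for_dataset(kch, dataset)
    else:
        kch_v = np.asarray(kch, dtype=float)
        if kch_v.shape != (len(system.residues),):
            raise ValidationError("k_ch vector length must match competent residues")

    rows_k, objs, conv, seeds = [], [], [], []
    for i in range(settings.replicates):
        kobs, mse, ok = optimize_replicate(system, kch_v, settings, i)
        rows_k.append(kobs)
        objs.append(mse)
        conv.append(ok)
        seeds.append(settings.replicate_seed(i))
        if not ok:
            log.warning("replicate %d did not converge (MSE %.3g)", i, mse)
    conv_arr = np.asarray(conv, dtype=bool)
    if not conv_arr.any():
        raise HDXError(
            "no replicate converged; inspect the input data (coverage, RFU "
            "plausibility, timepoint span) before refitting"
        )
    kobs_mat = np.vstack(rows_k)
    lnp_mat = np.log(kch_v)[None, :] - np.log(kobs_mat)
    return ReplicateEnsemble(
        residues=system.residues,
        lnp=lnp_mat,
        kobs=kobs_mat,
        kch=kch_v,
        seeds=tuple(seeds),
        objective=np.asarray(objs, dtype=float),
        converged=conv_arr,
        settings=settings,
    )


def _kmeans_centre(values: np.ndarray, seed: int = 0) -> float:
    """Centroid of the dominant cluster of a 2-means split of one residue."""
    from sklearn.cluster import KMeans

    if np.ptp(values) == 0:
        return float(values[0])
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(values.reshape(-1, 1))
    dominant = np.argmax(np.bincount(labels))
    return float(km.cluster_centers_[dominant, 0])


def aggregate(
    ensemble: ReplicateEnsemble,
    method: Literal["median", "mean", "kmeans"] = "median",
) -> tuple[ProtectionVector, np.ndarray]:
    """Aggregate replicate lnP into a final model plus per-residue IQR.

    The median is the recommended (default) central tendency; ``kmeans``
    clusters each residue's replicate values (k = 2) and reports the
    centroid of the most populated cluster.
    """
    if ensemble.n_replicates < 2:
        raise ValidationError("aggregation needs >= 2 replicates")
    lnp = ensemble.lnp
    if method == "median":
        centre = np.median(lnp, axis=0)
    elif method == "mean":
        centre = lnp.mean(axis=0)
    elif method == "kmeans":
        centre = np.array([_kmeans_centre(lnp[:, j]) for j in range(lnp.shape[1])])
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    q75, q25 = np.percentile(lnp, [75, 25], axis=0)
    return ProtectionVector(ensemble.residues, centre), q75 - q25


def flag_collapse(
    ensemble: ReplicateEnsemble, threshold: float = COLLAPSE_IQR
) -> dict[int, bool]:
    """Flag residues whose replicate lnP IQR reaches ``threshold`` (inclusive).

    Exceptionally broad interquartile ranges (20-30 lnP) indicate data
    collapse: the fit drifting to the weak lower k_obs bound, typically from
    insufficient long-timepoint sampling.
    """
    q75, q25 = np.percentile(ensemble.lnp, [75, 25], axis=0)
    iqr = q75 - q25
    return {r: bool(iqr[j] >= threshold) for j, r in enumerate(ensemble.residues)}
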