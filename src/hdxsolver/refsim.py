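"""Synthetic reference HDX-MS data with known ground-truth protection.

The generator reproduces the kind of benchmark library the method was
developed on: a ground-truth lnP profile with realistic spatial structure,
a peptide map of controlled redundancy, and peptide RFU projected from the
truth at the standard 7 labelling timepoints (0.25-480 min).  Because the
truth is known for every residue, replicate fits can be scored exactly --
something no experimental dataset permits.

Noise-free RFU is the default: the point of the reference library is an
unambiguous benchmark under accepted exchange kinetics, not an instrument
model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .coverage import filter_by_occupancy, find_subsections
from .forward_model import ProtectionVector, kobs_from_lnp, peptide_rfu
from .hx_io import Dataset, IntrinsicRateTable, Peptide, ValidationError
from .intrinsic_rates import compute_kch

__all__ = [
    "PAPER_TIMEPOINTS",
    "ReferenceSet",
    "random_sequence",
    "simulate_lnp",
    "simulate_map",
    "project_rfu",
    "variant_lnp",
    "build_library",
]

log = logging.getLogger(__name__)

#: Standard labelling schedule, minutes.
PAPER_TIMEPOINTS: tuple[float, ...] = (0.25, 1.0, 5.0, 20.0, 60.0, 240.0, 480.0)

#: Simulation conditions for sequence-derived intrinsic rates.
DEFAULT_PD = 7.0
DEFAULT_TEMPERATURE = 293.0
PROLINE_FRACTION = 0.04


@dataclass
class ReferenceSet:
    """A simulated dataset bundled with its generating truth."""

    dataset: Dataset
    truth: ProtectionVector          # over all non-proline residues >= 2
    kch: IntrinsicRateTable
    provenance: dict = field(default_factory=dict)

    def truth_for(self, residues: Sequence[int]) -> np.ndarray:
        m = self.truth.as_dict()
        return np.array([m[r] for r in residues], dtype=float)


def random_sequence(
    n_residues: int, seed: int | np.random.Generator = 0,
    proline_fraction: float = PROLINE_FRACTION,
) -> str:
    """Random protein sequence with a small proline admixture.

    Position 1 and 2 are never proline so that the chain always has at
    least one well-defined leading amide environment.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    non_pro = list("ACDEFGHIKLMNQRSTVWY")
    seq = []
    for i in range(n_residues):
        if i >= 2 and rng.random() < proline_fraction:
            seq.append("P")
        else:
            seq.append(non_pro[rng.integers(len(non_pro))])
    return "".join(seq)


def simulate_lnp(
    n_residues: int,
    mode: Literal["smooth-random", "two-term"] = "smooth-random",
    *,
    lnp_range: tuple[float, float] = (0.0, 14.0),
    window: int = 7,
    contacts: Sequence[float] | None = None,
    hbonds: Sequence[float] | None = None,
    beta_c: float = 0.35,
    beta_h: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> ProtectionVector:
    """Ground-truth lnP profile over residues 1..n_residues.

    ``smooth-random`` draws a moving-average-smoothed random field rescaled
    to ``lnp_range`` -- spatially correlated, as protection along real
    chains is.  ``two-term`` evaluates the standard phenomenological
    expression lnP_i = beta_c * N_c(i) + beta_h * N_h(i) from per-residue
    heavy-atom contact and hydrogen-bond counts supplied by the caller.
    """
    if n_residues < 2:
        raise ValidationError("need at least 2 residues")
    residues = tuple(range(1, n_residues + 1))
    if mode == "two-term":
        if contacts is None or hbonds is None:
            raise ValidationError("two-term mode requires contact and H-bond counts")
        nc = np.asarray(contacts, dtype=float)
        nh = np.asarray(hbonds, dtype=float)
        if nc.shape != (n_residues,) or nh.shape != (n_residues,):
            raise ValidationError("counts must have one value per residue")
        return ProtectionVector(residues, beta_c * nc + beta_h * nh)
    if mode != "smooth-random":
        raise ValueError(f"unknown lnP simulation mode {mode!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    raw = rng.uniform(0.0, 1.0, size=n_residues + window - 1)
    kernel = np.ones(window) / window
    smooth = np.convolve(raw, kernel, mode="valid")
    lo, hi = lnp_range
    if hi < lo:
        raise ValidationError("lnp_range must be (low, high)")
    span = smooth.max() - smooth.min()
    if span == 0:
        values = np.full(n_residues, (lo + hi) / 2.0)
    else:
        values = lo + (hi - lo) * (smooth - smooth.min()) / span
    return ProtectionVector(residues, values)


def simulate_map(
    n_residues: int,
    peptide_length_range: tuple[int, int] = (5, 15),
    target_redundancy: float = 3.0,
    seed: int | np.random.Generator = 0,
    layout: Literal["random", "dense"] = "random",
) -> list[tuple[int, int]]:
    """Random peptide tiling with full coverage and controlled redundancy.

    Realised mean redundancy (total covered residue-instances / n) lands
    within 20% of ``target_redundancy``.  Raises for infeasible parameters.

    ``layout="dense"`` instead places one random-length peptide starting at
    every residue (redundancy equals the mean peptide length and
    ``target_redundancy`` is ignored).  Dense maps maximise terminus
    diversity -- nearly every residue pair is separated by some peptide
    boundary -- which is what makes a map informative at single-residue
    level; they emulate the best experimental digests.
    """
    lmin, lmax = peptide_length_range
    if lmin < 2 or lmax < lmin:
        raise ValidationError("peptide lengths must satisfy 2 <= min <= max")
    if lmin > n_residues:
        raise ValidationError("peptides longer than the protein")
    if target_redundancy < 1:
        raise ValidationError("target redundancy must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    if layout == "dense":
        spans_d: list[tuple[int, int]] = []
        for start in range(1, n_residues - lmin + 2):
            length = int(rng.integers(lmin, lmax + 1))
            span = (start, min(start + length - 1, n_residues))
            if span not in spans_d:
                spans_d.append(span)
        return sorted(spans_d)
    if layout != "random":
        raise ValueError(f"unknown map layout {layout!r}")

    spans: list[tuple[int, int]] = []

    def realised() -> float:
        return sum(e - s + 1 for s, e in spans) / n_residues

    # Coverage pass: overlapping walk left to right.
    pos = 1
    while pos <= n_residues:
        length = int(rng.integers(lmin, lmax + 1))
        start = pos
        if start + length - 1 > n_residues:
            start = max(1, n_residues - length + 1)
            length = min(length, n_residues - start + 1)
        spans.append((start, start + length - 1))
        if start + length - 1 >= n_residues:
            break
        # keep the walk's own redundancy (~ length / step) below target so
        # low-redundancy maps stay feasible
        max_overlap = min(length - 2, int(length - length / target_redundancy))
        overlap = int(rng.integers(1, max(2, max_overlap + 1)))
        pos = start + length - overlap
        if pos <= start:  # always advance
            pos = start + 1

    spans = sorted(set(spans))

    # Top-up passes: random peptides until the redundancy target is met,
    # shortening the final additions so the target is not overshot.
    stall = 0
    while realised() < target_redundancy and stall < 10_000:
        budget = (target_redundancy * 1.1 - realised()) * n_residues
        length = int(rng.integers(lmin, lmax + 1))
        if length > budget and budget >= lmin:
            length = int(budget)
        length = min(length, n_residues)
        start = int(rng.integers(1, n_residues - length + 2))
        span = (start, start + length - 1)
        if span not in spans:
            spans.append(span)
        else:
            stall += 1

    if abs(realised() - target_redundancy) > 0.2 * target_redundancy:
        raise ValidationError(
            f"could not realise redundancy {target_redundancy:g} "
            f"(got {realised():.2f}) with lengths {peptide_length_range}"
        )
    return sorted(spans)


def project_rfu(
    truth: ProtectionVector,
    kch: IntrinsicRateTable,
    peptide_map: Sequence[tuple[int, int]],
    timepoints: Sequence[float] = PAPER_TIMEPOINTS,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    protein_id: str = "sim",
    provenance: dict | None = None,
) -> ReferenceSet:
    """Project ground-truth lnP onto a peptide map as an RFU dataset.

    k_obs = k_ch * exp(-lnP) per residue, then per-peptide mean uptake at
    each timepoint.  Optional Gaussian noise (sd in RFU units) is truncated
    to [0, 1]; the default is noise-free, in which case the emitted dataset
    reproduces the truth exactly under the forward model.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    aa = {r: kch.entries[r][0] for r in kch.residues}
    exchanging = set(kch.exchanging_residues())
    truth_map = truth.as_dict()
    comp_residues = sorted(set(truth_map) & exchanging)
    kobs = kobs_from_lnp(
        ProtectionVector(tuple(comp_residues),
                         np.array([truth_map[r] for r in comp_residues])),
        kch,
    )
    rate_map = kobs.as_dict()
    t = np.asarray(timepoints, dtype=float)
    peptides = []
    for pid, (start, end) in enumerate(peptide_map):
        seq = "".join(aa[r] for r in range(start, end + 1))
        pep = Peptide(id=pid, start=start, end=end, sequence=seq,
                      rfu=tuple(0.0 for _ in t))
        rfu = np.asarray(peptide_rfu(rate_map, pep, t), dtype=float)
        if noise_sd > 0:
            rfu = np.clip(rfu + rng.normal(0.0, noise_sd, size=rfu.shape), 0.0, 1.0)
        peptides.append(
            Peptide(id=pid, start=start, end=end, sequence=seq,
                    rfu=tuple(float(v) for v in rfu))
        )
    dataset = Dataset(protein_id=protein_id, timepoints=tuple(t), peptides=peptides)
    return ReferenceSet(
        dataset=dataset,
        truth=truth,
        kch=kch,
        provenance={"noise_sd": noise_sd, "timepoints": tuple(t),
                    **(provenance or {})},
    )


def variant_lnp(
    truth: ProtectionVector,
    kind: Literal["inverted", "randomised"],
    seed: int | np.random.Generator = 0,
) -> ProtectionVector:
    """Control profiles: inverted (max+min-x) or a random permutation."""
    if kind == "inverted":
        v = truth.values
        return ProtectionVector(truth.residues, v.max() + v.min() - v)
    if kind == "randomised":
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        return ProtectionVector(truth.residues, rng.permutation(truth.values))
    raise ValueError(f"unknown variant kind {kind!r}")


#: Grid of generator regimes from well to poorly constrained: short peptides
#: at high redundancy pin residues tightly; long peptides at low redundancy
#: average many residues together and leave the fit underdetermined.
DEFAULT_GRID: tuple[dict, ...] = (
    dict(n_residues=60, peptide_length_range=(5, 10), target_redundancy=6.0,
         lnp_range=(0.0, 10.0)),
    dict(n_residues=50, peptide_length_range=(5, 12), target_redundancy=5.0,
         lnp_range=(0.0, 12.0)),
    dict(n_residues=40, peptide_length_range=(6, 12), target_redundancy=4.5,
         lnp_range=(0.0, 12.0)),
    dict(n_residues=60, peptide_length_range=(8, 16), target_redundancy=4.0,
         lnp_range=(0.0, 12.0)),
    dict(n_residues=70, peptide_length_range=(10, 18), target_redundancy=3.5,
         lnp_range=(0.0, 13.0)),
    dict(n_residues=80, peptide_length_range=(12, 20), target_redundancy=3.0,
         lnp_range=(0.0, 14.0)),
    dict(n_residues=60, peptide_length_range=(14, 22), target_redundancy=3.0,
         lnp_range=(2.0, 14.0)),
    dict(n_residues=50, peptide_length_range=(15, 25), target_redundancy=2.5,
         lnp_range=(2.0, 14.0)),
    dict(n_residues=70, peptide_length_range=(16, 24), target_redundancy=2.5,
         lnp_range=(2.0, 14.0)),
    dict(n_residues=40, peptide_length_range=(10, 20), target_redundancy=2.0,
         lnp_range=(0.0, 14.0)),
    dict(n_residues=60, peptide_length_range=(12, 24), target_redundancy=1.8,
         lnp_range=(2.0, 14.0)),
    dict(n_residues=50, peptide_length_range=(8, 18), target_redundancy=1.5,
         lnp_range=(0.0, 14.0)),
)


def _one_reference(
    params: dict,
    rng: np.random.Generator,
    occupancy_threshold: float,
    kch_mode: str,
    uniform_kch: float,
    index: int,
) -> ReferenceSet | None:
    n = params["n_residues"]
    seq = random_sequence(n, rng)
    truth = simulate_lnp(n, lnp_range=params["lnp_range"], seed=rng)
    if kch_mode == "sequence":
        kch = compute_kch(seq, DEFAULT_PD, DEFAULT_TEMPERATURE)
    else:
        entries = {1: (seq[0], None)}
        for i in range(2, n + 1):
            aa = seq[i - 1]
            entries[i] = (aa, None if aa == "P" else uniform_kch)
        kch = IntrinsicRateTable(entries=entries)
    try:
        spans = simulate_map(
            n, params["peptide_length_range"], params["target_redundancy"], rng,
            layout=params.get("layout", "random"),
        )
    except ValidationError:
        return None
    refset = project_rfu(
        truth, kch, spans,
        seed=rng, protein_id=f"sim{index:02d}",
        provenance={**params, "kch_mode": kch_mode},
    )
    from .coverage import compute_occupancy

    pre_filter = compute_occupancy(refset.dataset)
    occ_by_key = {
        (p.start, p.end): pre_filter.occupancy[p.id]
        for p in refset.dataset.peptides
    }
    kept, _removed = filter_by_occupancy(refset.dataset, occupancy_threshold)
    if not kept.peptides:
        return None
    subs = find_subsections(kept)
    best = None
    for sub in subs:
        if len(sub.peptides) >= 2 and len(sub.competent_residues) >= 4:
            if best is None or len(sub.competent_residues) > len(best.competent_residues):
                best = sub
    if best is None:
        return None
    prov = dict(refset.provenance)
    prov["occupancy_threshold"] = occupancy_threshold
    prov["min_occupancy_at_filter"] = min(
        occ_by_key[(p.start, p.end)] for p in best.peptides
    )
    return ReferenceSet(dataset=best, truth=refset.truth, kch=refset.kch,
                        provenance=prov)


def build_library(
    n_datasets: int = 30,
    grid: Sequence[dict] | None = None,
    seed: int = 0,
    occupancy_threshold: float = 2.5,
    kch_mode: Literal["sequence", "uniform"] = "sequence",
    uniform_kch: float = 100.0,
    max_tries_per_dataset: int = 50,
) -> list[ReferenceSet]:
    """A reference library of independent simulated HDX-MS subsections.

    Cycles through ``grid`` regimes (default spans well to poorly
    constrained), applies the occupancy filter and subsection splitting to
    each generated map, and emits the largest surviving subsection as one
    ReferenceSet.  Regimes whose maps are gutted by the filter are retried
    with fresh spawned seeds, so the library always reaches ``n_datasets``
    members while deliberately retaining weakly constrained ones.
    """
    if n_datasets < 1:
        raise ValidationError("n_datasets must be >= 1")
    grid = tuple(grid) if grid is not None else DEFAULT_GRID
    ss = np.random.SeedSequence(seed)
    out: list[ReferenceSet] = []
    i = 0
    while len(out) < n_datasets:
        params = dict(grid[i % len(grid)])
        made = None
        for _try in range(max_tries_per_dataset):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            made = _one_reference(
                params, rng, occupancy_threshold, kch_mode, uniform_kch, len(out)
            )
            if made is not None:
                break
        if made is None:
            log.warning("skipping infeasible grid entry %r", params)
        else:
            made.provenance["library_index"] = len(out)
            out.append(made)
        i += 1
        if i > 20 * n_datasets:  # safety against a fully infeasible grid
            raise ValidationError("could not assemble the requested library")
    return out
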