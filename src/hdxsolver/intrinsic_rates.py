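"""Intrinsic (chemical) amide exchange rates from sequence, pD, temperature.

For an unstructured backbone amide the observed exchange rate in D2O is the
sum of an acid-, a base- and a water-catalysed term,

    k_ch = k_A * F_A * 10^(-pD)  +  k_B * F_B * 10^(pD - pK_D)  +  k_W * F_W

with each term Arrhenius-scaled from the 293 K poly-DL-alanine reference and
modulated by log-additive near-neighbour side-chain correction factors: the
amide of residue i feels its own side chain ("lambda") and the side chain of
residue i-1 ("rho").  Prolines and the first residue of the chain carry no
amide proton and get no rate; the free N-terminal ammonium perturbs residue
2 and the C-terminal carboxyl perturbs the final residue.

pD is used as given (no internal pH-meter correction is applied).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from . import _rate_tables as T
from .hx_io import AMINO_ACIDS, Dataset, HDXError, IntrinsicRateTable, ValidationError

__all__ = ["compute_kch", "kch_for_dataset"]


def _titrated(prot: float, deprot: float, pka: float, pD: float) -> float:
    """Log-interpolate a correction factor between protonated/deprotonated forms."""
    num = 10.0 ** (prot - pD) + 10.0 ** (deprot - pka)
    den = 10.0 ** (-pD) + 10.0 ** (-pka)
    return math.log10(num / den)


def _factors(aa: str, pD: float) -> tuple[float, float, float, float]:
    """(acid lambda, acid rho, base lambda, base rho) for one side chain."""
    if aa in T.TITRATABLE:
        prot, deprot, pka = T.TITRATABLE[aa]
        return tuple(
            _titrated(p, d, pka, pD) for p, d in zip(prot, deprot)
        )  # type: ignore[return-value]
    lam_a, rho_a, lam_b, rho_b = T.SIDECHAIN[aa]
    return (lam_a if lam_a is not None else 0.0, rho_a,
            lam_b if lam_b is not None else 0.0, rho_b)


def _arrhenius(ea: float, temperature: float) -> float:
    return math.exp(-ea / T.R_GAS * (1.0 / temperature - 1.0 / T.T_REF))


def compute_kch(
    sequence: str, pD: float, temperature: float
) -> IntrinsicRateTable:
    """Per-residue intrinsic exchange rates (min^-1) for ``sequence``.

    ``temperature`` is in kelvin.  Residue numbers are 1-based positions in
    the sequence.  The first residue and prolines are returned as
    non-exchanging (``None`` rate).
    """
    sequence = sequence.strip().upper()
    if not (2.0 <= pD <= 12.0):
        raise ValidationError(f"pD {pD} outside supported range [2, 12]")
    if not (273.0 <= temperature <= 333.0):
        raise ValidationError(
            f"temperature {temperature} K outside supported range [273, 333]"
        )
    for pos, aa in enumerate(sequence, start=1):
        if aa not in AMINO_ACIDS:
            raise ValidationError(f"unknown residue code {aa!r} at position {pos}")
    if len(sequence) < 2:
        raise ValidationError("sequence must contain at least 2 residues")

    fa = _arrhenius(T.EA_ACID, temperature)
    fb = _arrhenius(T.EA_BASE, temperature)
    fw = _arrhenius(T.EA_WATER, temperature)
    ka = 10.0 ** (T.LOG_KA_REF - pD) * fa
    kb = 10.0 ** (T.LOG_KB_REF + pD - T.PKD_WATER) * fb
    kw = 10.0 ** T.LOG_KW_REF * fw

    entries: dict[int, tuple[str, float | None]] = {1: (sequence[0], None)}
    n = len(sequence)
    for i in range(2, n + 1):
        aa = sequence[i - 1]
        if aa == "P":
            entries[i] = (aa, None)
            continue
        lam_a, _, lam_b, _ = _factors(aa, pD)
        _, rho_a, _, rho_b = _factors(sequence[i - 2], pD)
        log_fa = lam_a + rho_a
        log_fb = lam_b + rho_b
        if i == 2:  # neighbour to the free alpha-ammonium
            log_fa += T.NTERM_RHO_ACID
            log_fb += T.NTERM_RHO_BASE
        if i == n:  # own C-terminal carboxyl
            log_fa += _titrated(T.CTERM_LAMBDA_ACID_PROT, 0.0, T.CTERM_PKA, pD)
            log_fb += _titrated(T.CTERM_LAMBDA_BASE_PROT, 0.0, T.CTERM_PKA, pD)
        # The water term carries the base-catalysis correction factors.
        k = ka * 10.0 ** log_fa + (kb + kw) * 10.0 ** log_fb
        entries[i] = (aa, k)
    return IntrinsicRateTable(entries=entries, pD=pD, temperature=temperature)


def kch_for_dataset(
    table: IntrinsicRateTable, dataset: Dataset
) -> np.ndarray:
    """k_ch vector aligned with ``dataset.competent_residues`` ordering.

    Raises if any exchange-competent residue is missing from the table or
    listed there as non-exchanging.
    """
    residues: Sequence[int] = dataset.competent_residues
    missing = [r for r in residues if table.rate(r) is None]
    if missing:
        raise HDXError(
            "missing k_ch for residue"
            + ("s " if len(missing) > 1 else " ")
            + ", ".join(str(r) for r in missing)
        )
    return np.array([table.rate(r) for r in residues], dtype=float)
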