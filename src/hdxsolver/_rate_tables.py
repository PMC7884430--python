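"""Reference constants for intrinsic amide H/D exchange rates.

Transcription of the poly-DL-alanine reference rates and the near-neighbour
side-chain correction factors of Bai, Milne, Mayne & Englander (Proteins
1993, 17, 75-86) as updated by Nguyen, Mayne, Phillips & Englander (JASMS
2018, 29, 1936-1939), for protium protein exchanging into D2O.  Values are
log10 factors; ``LAMBDA`` entries describe the effect of a side chain on its
*own* backbone amide, ``RHO`` entries the effect on the amide of the
*following* residue.

This file is the versioned record of the constant set the package uses.
The poly-alanine arithmetic is verified by hand in the test suite; the
per-side-chain entries are a careful manual transcription of the published
tables and should be diffed against the original publication before any
quantitative use of absolute k_ch values at unusual pD.
"""

from __future__ import annotations

# Reference rates for poly-DL-alanine at 293 K in D2O, log10, per minute:
#   acid/base terms are second order (per molar catalyst), water first order.
LOG_KA_REF = 1.62
LOG_KB_REF = 10.18
LOG_KW_REF = -1.5

# Apparent activation energies, kcal/mol.
EA_ACID = 14.0
EA_BASE = 17.0
EA_WATER = 19.0

T_REF = 293.0  # K
R_GAS = 1.987e-3  # kcal / (mol K)

PKD_WATER = 15.05  # ion product of D2O at the reference temperature

# (acid lambda, acid rho, base lambda, base rho) log10 correction factors.
SIDECHAIN: dict[str, tuple[float | None, float, float | None, float]] = {
    "A": (0.00, 0.00, 0.00, 0.00),
    "C": (-0.54, -0.46, 0.62, 0.55),
    "F": (-0.52, -0.43, -0.24, 0.06),
    "G": (-0.22, 0.22, 0.27, 0.17),
    "I": (-0.91, -0.59, -0.73, -0.23),
    "K": (-0.56, -0.29, -0.04, 0.12),
    "L": (-0.57, -0.13, -0.58, -0.21),
    "M": (-0.64, -0.28, -0.01, 0.11),
    "N": (-0.58, -0.13, 0.49, 0.32),
    # Proline has no backbone amide proton: no lambda entries (trans values).
    "P": (None, -0.19, None, -0.24),
    "Q": (-0.47, -0.27, 0.06, 0.20),
    "R": (-0.59, -0.32, 0.08, 0.22),
    "S": (-0.44, -0.39, 0.37, 0.30),
    "T": (-0.79, -0.47, -0.07, 0.20),
    "V": (-0.74, -0.30, -0.70, -0.14),
    "W": (-0.40, -0.44, -0.41, -0.11),
    "Y": (-0.41, -0.37, -0.27, 0.05),
}

# Titratable side chains: (protonated 4-tuple, deprotonated 4-tuple, pKa in
# D2O).  Effective factors are log-interpolated between the two forms at the
# working pD.
TITRATABLE: dict[str, tuple[tuple[float, float, float, float],
                            tuple[float, float, float, float], float]] = {
    "D": ((0.90, 0.58, -0.30, -0.18), (-0.90, -0.12, 0.69, 0.60), 4.48),
    "E": ((-0.60, -0.27, 0.24, 0.39), (-0.90, 0.31, -0.11, -0.15), 4.93),
    "H": ((-0.80, -0.51, 0.80, 0.83), (0.00, 0.00, -0.10, 0.14), 7.42),
}

# Chain termini.  The free alpha-ammonium of residue 1 perturbs the amide of
# residue 2 (a rho-type effect); the C-terminal carboxyl perturbs the amide
# of the last residue (a lambda-type effect, titrating with ~pKa 4).
NTERM_RHO_ACID = -1.32
NTERM_RHO_BASE = 1.62
CTERM_LAMBDA_ACID_PROT = 0.96
CTERM_LAMBDA_BASE_PROT = -1.80
CTERM_PKA = 4.0
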