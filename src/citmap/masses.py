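"""Monoisotopic mass arithmetic for tryptic peptides and their
citrullination / phenylglyoxal (PGM) modification states, plus a
Henderson-Hasselbalch isoelectric-point calculator.

Citrullination (deimination of arginine by peptidylarginine deiminase)
replaces the guanidinium =NH by =O, a mass change of +0.984016 Da, and
removes the side chain's positive charge.  Phenylglyoxal condenses with the
citrulline ureido group under acidic conditions, adding one C8H6O2 minus
water per citrulline (+116.026215 Da); the combined +117.010 Da shift is
the diagnostic that separates a citrullinated peptide from a plain
missed-cleavage product of the same sequence.

All masses are monoisotopic and in daltons; peptide ions are treated as
singly protonated (MH+), the dominant species in positive-mode MALDI-TOF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

__all__ = [
    "RESIDUE_MASSES",
    "MassConstants",
    "ModificationState",
    "peptide_mh",
    "mod_delta",
    "isoelectric_point",
    "load_config",
    "PKA_SIDECHAIN",
    "PKA_NTERM",
    "PKA_CTERM",
]

#: Monoisotopic residue (amino-acid minus water) masses in Da, 20 standard
#: residues.  Values are the CODATA-derived ones used across proteomics
#: software (unimod / expasy tables).
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}


@dataclass(frozen=True)
class MassConstants:
    """Fixed monoisotopic constants (Da).

    ``delta_cit`` is the Arg -> citrulline deimination shift; ``delta_pgm``
    is the phenylglyoxal condensation adduct per citrulline (C8H6O2 with
    loss of H2O).
    """

    water: float = 18.010565
    proton: float = 1.007276
    delta_cit: float = 0.984016
    delta_pgm: float = 116.026215

    def __post_init__(self) -> None:
        if not (0.984 <= self.delta_cit <= 0.9841):
            raise ValueError(f"delta_cit {self.delta_cit} outside plausible range")
        if not (116.026 <= self.delta_pgm <= 116.027):
            raise ValueError(f"delta_pgm {self.delta_pgm} outside plausible range")
        if not (1.0072 <= self.proton <= 1.0073):
            raise ValueError(f"proton {self.proton} outside plausible range")
        if not (18.0105 <= self.water <= 18.0106):
            raise ValueError(f"water {self.water} outside plausible range")


DEFAULT_CONSTANTS = MassConstants()


@dataclass(frozen=True)
class ModificationState:
    """Citrullination / PGM state of one peptide.

    ``citrullinated_positions`` are 1-based coordinates (chain coordinates
    for peptides cut out of a chain; pass ``start`` to :func:`peptide_mh`
    to anchor them).  When ``pgm_derivatized`` is true the phenylglyoxal
    adduct applies to every citrulline in the peptide; with zero
    citrullines it contributes nothing.
    """

    citrullinated_positions: frozenset[int] = field(default_factory=frozenset)
    pgm_derivatized: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "citrullinated_positions", frozenset(self.citrullinated_positions)
        )

    @property
    def n_cit(self) -> int:
        return len(self.citrullinated_positions)


UNMODIFIED = ModificationState()


def mod_delta(
    n_cit: int, pgm: bool, constants: MassConstants = DEFAULT_CONSTANTS
) -> float:
    """Total mass shift (Da) for ``n_cit`` citrullines, optionally all
    PGM-derivatized.  Exactly linear in ``n_cit``."""
    if n_cit < 0:
        raise ValueError(f"n_cit must be non-negative, got {n_cit}")
    per_site = constants.delta_cit + (constants.delta_pgm if pgm else 0.0)
    return n_cit * per_site


def peptide_mh(
    sequence: str,
    state: ModificationState = UNMODIFIED,
    start: int = 1,
    constants: MassConstants = DEFAULT_CONSTANTS,
    residue_masses: Mapping[str, float] = RESIDUE_MASSES,
) -> float:
    """Singly protonated monoisotopic mass (MH+, Da) of a peptide.

    Parameters
    ----------
    sequence:
        One-letter amino-acid string (the unmodified sequence; citrullines
        are still written as R).
    state:
        Citrullination / PGM state.  Positions are 1-based and interpreted
        relative to ``start`` (so chain coordinates work for peptides cut
        out of a chain, and 1-based peptide-local coordinates are the
        default).
    start:
        Chain coordinate of the first residue of ``sequence``.

    Raises
    ------
    ValueError
        On an empty sequence, an unknown residue symbol, or a
        citrullinated position that does not map to an R in the span.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    total = 0.0
    for symbol in sequence:
        try:
            total += residue_masses[symbol]
        except KeyError:
            raise ValueError(
                f"unknown residue symbol {symbol!r} in sequence {sequence!r}"
            ) from None
    for pos in state.citrullinated_positions:
        idx = pos - start
        if not (0 <= idx < len(sequence)):
            raise ValueError(
                f"citrullinated position {pos} outside peptide span "
                f"{start}-{start + len(sequence) - 1}"
            )
        if sequence[idx] != "R":
            raise ValueError(
                f"citrullinated position {pos} is {sequence[idx]!r}, not R"
            )
    total += mod_delta(state.n_cit, state.pgm_derivatized, constants)
    return total + constants.water + constants.proton


# --- isoelectric point ------------------------------------------------------

# EMBOSS pKa set: a single classical table, used only for orderings (the
# absolute pI of a short peptide is model-dependent; the direction of the
# citrullination shift is not).
PKA_NTERM = 8.6
PKA_CTERM = 3.6
PKA_SIDECHAIN: dict[str, tuple[float, int]] = {
    # residue -> (pKa, charge sign when protonated side is counted)
    "D": (3.9, -1),
    "E": (4.1, -1),
    "C": (8.5, -1),
    "Y": (10.1, -1),
    "H": (6.5, +1),
    "K": (10.8, +1),
    "R": (12.5, +1),
}


def _net_charge(counts: Mapping[str, int], ph: float) -> float:
    charge = 1.0 / (1.0 + 10 ** (ph - PKA_NTERM))
    charge -= 1.0 / (1.0 + 10 ** (PKA_CTERM - ph))
    for res, n in counts.items():
        if n == 0 or res not in PKA_SIDECHAIN:
            continue
        pka, sign = PKA_SIDECHAIN[res]
        if sign > 0:
            charge += n / (1.0 + 10 ** (ph - pka))
        else:
            charge -= n / (1.0 + 10 ** (pka - ph))
    return charge


def isoelectric_point(sequence: str, n_cit: int = 0) -> float:
    """Theoretical pI of a peptide in which ``n_cit`` arginines have been
    deiminated to citrulline.

    Citrulline has a neutral ureido side chain, so each citrullinated
    arginine is simply removed from the titratable-group census; with every
    deimination the pI can only move down (a basic group is lost).  Solved
    by bisection of net charge = 0 on pH in (0, 14).
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    n_arg = sequence.count("R")
    if n_cit < 0 or n_cit > n_arg:
        raise ValueError(f"n_cit={n_cit} exceeds arginine count {n_arg}")
    counts = {res: sequence.count(res) for res in PKA_SIDECHAIN}
    counts["R"] = n_arg - n_cit
    lo, hi = 0.0, 14.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if _net_charge(counts, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def load_config(path: str) -> tuple[MassConstants, dict[str, float]]:
    """Read a YAML override file with optional ``constants:`` (water,
    proton, delta_cit, delta_pgm) and ``residue_masses:`` sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    constants = MassConstants(**raw.get("constants", {}))
    masses = dict(RESIDUE_MASSES)
    masses.update(raw.get("residue_masses", {}))
    if any(m <= 0 for m in masses.values()):
        raise ValueError("residue masses must be strictly positive")
    return constants, masses
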