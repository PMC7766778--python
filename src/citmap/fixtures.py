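"""Worked-example fixture: the published bovine-fibrinogen citrullination
peptides embedded in SYNTHETIC stand-in chains.

The source study printed, per tryptic peptide, the observed m/z of the
PGM-derivatized ion, the residue span on its fibrinogen chain, the
sequence with the PAD2-citrullinated arginines marked, the unmodified
MH+, and whether PAD4 produced the same peptide.  The full bovine chain
sequences are not part of that record, so this module rebuilds each chain
as a synthetic scaffold: the printed peptides sit at their printed
coordinates, all other positions are glycine filler with a lysine placed
immediately before each peptide start so that every printed span is a
legitimate tryptic product.  The PAD4-only peptide has no printed
coordinates and is placed at an arbitrary, documented span in the
synthetic beta chain.

Everything downstream (digestion, matching, site assignment, the
PAD2-vs-PAD4 comparison) then runs through the ordinary theory path; no
mass is injected by hand.
"""

from __future__ import annotations

from dataclasses import dataclass

from .digest import CandidatePeptide, ProteinChain, enumerate_candidates
from .mapping import (
    DEFAULT_TOLERANCE_DA,
    PeakList,
    RunComparison,
    SiteAssignment,
    assign_sites,
    compare_runs,
    match_peaks,
)
from .masses import ModificationState, peptide_mh

__all__ = [
    "Table1Peptide",
    "TABLE1_PEPTIDES",
    "PAD4_EXTRA_PEPTIDE",
    "build_chains",
    "pad2_peaklist",
    "pad4_peaklist",
    "map_run",
    "pad2_vs_pad4",
]


@dataclass(frozen=True)
class Table1Peptide:
    """One published peptide: observed PGM-ion m/z, chain span, sequence,
    PAD2-citrullinated chain positions, printed unmodified MH+, and
    whether PAD4 gave the same peptide."""

    label: str
    chain_id: str
    observed_mz: float
    start: int
    sequence: str
    cit_positions: frozenset[int]
    printed_mh: float
    in_pad4: bool

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1


TABLE1_PEPTIDES: tuple[Table1Peptide, ...] = (
    Table1Peptide("(1)", "alpha", 1276.77, 139, "SRIEILRR", frozenset({140, 145}), 1042.65, True),
    Table1Peptide("(2)", "alpha", 1400.87, 91, "LRDSLFNYQK", frozenset({92}), 1283.67, True),
    Table1Peptide("(3)", "alpha", 1509.69, 111, "NIVELMRGDFAK", frozenset({117}), 1392.73, False),
    Table1Peptide("(4)", "alpha", 1579.67, 229, "MSTITGPVPREFK", frozenset({238}), 1462.77, True),
    Table1Peptide("(5)", "beta", 1542.76, 16, "VGLGARGHRPYDK", frozenset({21}), 1425.77, True),
    Table1Peptide("(6)", "beta", 1659.69, 16, "VGLGARGHRPYDK", frozenset({21, 24}), 1425.77, True),
    Table1Peptide("(7)", "gamma", 1787.71, 169, "IHDVTGRDCQDVANK", frozenset({175}), 1670.79, False),
)

#: PAD4 additionally citrullinated one beta-chain peptide with no printed
#: coordinates; the span below is the synthetic placement (R at peptide
#: position 8 -> chain position 47).
PAD4_EXTRA_PEPTIDE = Table1Peptide(
    "(PAD4)", "beta", 0.0, 40, "KEEAPSLRPVPPPISGGGYR", frozenset({47}), 0.0, True
)


def _scaffold(chain_id: str, peptides: list[Table1Peptide], length: int) -> ProteinChain:
    """Glycine scaffold of ``length`` residues carrying each peptide at its
    printed span, with K immediately before each span so trypsin cuts
    there.  Synthetic stand-in, not the real fibrinogen chain."""
    residues = ["G"] * length
    for pep in peptides:
        if pep.start > 1:
            residues[pep.start - 2] = "K"
        residues[pep.start - 1 : pep.end] = list(pep.sequence)
    return ProteinChain(chain_id=chain_id, sequence="".join(residues))


def build_chains() -> dict[str, ProteinChain]:
    """The three synthetic fixture chains (alpha 241, beta 64, gamma 183
    residues).  The beta chain extends past the PAD4-only peptide so its
    C-terminal arginine is an ordinary cleavage site."""
    by_chain: dict[str, list[Table1Peptide]] = {"alpha": [], "beta": [], "gamma": []}
    for pep in TABLE1_PEPTIDES:
        by_chain[pep.chain_id].append(pep)
    by_chain["beta"].append(PAD4_EXTRA_PEPTIDE)
    return {
        "alpha": _scaffold("alpha", by_chain["alpha"], 241),
        "beta": _scaffold("beta", by_chain["beta"] , 64),
        "gamma": _scaffold("gamma", by_chain["gamma"], 183),
    }


def pad2_peaklist() -> PeakList:
    """The seven printed observed m/z values of the PAD2 + PGM run."""
    return PeakList(tuple(p.observed_mz for p in TABLE1_PEPTIDES))


def pad4_peaklist() -> PeakList:
    """Synthetic PAD4 + PGM run: theoretical PGM-ion masses of the
    PAD4-shared peptides plus the PAD4-only peptide (no observed values
    were printed for PAD4)."""
    mz = []
    seen = set()
    for pep in TABLE1_PEPTIDES + (PAD4_EXTRA_PEPTIDE,):
        if not pep.in_pad4 or (pep.chain_id, pep.cit_positions) in seen:
            continue
        seen.add((pep.chain_id, pep.cit_positions))
        state = ModificationState(pep.cit_positions, pgm_derivatized=True)
        mz.append(peptide_mh(pep.sequence, state, start=pep.start))
    return PeakList(tuple(mz))


def map_run(
    peaks: PeakList,
    chains: dict[str, ProteinChain] | None = None,
    tolerance_da: float = DEFAULT_TOLERANCE_DA,
    max_missed: int = 2,
    max_cit: int = 3,
) -> list[SiteAssignment]:
    """Full pipeline for one run: enumerate PGM-derivatized candidates for
    every chain, match the peaks, assign sites."""
    chains = chains or build_chains()
    candidates: list[CandidatePeptide] = []
    for chain in chains.values():
        candidates.extend(
            enumerate_candidates(chain, max_missed=max_missed, max_cit=max_cit, pgm=True)
        )
    matches = match_peaks(candidates, peaks, tolerance_da)
    return assign_sites(matches, tolerance_da=tolerance_da)


def pad2_vs_pad4(tolerance_da: float = DEFAULT_TOLERANCE_DA) -> tuple[
    list[SiteAssignment], list[SiteAssignment], RunComparison
]:
    """Map both runs on the shared fixture chains and compare site calls."""
    chains = build_chains()
    pad2 = map_run(pad2_peaklist(), chains, tolerance_da)
    pad4 = map_run(pad4_peaklist(), chains, tolerance_da)
    return pad2, pad4, compare_runs(pad2, pad4, chains=chains.keys())
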