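"""In-silico tryptic digestion with citrullination-aware cleavage.

Trypsin cleaves C-terminal to K and R but not before proline (Keil rule),
and it cannot cleave after citrulline.  A peptide observed in a digest of a
partially citrullinated chain therefore carries two kinds of internal K/R:
blocked sites (citrullinated R — no cleavage possible, not a miscleavage)
and genuine missed cleavages (uncitrullinated K/R the enzyme simply
skipped).  By mass alone the two are indistinguishable, which is exactly
why PGM derivatization is needed downstream; this module enumerates every
candidate (span, citrullination subset) pair consistent with that logic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .masses import (
    DEFAULT_CONSTANTS,
    MassConstants,
    ModificationState,
    RESIDUE_MASSES,
    peptide_mh,
)

__all__ = [
    "ProteinChain",
    "TrypticPeptide",
    "CandidatePeptide",
    "digest",
    "enumerate_candidates",
    "read_chains_fasta",
    "candidates_to_tsv",
    "DEFAULT_MAX_MISSED",
    "DEFAULT_MAX_CIT",
]

DEFAULT_MAX_MISSED = 2
DEFAULT_MAX_CIT = 3


@dataclass(frozen=True)
class ProteinChain:
    """A protein chain with 1-based inclusive residue coordinates.

    ``chain_id`` is free-form but fibrinogen work uses alpha/beta/gamma.
    """

    chain_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("chain sequence must be non-empty")
        bad = set(self.sequence) - set(RESIDUE_MASSES)
        if bad:
            raise ValueError(f"non-standard residues in chain {self.chain_id}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int) -> str:
        """Residues ``start..end``, 1-based inclusive."""
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class TrypticPeptide:
    chain_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int


@dataclass(frozen=True)
class CandidatePeptide:
    """A digestion product with a citrullination/PGM state and its MH+."""

    chain_id: str
    start: int
    end: int
    sequence: str
    state: ModificationState
    missed_cleavages: int
    theoretical_mh: float

    @property
    def n_cit(self) -> int:
        return self.state.n_cit


def _cut_sites(sequence: str) -> list[int]:
    """1-based residue positions after which trypsin can cleave: K/R not
    followed by P.  The chain C-terminus is not listed (it is always a
    boundary, never a cleavage event)."""
    n = len(sequence)
    return [
        i
        for i in range(1, n)
        if sequence[i - 1] in "KR" and sequence[i] != "P"
    ]


def digest(chain: ProteinChain, max_missed: int = DEFAULT_MAX_MISSED) -> list[TrypticPeptide]:
    """Unmodified tryptic peptides of ``chain`` with up to ``max_missed``
    retained internal cleavage sites.  The zero-missed peptides tile the
    chain exactly."""
    if max_missed < 0:
        raise ValueError("max_missed must be non-negative")
    cuts = _cut_sites(chain.sequence)
    bounds = [0] + cuts + [len(chain)]
    out: list[TrypticPeptide] = []
    for i, a in enumerate(bounds[:-1]):
        for skipped, b in enumerate(bounds[i + 1 : i + 2 + max_missed]):
            out.append(
                TrypticPeptide(
                    chain_id=chain.chain_id,
                    start=a + 1,
                    end=b,
                    sequence=chain.subseq(a + 1, b),
                    missed_cleavages=skipped,
                )
            )
    return out


def enumerate_candidates(
    chain: ProteinChain,
    max_missed: int = DEFAULT_MAX_MISSED,
    max_cit: int = DEFAULT_MAX_CIT,
    pgm: bool = False,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> list[CandidatePeptide]:
    """All candidate peptides of ``chain`` whose citrullination states are
    consistent with tryptic digestion of a partially citrullinated chain.

    For every span bounded by cleavage-compatible positions, every subset
    of its citrullinatable arginines (size <= ``max_cit``) is emitted.
    Citrullinatable means: any internal R, including R before P (mass
    relevant though never a cleavage site), and the C-terminal R only when
    the peptide ends at the chain terminus — a cleaved C-terminal R cannot
    have been citrullinated or trypsin could not have cut there.  A
    citrullinated R at a cleavage position is a blocked site and does not
    consume the missed-cleavage budget; uncitrullinated internal K/R
    cleavage sites do.

    With ``max_cit=0`` the output reduces to :func:`digest` (unmodified
    states only, same spans).
    """
    if max_cit < 0:
        raise ValueError("max_cit must be non-negative")
    if max_missed < 0:
        raise ValueError("max_missed must be non-negative")
    seq = chain.sequence
    n = len(seq)
    cuts = _cut_sites(seq)
    cutset = set(cuts)
    bounds = [0] + cuts + [n]
    out: list[CandidatePeptide] = []
    for i, a in enumerate(bounds[:-1]):
        for b in bounds[i + 1 :]:
            internal_cuts = [c for c in cuts if a < c < b]
            if len(internal_cuts) > max_missed + max_cit:
                break  # spans only grow; no cit assignment can rescue this or any later b
            # Arginines that may be citrullinated in this span.
            cit_able = [
                p
                for p in range(a + 1, b + 1)
                if seq[p - 1] == "R" and not (p == b and b < n)
            ]
            internal_r_cuts = {p for p in internal_cuts if seq[p - 1] == "R"}
            emitted = False
            for k in range(0, min(max_cit, len(cit_able)) + 1):
                for subset in itertools.combinations(cit_able, k):
                    blocked = internal_r_cuts & set(subset)
                    missed = len(internal_cuts) - len(blocked)
                    if missed > max_missed:
                        continue
                    state = ModificationState(frozenset(subset), pgm)
                    pep = chain.subseq(a + 1, b)
                    out.append(
                        CandidatePeptide(
                            chain_id=chain.chain_id,
                            start=a + 1,
                            end=b,
                            sequence=pep,
                            state=state,
                            missed_cleavages=missed,
                            theoretical_mh=peptide_mh(
                                pep, state, start=a + 1, constants=constants
                            ),
                        )
                    )
                    emitted = True
            if not emitted and len(internal_cuts) > max_missed:
                # No citrullination assignment can unblock this span, and
                # wider spans from the same start only add cut sites.
                break
    return out


def read_chains_fasta(path: str | Path) -> list[ProteinChain]:
    """Load chains from FASTA; the record id becomes the chain_id."""
    chains = [
        ProteinChain(chain_id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not chains:
        raise ValueError(f"no FASTA records in {path}")
    return chains


def candidates_to_tsv(candidates: Iterable[CandidatePeptide], path: str | Path) -> None:
    cols = "chain_id\tstart\tend\tsequence\tcit_positions\tpgm\tmissed_cleavages\tmh\n"
    with open(path, "w") as fh:
        fh.write(cols)
        for c in candidates:
            sites = ";".join(str(p) for p in sorted(c.state.citrullinated_positions))
            fh.write(
                f"{c.chain_id}\t{c.start}\t{c.end}\t{c.sequence}\t{sites}\t"
                f"{int(c.state.pgm_derivatized)}\t{c.missed_cleavages}\t{c.theoretical_mh:.4f}\n"
            )
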