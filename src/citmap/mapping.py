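"""Match observed MALDI-TOF peak lists against candidate peptides and call
citrullination sites.

A site call requires a PGM-derivatized match: the +116.03 Da adduct per
citrulline is what distinguishes a citrullinated peptide from the
isobaric missed-cleavage product.  Optionally a paired non-PGM peak
(the same candidate shifted down by exactly n_cit * delta_pgm) can be
demanded as corroboration.  When several candidates explain one peak
equally well the peak is reported as an ambiguity group rather than
silently resolved; ambiguous evidence never creates a site on its own.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .digest import CandidatePeptide
from .masses import DEFAULT_CONSTANTS, MassConstants

__all__ = [
    "PeakList",
    "PeakMatch",
    "SiteAssignment",
    "RunComparison",
    "match_peaks",
    "assign_sites",
    "compare_runs",
    "read_peaks_tsv",
    "read_peaks_mgf",
    "sites_to_tsv",
    "read_sites_tsv",
    "DEFAULT_TOLERANCE_DA",
]

DEFAULT_TOLERANCE_DA = 0.2


@dataclass(frozen=True)
class PeakList:
    """Positive-mode peak list; stored sorted by m/z."""

    mz: tuple[float, ...]
    intensity: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.mz):
            raise ValueError("m/z values must be strictly positive")
        order = sorted(range(len(self.mz)), key=lambda i: self.mz[i])
        object.__setattr__(self, "mz", tuple(self.mz[i] for i in order))
        if self.intensity is not None:
            if len(self.intensity) != len(self.mz):
                raise ValueError("intensity length does not match m/z length")
            object.__setattr__(
                self, "intensity", tuple(self.intensity[i] for i in order)
            )

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class PeakMatch:
    peak_mz: float
    candidate: CandidatePeptide
    error_da: float
    error_ppm: float
    #: True when other candidates explained this peak equally well under
    #: every tie-break key; all tied matches are returned, each flagged.
    ambiguous: bool = False


@dataclass(frozen=True)
class SiteAssignment:
    chain_id: str
    position: int
    evidence: tuple[PeakMatch, ...]


@dataclass(frozen=True)
class RunComparison:
    a_only: frozenset[tuple[str, int]]
    b_only: frozenset[tuple[str, int]]
    shared: frozenset[tuple[str, int]]

    def counts(self) -> dict[str, int]:
        return {
            "a_only": len(self.a_only),
            "b_only": len(self.b_only),
            "shared": len(self.shared),
            "a_total": len(self.a_only) + len(self.shared),
            "b_total": len(self.b_only) + len(self.shared),
        }


def _tie_key(error_da: float, cand: CandidatePeptide) -> tuple:
    # smallest |error|, then fewest modifications, then fewest missed
    # cleavages, then lowest start coordinate; rounding keeps float noise
    # from hiding genuine ties between isobaric candidates.
    return (
        round(abs(error_da), 9),
        cand.n_cit,
        cand.missed_cleavages,
        cand.start,
    )


def match_peaks(
    candidates: Sequence[CandidatePeptide],
    peaks: PeakList,
    tolerance_da: float = DEFAULT_TOLERANCE_DA,
) -> list[PeakMatch]:
    """Assign each observed peak its best-matching candidate within
    ``tolerance_da``.

    At most one candidate wins per peak; residual ties after all tie-break
    keys (typically positional isomers of the same modified peptide, which
    are exactly isobaric) are all returned, flagged ``ambiguous``.  Output
    is deterministic for fixed inputs and sorted by m/z.
    """
    if tolerance_da <= 0:
        raise ValueError("tolerance_da must be positive")
    out: list[PeakMatch] = []
    for mz in peaks.mz:
        hits = [
            (c, mz - c.theoretical_mh)
            for c in candidates
            if abs(mz - c.theoretical_mh) <= tolerance_da
        ]
        if not hits:
            continue
        best = min(_tie_key(err, c) for c, err in hits)
        tied = [
            (c, err)
            for c, err in hits
            if _tie_key(err, c)[:3] == best[:3]
        ]
        # Distinct start coordinates are a genuine tie-break, not an
        # ambiguity: keep only the lowest-start representative unless the
        # tied candidates differ in which sites they implicate.
        implicated = {
            (c.chain_id, c.state.citrullinated_positions) for c, _ in tied
        }
        if len(implicated) > 1:
            for c, err in sorted(tied, key=lambda h: _tie_key(h[1], h[0])):
                out.append(
                    PeakMatch(mz, c, err, 1e6 * err / c.theoretical_mh, ambiguous=True)
                )
        else:
            c, err = min(tied, key=lambda h: _tie_key(h[1], h[0]))
            out.append(PeakMatch(mz, c, err, 1e6 * err / c.theoretical_mh))
    return out


def assign_sites(
    matches: Iterable[PeakMatch],
    require_paired_native: bool = False,
    constants: MassConstants = DEFAULT_CONSTANTS,
    tolerance_da: float = DEFAULT_TOLERANCE_DA,
) -> list[SiteAssignment]:
    """Collapse peak matches into per-(chain, position) citrullination
    calls.

    Every call is evidenced by at least one unambiguous PGM-derivatized
    match whose citrullination set contains the position.  With
    ``require_paired_native`` a non-PGM match for the same candidate
    (same span and citrullination set, theoretical mass lower by exactly
    n_cit * delta_pgm) must also be present among ``matches``.  Output is
    independent of the order of ``matches``.
    """
    matches = list(matches)
    pgm_matches = [
        m
        for m in matches
        if m.candidate.state.pgm_derivatized and m.candidate.n_cit > 0 and not m.ambiguous
    ]
    if require_paired_native:
        native_keys = {
            (
                m.candidate.chain_id,
                m.candidate.start,
                m.candidate.end,
                m.candidate.state.citrullinated_positions,
            )
            for m in matches
            if not m.candidate.state.pgm_derivatized and m.candidate.n_cit > 0
        }
        pgm_matches = [
            m
            for m in pgm_matches
            if (
                m.candidate.chain_id,
                m.candidate.start,
                m.candidate.end,
                m.candidate.state.citrullinated_positions,
            )
            in native_keys
        ]
    evidence: dict[tuple[str, int], list[PeakMatch]] = {}
    for m in pgm_matches:
        for pos in m.candidate.state.citrullinated_positions:
            evidence.setdefault((m.candidate.chain_id, pos), []).append(m)
    return [
        SiteAssignment(
            chain_id=chain,
            position=pos,
            evidence=tuple(sorted(ev, key=lambda m: (m.peak_mz, m.candidate.start))),
        )
        for (chain, pos), ev in sorted(evidence.items())
    ]


def compare_runs(
    run_a: Sequence[SiteAssignment],
    run_b: Sequence[SiteAssignment],
    chains: Iterable[str] | None = None,
) -> RunComparison:
    """Intersect two runs' site calls on (chain, position).

    ``chains``, when given, is the shared chain universe; an assignment
    referencing any other chain is an error (the runs are not comparable).
    """
    if chains is not None:
        universe = set(chains)
        for run, name in ((run_a, "a"), (run_b, "b")):
            extra = {s.chain_id for s in run} - universe
            if extra:
                raise ValueError(f"run {name} references unknown chains {sorted(extra)}")
    a = {(s.chain_id, s.position) for s in run_a}
    b = {(s.chain_id, s.position) for s in run_b}
    return RunComparison(
        a_only=frozenset(a - b), b_only=frozenset(b - a), shared=frozenset(a & b)
    )


# --- I/O --------------------------------------------------------------------


def read_peaks_tsv(path: str | Path) -> PeakList:
    """Two-column TSV (m/z, optional intensity); '#' lines and a non-numeric
    header row are skipped."""
    mz: list[float] = []
    inten: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            try:
                m = float(parts[0])
            except ValueError:
                continue  # header
            mz.append(m)
            if len(parts) > 1:
                inten.append(float(parts[1]))
    return PeakList(tuple(mz), tuple(inten) if len(inten) == len(mz) else None)


def read_peaks_mgf(path: str | Path) -> PeakList:
    """Minimal MGF reader: collects PEPMASS lines and bare 'm/z intensity'
    rows from every BEGIN IONS block into one positive-mode peak list."""
    mz: list[float] = []
    inten: list[float] = []
    in_block = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line == "BEGIN IONS":
                in_block = True
                continue
            if line == "END IONS":
                in_block = False
                continue
            if not in_block or not line:
                continue
            if "=" in line:
                key, _, value = line.partition("=")
                if key.upper() == "PEPMASS":
                    fields = value.split()
                    mz.append(float(fields[0]))
                    inten.append(float(fields[1]) if len(fields) > 1 else 0.0)
                continue
            fields = line.split()
            try:
                mz.append(float(fields[0]))
                inten.append(float(fields[1]) if len(fields) > 1 else 0.0)
            except ValueError:
                continue
    return PeakList(tuple(mz), tuple(inten) if inten else None)


def sites_to_tsv(sites: Sequence[SiteAssignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chain_id\tposition\tn_evidence\terrors_da\terrors_ppm\n")
        for s in sites:
            da = ";".join(f"{m.error_da:.4f}" for m in s.evidence)
            ppm = ";".join(f"{m.error_ppm:.1f}" for m in s.evidence)
            fh.write(f"{s.chain_id}\t{s.position}\t{len(s.evidence)}\t{da}\t{ppm}\n")


def read_sites_tsv(path: str | Path) -> list[SiteAssignment]:
    """Read a site report back as bare (chain, position) assignments."""
    out: list[SiteAssignment] = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            out.append(SiteAssignment(fields[0], int(fields[1]), ()))
    return out


def comparison_to_json(comparison: RunComparison, path: str | Path) -> None:
    payload = comparison.counts()
    payload["shared_sites"] = sorted([list(x) for x in comparison.shared])
    payload["a_only_sites"] = sorted([list(x) for x in comparison.a_only])
    payload["b_only_sites"] = sorted([list(x) for x in comparison.b_only])
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
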