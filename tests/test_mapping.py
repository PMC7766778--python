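"""Peak matching, site assignment, and run comparison."""

import random

import pytest

from citmap.digest import enumerate_candidates
from citmap.fixtures import (
    PAD4_EXTRA_PEPTIDE,
    TABLE1_PEPTIDES,
    build_chains,
    map_run,
    pad2_peaklist,
    pad2_vs_pad4,
    pad4_peaklist,
)
from citmap.mapping import (
    PeakList,
    SiteAssignment,
    assign_sites,
    compare_runs,
    match_peaks,
    read_peaks_mgf,
    read_peaks_tsv,
)


def alpha_candidates(fixture_chains, pgm=True):
    return enumerate_candidates(fixture_chains["alpha"], 2, 3, pgm=pgm)


def test_match_within_default_tolerance(fixture_chains):
    """The printed 1400.87 ion is the singly citrullinated, PGM-derivatized
    LRDSLFNYQK (theoretical ~1400.69): matched at 0.2 Da, not at 0.05."""
    peaks = PeakList((1400.87,))
    cands = alpha_candidates(fixture_chains)
    [m] = match_peaks(cands, peaks, tolerance_da=0.2)
    assert m.candidate.sequence == "LRDSLFNYQK"
    assert m.candidate.state.citrullinated_positions == frozenset({92})
    assert m.error_da == pytest.approx(0.185, abs=0.02)
    assert match_peaks(cands, peaks, tolerance_da=0.05) == []


def test_empty_inputs_give_empty_matches(fixture_chains):
    assert match_peaks([], PeakList((1000.0,)), 0.2) == []
    assert match_peaks(alpha_candidates(fixture_chains), PeakList(()), 0.2) == []


def test_tolerance_must_be_positive(fixture_chains):
    with pytest.raises(ValueError):
        match_peaks(alpha_candidates(fixture_chains), PeakList((1.0,)), 0.0)


def test_isobaric_positional_isomers_are_flagged_ambiguous(fixture_chains):
    """A 1-citrulline ion of the beta 16-28 peptide could sit on either
    arginine; the R21 isomer wins the missed-cleavage tie-break (a blocked
    R21 is not a miscleavage, an uncitrullinated one is), so the call is
    unambiguous.  Forcing equal missed counts by restricting the budget
    produces a flagged ambiguity group instead of a silent pick."""
    beta = build_chains()["beta"]
    cands = [
        c
        for c in enumerate_candidates(beta, 2, 3, pgm=True)
        if (c.start, c.end) == (16, 28) and c.n_cit == 1
    ]
    mz = cands[0].theoretical_mh
    assert all(c.theoretical_mh == pytest.approx(mz, abs=1e-9) for c in cands)
    matches = match_peaks(cands, PeakList((mz,)), 0.2)
    assert len(matches) == 1 and not matches[0].ambiguous
    assert matches[0].candidate.state.citrullinated_positions == frozenset({21})
    # drop the miscleavage distinction: both isomers now tie on every key
    forced = [
        c.__class__(**{**c.__dict__, "missed_cleavages": 0}) for c in cands
    ]
    matches = match_peaks(forced, PeakList((mz,)), 0.2)
    assert len(matches) == 2 and all(m.ambiguous for m in matches)
    assert assign_sites(matches) == []


def test_pad2_site_tallies():
    """The PAD2 + PGM run yields five alpha-chain sites, two beta-chain
    sites, and one gamma-chain site."""
    sites = map_run(pad2_peaklist())
    by_chain = {}
    for s in sites:
        by_chain.setdefault(s.chain_id, set()).add(s.position)
    assert by_chain["alpha"] == {92, 117, 140, 145, 238}
    assert by_chain["beta"] == {21, 24}
    assert by_chain["gamma"] == {175}


def test_every_site_has_pgm_evidence_covering_it():
    for s in map_run(pad2_peaklist()):
        assert s.evidence
        for m in s.evidence:
            assert m.candidate.state.pgm_derivatized
            assert s.position in m.candidate.state.citrullinated_positions


def test_assign_sites_order_invariant(fixture_chains):
    cands = []
    for chain in fixture_chains.values():
        cands.extend(enumerate_candidates(chain, 2, 3, pgm=True))
    matches = match_peaks(cands, pad2_peaklist(), 0.2)
    baseline = assign_sites(matches)
    rng = random.Random(7)
    for _ in range(5):
        shuffled = matches[:]
        rng.shuffle(shuffled)
        assert assign_sites(shuffled) == baseline


def test_paired_native_requirement(fixture_chains):
    """With require_paired_native, a PGM ion only counts when the same
    candidate's underivatized citrullinated ion is also present."""
    cands = alpha_candidates(fixture_chains, pgm=True) + alpha_candidates(
        fixture_chains, pgm=False
    )
    pgm_ion = 1400.69
    native_ion = pgm_ion - 116.026215
    only_pgm = match_peaks(cands, PeakList((pgm_ion,)), 0.2)
    assert assign_sites(only_pgm, require_paired_native=True) == []
    paired = match_peaks(cands, PeakList((native_ion, pgm_ion)), 0.2)
    sites = assign_sites(paired, require_paired_native=True)
    assert [(s.chain_id, s.position) for s in sites] == [("alpha", 92)]


def test_pad2_vs_pad4_comparison():
    """PAD4 produced seven sites, six shared with PAD2's eight."""
    pad2, pad4, comparison = pad2_vs_pad4()
    counts = comparison.counts()
    assert counts == {"a_only": 2, "b_only": 1, "shared": 6, "a_total": 8, "b_total": 7}
    assert ("beta", PAD4_EXTRA_PEPTIDE.start + 7) in comparison.b_only


def test_compare_runs_trivia():
    a = [SiteAssignment("alpha", 10, ()), SiteAssignment("alpha", 20, ())]
    same = compare_runs(a, a)
    assert same.counts() == {"a_only": 0, "b_only": 0, "shared": 2, "a_total": 2, "b_total": 2}
    disjoint = compare_runs(a, [SiteAssignment("alpha", 30, ())])
    assert disjoint.counts()["shared"] == 0
    with pytest.raises(ValueError, match="unknown chains"):
        compare_runs(a, [SiteAssignment("delta", 1, ())], chains=["alpha", "beta"])


def test_peak_list_sorted_and_validated():
    peaks = PeakList((300.0, 100.0, 200.0), (3.0, 1.0, 2.0))
    assert peaks.mz == (100.0, 200.0, 300.0)
    assert peaks.intensity == (1.0, 2.0, 3.0)
    with pytest.raises(ValueError):
        PeakList((0.0,))


def test_peak_readers(tmp_path):
    tsv = tmp_path / "run.tsv"
    tsv.write_text("mz\tintensity\n# comment\n1400.87\t250\n1276.77\t90\n")
    peaks = read_peaks_tsv(tsv)
    assert peaks.mz == (1276.77, 1400.87)
    mgf = tmp_path / "run.mgf"
    mgf.write_text(
        "BEGIN IONS\nTITLE=spot1\nPEPMASS=1400.87 250\nEND IONS\n"
        "BEGIN IONS\nPEPMASS=1276.77\nEND IONS\n"
    )
    assert read_peaks_mgf(mgf).mz == (1276.77, 1400.87)
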