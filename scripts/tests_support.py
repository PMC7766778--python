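"""Shared helpers for the acceptance script: the alpha-chain-like test
fragment and the site-recovery wrapper (mirrors the test suite's fixture
without importing from tests/)."""

from citmap.digest import ProteinChain, enumerate_candidates
from citmap.mapping import assign_sites, match_peaks

FRAGMENT = ProteinChain("alpha_frag", "GAGAGKSRIEILRRGAGAGK")
FRAGMENT_SITES = frozenset({8, 13})


def recovered_sites(peaks, chain, tolerance=0.2):
    cands = enumerate_candidates(chain, 2, 3, pgm=True)
    return {
        (s.chain_id, s.position)
        for s in assign_sites(match_peaks(cands, peaks, tolerance))
    }
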