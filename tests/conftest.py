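import itertools

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def oracle_candidates(sequence: str, max_missed: int, max_cit: int):
    """Exhaustive reference enumeration of candidate peptides.

    Checks every (start, end, citrullination subset) triple directly
    against the digestion invariants: boundaries are chain termini or
    K/R-not-before-P cleavage points, a cleaved C-terminal R is never
    citrullinated, citrullinated internal cleavage sites are blocked, and
    uncitrullinated internal cleavage sites consume the missed budget.
    Deliberately written as plain loops, independent of the engine.
    """
    n = len(sequence)
    out = set()
    for start in range(1, n + 1):
        if start > 1 and not (
            sequence[start - 2] in "KR" and sequence[start - 1] != "P"
        ):
            continue
        for end in range(start, n + 1):
            if end < n and not (sequence[end - 1] in "KR" and sequence[end] != "P"):
                continue
            r_positions = [
                p
                for p in range(start, end + 1)
                if sequence[p - 1] == "R" and not (p == end and end < n)
            ]
            cut_positions = [
                p
                for p in range(start, end)
                if sequence[p - 1] in "KR" and sequence[p] != "P"
            ]
            for k in range(0, min(max_cit, len(r_positions)) + 1):
                for subset in itertools.combinations(r_positions, k):
                    missed = sum(1 for p in cut_positions if p not in subset)
                    if missed <= max_missed:
                        out.add((start, end, frozenset(subset), missed))
    return out


@pytest.fixture(scope="session")
def fixture_chains():
    from citmap.fixtures import build_chains

    return build_chains()
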