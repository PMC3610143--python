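"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results by exhaustive scanning or
exact rational arithmetic, independent of the library code paths they
check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import pytest
from hypothesis import HealthCheck, settings

from tagdge import TranscriptRecord, build_reference_library

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def brute_force_digest(sequence: str) -> set[tuple[str, str, int, int]]:
    """Exhaustive window scan of both strands.

    Returns {(tag_seq, strand, position_rank, offset)}: every CATG-anchored
    21-nt window, ranked from the 3' end among full-length sites, N tags
    dropped after ranking.
    """
    out = set()
    for strand, s in (("sense", sequence), ("antisense", revcomp(sequence))):
        sites = [i for i in range(len(s) - 20) if s[i:i + 4] == "CATG"]
        for rank, off in enumerate(reversed(sites), start=1):
            tag = s[off:off + 21]
            if "N" not in tag:
                out.add((tag, strand, rank, off))
    return out


def brute_force_hamming_hits(tag: str, library) -> tuple[int, list]:
    """Best Hamming tier (0 or 1) and its reference hits, by full scan."""
    best_d, hits = 2, []
    for ref_seq, ref_hits in library.entries.items():
        d = sum(a != b for a, b in zip(tag, ref_seq))
        if d < best_d:
            best_d, hits = d, list(ref_hits)
        elif d == best_d:
            hits.extend(ref_hits)
    return best_d, hits


def ac_pmf_exact(j: int, x: int, n1: int, n2: int) -> Fraction:
    r = Fraction(n2, n1 + n2)
    return comb(x + j, j) * r ** j * (1 - r) ** (x + 1)


def ac_test_exact(x: int, n1: int, y: int, n2: int) -> Fraction:
    """Exact rational two-sided Audic-Claverie p-value.

    The pmf in y sums to 1 over j >= 0, so the upper tail is
    1 - P(Y <= y-1) exactly.
    """
    lower = sum(ac_pmf_exact(j, x, n1, n2) for j in range(y + 1))
    upper = 1 - lower + ac_pmf_exact(y, x, n1, n2)
    return min(Fraction(1), 2 * min(lower, upper))


def hypergeom_upper_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) by full pmf enumeration."""
    denom = comb(N, n)
    return Fraction(
        sum(comb(K, i) * comb(N - K, n - i)
            for i in range(k, min(K, n) + 1)),
        denom,
    )


@pytest.fixture
def toy_transcripts() -> list[TranscriptRecord]:
    """Three transcripts with hand-placed CATG sites.

    g1: one sense site; g2: two sense sites (distinct tags); g3 shares
    g1's tag, planting reference ambiguity.
    """
    shared = "CATG" + "ACTGACTGACTGACTGA"          # 21 nt
    t2a = "CATG" + "A" * 17
    t2b = "CATG" + "C" * 17
    return [
        TranscriptRecord("g1", "dbA", 1, "TTT" + shared + "TTT"),
        TranscriptRecord("g2", "dbA", 1, "AA" + t2a + "TT" + t2b + "AA"),
        TranscriptRecord("g3", "dbB", 2, "CCTT" + shared + "AACC"),
    ]


@pytest.fixture
def toy_library(toy_transcripts):
    return build_reference_library(toy_transcripts)
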