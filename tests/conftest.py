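"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from linkfrag.seqio import Genome, revcomp

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def brute_levenshtein(a: str, b: str) -> int:
    """Textbook O(nm) edit distance with the N-never-matches rule."""
    n, m = len(a), len(b)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        dp[i][0] = i
    for j in range(m + 1):
        dp[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            same = a[i - 1] == b[j - 1] and a[i - 1] != "N"
            dp[i][j] = min(
                dp[i - 1][j - 1] + (0 if same else 1),
                dp[i - 1][j] + 1,
                dp[i][j - 1] + 1,
            )
    return dp[n][m]


def brute_semiglobal_cost(read: str, window: str) -> int:
    """Min edit cost of the full read against any substring of the window
    (free end gaps on the reference), by direct DP."""
    n, m = len(read), len(window)
    prev = [0] * (m + 1)  # free start on the reference
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            same = read[i - 1] == window[j - 1] and read[i - 1] != "N"
            cur[j] = min(
                prev[j - 1] + (0 if same else 1),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    return min(prev)


def brute_guide_sites(seq: str) -> set[tuple[int, str]]:
    """All (forward-strand site start, strand) of 20-mer+NGG occurrences,
    scanning both strands naively."""
    out = set()
    for i in range(len(seq) - 22):
        if seq[i + 21 : i + 23] == "GG" and "N" not in seq[i : i + 20]:
            out.add((i, "+"))
    rc = revcomp(seq)
    L = len(seq)
    for i in range(len(rc) - 22):
        if rc[i + 21 : i + 23] == "GG" and "N" not in rc[i : i + 20]:
            out.add((L - (i + 23), "-"))
    return out


def fisher_two_sided_oracle(table) -> float:
    """Two-sided Fisher's exact p by hypergeometric enumeration: sum the
    probabilities of all tables with the same margins whose probability does
    not exceed that of the observed table (within float slack)."""
    from scipy.stats import hypergeom

    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    rv = hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = rv.pmf(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(1.0, total)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture
def tiny_genome():
    rng = np.random.default_rng(7)
    return Genome({"chr1": random_dna(rng, 3000), "chr2": random_dna(rng, 1500)})
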