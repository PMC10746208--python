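"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's vectorised code paths:
counting is a per-window Python loop, expectations come from an explicit
contingency table, and hit finding checks every offset.  They exist so the
fast implementation can be validated against something simple enough to be
obviously correct.
"""

from __future__ import annotations

import math
import random

import pytest

BASES = "ACGT"


def naive_window_counts(seq: str, k: int, circular: bool = True) -> tuple[dict, int]:
    """Per-window sliding-loop k-mer counts; skips windows containing N."""
    s = seq + seq[: k - 1] if circular else seq
    counts: dict[str, int] = {}
    n_windows = 0
    for i in range(len(s) - k + 1):
        w = s[i : i + k]
        if set(w) <= set(BASES):
            counts[w] = counts.get(w, 0) + 1
            n_windows += 1
    return counts, n_windows


def contingency_expected(seq: str, k: int, circular: bool = True) -> dict[str, float]:
    """Expected counts of all 4**k words from the (first base x last base)
    contingency table of each middle word: E = row_total * col_total / grand.

    Words with an unobserved middle are omitted (inestimable).
    """
    c_km1, _ = naive_window_counts(seq, k - 1, circular)
    c_km2, _ = naive_window_counts(seq, k - 2, circular)
    expected: dict[str, float] = {}
    for mid, grand in c_km2.items():
        for a in BASES:
            row = c_km1.get(a + mid, 0)
            for b in BASES:
                col = c_km1.get(mid + b, 0)
                expected[a + mid + b] = row * col / grand
    return expected


def naive_motif_stats(
    seq: str, k_min: int, k_max: int, circular: bool = True
) -> dict[str, tuple[int, float, float]]:
    """(O, E, Z) for every estimable, non-degenerate word of length k_min..k_max."""
    out: dict[str, tuple[int, float, float]] = {}
    for k in range(k_min, k_max + 1):
        counts, n = naive_window_counts(seq, k, circular)
        for motif, e in contingency_expected(seq, k, circular).items():
            if not 0 < e < n:
                continue
            o = counts.get(motif, 0)
            z = (o - e) / math.sqrt(e * (1 - e / n))
            out[motif] = (o, e, z)
    return out


def naive_find_offsets(seq: str, word: str) -> list[int]:
    """Every offset where word occurs, by direct comparison."""
    return [
        i for i in range(len(seq) - len(word) + 1) if seq[i : i + len(word)] == word
    ]


def random_dna(n: int, seed: int) -> str:
    rng = random.Random(seed)
    return "".join(rng.choice(BASES) for _ in range(n))


@pytest.fixture
def small_genome():
    from stealth import GenomeSequence

    return GenomeSequence(id="fixture", seq=random_dna(2000, seed=42))
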