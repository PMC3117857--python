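"""Shared fixtures: an independent brute-force autocorrelation oracle and
random masked-sequence generators used across test modules."""

from __future__ import annotations

import random

import pytest


def oracle_autocorr(seq: str, dinuc: str, window: int, mask_mode: str = "none"):
    """Literal O(n*W) re-implementation of the counting rules.

    Independent of the package: works character by character on the raw
    string.  An anchor at i is counted only if no masked base and no
    sequence end occurs within its window span [i, i + window + 1]; each
    downstream occurrence at distance 2..window then scores one count.
    """

    def analyzable(ch: str) -> bool:
        if ch in "Nn":
            return False
        if mask_mode == "masked":
            return ch.isupper()
        return True

    def occurrence(i: int) -> bool:
        return (
            i + 1 < len(seq)
            and seq[i].upper() + seq[i + 1].upper() == dinuc
            and analyzable(seq[i])
            and analyzable(seq[i + 1])
        )

    counts = {d: 0 for d in range(2, window + 1)}
    n = len(seq)
    n_anchors = 0
    for i in range(n - 1):
        if not occurrence(i):
            continue
        if i + window + 1 > n - 1:
            continue  # end of sequence inside the window span
        if any(not analyzable(seq[p]) for p in range(i, i + window + 2)):
            continue  # masked stretch inside the window span
        n_anchors += 1
        for d in range(2, window + 1):
            if occurrence(i + d):
                counts[d] += 1
    return counts, n_anchors


def random_masked_sequence(rng: random.Random, length: int, p_mask: float = 0.1, p_n: float = 0.03) -> str:
    """Random ACGT sequence with random soft-masked (lowercase) and
    hard-masked (N) stretches, emulating a masked genome build."""
    out: list[str] = []
    i = 0
    while i < length:
        run = rng.randint(1, 120)
        roll = rng.random()
        if roll < p_n:
            out.append("N" * run)
        elif roll < p_n + p_mask:
            out.append("".join(rng.choice("acgt") for _ in range(run)))
        else:
            out.append("".join(rng.choice("ACGT") for _ in range(run)))
        i += run
    return "".join(out)[:length]


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20110531)
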