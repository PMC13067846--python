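"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive — character-by-character scans,
exhaustive structure enumeration, exhaustive sliding-window matching — and
shares no code with the package's own algorithms.
"""

from __future__ import annotations

import math

import numpy as np


def naive_gu_scan(seq: str) -> list[int]:
    """1-based G positions of every GU dinucleotide, by character comparison."""
    return [i + 1 for i in range(len(seq) - 1) if seq[i : i + 2] == "GU"]


def naive_reverse_complement(seq: str) -> str:
    comp = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


def enumerate_ensemble(seq: str, pair_energies: dict, min_hairpin: int, rt: float):
    """Boltzmann sums over all nested structures by explicit enumeration.

    Returns (Z, P, q) with P the pair-probability matrix and q the
    unpaired probabilities.  Exponential in length; keep sequences short.
    """
    table = dict(pair_energies)
    table.update({(b, a): e for (a, b), e in pair_energies.items()})
    n = len(seq)

    def structures(start: int, limit: int):
        if start >= limit:
            yield []
            return
        yield from structures(start + 1, limit)
        for k in range(start + min_hairpin + 1, limit):
            if (seq[start], seq[k]) in table:
                for inner in structures(start + 1, k):
                    for outer in structures(k + 1, limit):
                        yield [(start, k)] + inner + outer

    z = 0.0
    p = np.zeros((n, n))
    for s in structures(0, n):
        weight = math.exp(sum(-table[(seq[i], seq[j])] / rt for i, j in s))
        z += weight
        for i, j in s:
            p[i, j] += weight
            p[j, i] += weight
    p /= z
    return z, p, 1.0 - p.sum(axis=1)


def naive_offtarget(footprint: str, seed_start: int, seed_length: int,
                    max_mismatches: int, transcriptome) -> list[tuple[str, int, int]]:
    """Exhaustive sliding-window search; returns (id, 1-based pos, mismatches).

    A window qualifies if it matches the footprint exactly over
    ``[seed_start, seed_start + seed_length)`` and has at most
    ``max_mismatches`` mismatches in total.
    """
    L = len(footprint)
    hits = []
    for t in transcriptome:
        seq = t.sequence
        for start in range(len(seq) - L + 1):
            window = seq[start : start + L]
            if window[seed_start : seed_start + seed_length] != \
                    footprint[seed_start : seed_start + seed_length]:
                continue
            mism = sum(a != b for a, b in zip(window, footprint))
            if mism <= max_mismatches:
                hits.append((t.id, start + 1, mism))
    return hits
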