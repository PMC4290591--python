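"""Independent oracles used by the test suite.

These deliberately avoid the implementation's code paths: the alignment
oracles are a biopython pairwise aligner and an exhaustive recursive path
enumeration; the BH oracle is the textbook step-up recurrence written
directly; the fixed-point oracle iterates the proportional-reassignment map
to convergence from scratch.
"""

from __future__ import annotations

import numpy as np


def biopython_local_score(read: str, target: str) -> float:
    """Best local alignment score from Bio.Align.PairwiseAligner under the
    pipeline's scheme (+4 match, -3 mismatch, gap of length k costs 4 + 2k;
    biopython convention: first gap base -6, each further base -2)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 4
    aligner.mismatch_score = -3
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -2
    return aligner.score(target, read)


def exhaustive_local_score(
    read: str,
    target: str,
    match: int = 4,
    mismatch: int = -3,
    gap_open: int = -4,
    gap_extend: int = -2,
) -> int:
    """Best local alignment score by enumerating every alignment path.

    Every start cell and every monotone sequence of substitution / gap moves
    is walked explicitly, scoring gaps affinely along the path.  Exponential:
    only usable for very short sequences.
    """
    m, n = len(read), len(target)
    best = 0

    def walk(i: int, j: int, score: int, last: str) -> None:
        nonlocal best
        if score > best:
            best = score
        if i < m and j < n:
            s = match if read[i] == target[j] else mismatch
            walk(i + 1, j + 1, score + s, "M")
        if j < n:
            cost = gap_extend if last == "D" else gap_open + gap_extend
            walk(i, j + 1, score + cost, "D")
        if i < m:
            cost = gap_extend if last == "I" else gap_open + gap_extend
            walk(i + 1, j, score + cost, "I")

    for i in range(m):
        for j in range(n):
            walk(i, j, 0, "")
    return best


def bh_step_up(p_values) -> list[float]:
    """Benjamini-Hochberg adjusted p-values by the literal step-up recurrence:
    sort ascending, adj_i = min over j >= i of m * p_j / j, cap at 1, return
    in input order."""
    m = len(p_values)
    order = sorted(range(m), key=lambda k: p_values[k])
    adjusted = [0.0] * m
    running = float("inf")
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p_values[idx] / rank)
        adjusted[idx] = min(running, 1.0)
    return adjusted


def fixed_point_weights(
    loci_per_read: dict[str, list[str]],
    counts: dict[str, float],
    n_iter: int = 10_000,
) -> dict[str, dict[str, float]]:
    """Proportional-reassignment fixed point with locus-identity expression
    (no footprint windows): run far past convergence and return the weights."""
    weights = {
        rid: {locus: 1.0 / len(loci) for locus in loci}
        for rid, loci in loci_per_read.items()
    }
    for _ in range(n_iter):
        expression: dict[str, float] = {}
        for rid, per_locus in weights.items():
            for locus, w in per_locus.items():
                expression[locus] = expression.get(locus, 0.0) + counts[rid] * w
        for rid, per_locus in weights.items():
            total = sum(expression[locus] for locus in per_locus)
            if total > 0:
                for locus in per_locus:
                    per_locus[locus] = expression[locus] / total
    return weights


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
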