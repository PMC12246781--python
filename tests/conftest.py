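"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results by the most transparent
route available — full dynamic-programming matrices in pure Python, and
exhaustive all-pairs orthology — so they share no code path with the
package's optimised implementations.
"""

from __future__ import annotations

import math
from typing import List, Optional, Tuple

import pytest

from fragani import (
    Genome,
    builtin_align,
    fragment_genome,
    filter_ambiguous,
    FragmentationParams,
)

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def sw_oracle(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = 5,
    gap_extend: int = 2,
) -> Tuple[int, int, int, int, int]:
    """Naive full-matrix local affine alignment (Gotoh), pure Python.

    Same deterministic conventions as the package states for its builtin
    aligner: gap of length L costs open + extend*L; cell preference
    diagonal > gap-in-subject > gap-in-query > stop; gap states prefer
    opening over extending; best cell is the smallest (i, j) among maxima.
    Returns (score, columns, matches, mismatches, gap_opens).
    """
    NEG = -(10**9)
    goe = gap_open + gap_extend
    m, n = len(a), len(b)
    ok = set("ACGT")
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    src = [[0] * (n + 1) for _ in range(m + 1)]  # 0 stop 1 diag 2 F 3 E
    e_ext = [[False] * (n + 1) for _ in range(m + 1)]
    f_ext = [[False] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            fo, fe = H[i - 1][j] - goe, F[i - 1][j] - gap_extend
            F[i][j] = max(fo, fe)
            f_ext[i][j] = fe > fo
            eo, ee = H[i][j - 1] - goe, E[i][j - 1] - gap_extend
            E[i][j] = max(eo, ee)
            e_ext[i][j] = ee > eo
            same = a[i - 1] == b[j - 1] and a[i - 1] in ok
            s = H[i - 1][j - 1] + (match if same else mismatch)
            h, sc = s, 1
            if F[i][j] > h:
                h, sc = F[i][j], 2
            if E[i][j] > h:
                h, sc = E[i][j], 3
            if h <= 0:
                h, sc = 0, 0
            H[i][j], src[i][j] = h, sc
            if h > best:
                best, bi, bj = h, i, j
    cols = matches = mism = gapopens = 0
    i, j, state = bi, bj, 0
    while i > 0 and j > 0:
        if state == 0:
            sc = src[i][j]
            if sc == 0:
                break
            if sc == 1:
                cols += 1
                if a[i - 1] == b[j - 1] and a[i - 1] in ok:
                    matches += 1
                else:
                    mism += 1
                i, j = i - 1, j - 1
            elif sc == 2:
                state = 2
            else:
                state = 1
        elif state == 1:
            cols += 1
            ext = e_ext[i][j]
            j -= 1
            if not ext:
                gapopens += 1
                state = 0
        else:
            cols += 1
            ext = f_ext[i][j]
            i -= 1
            if not ext:
                gapopens += 1
                state = 0
    return best, cols, matches, mism, gapopens


def brute_force_ani(
    query: Genome,
    reference: Genome,
    fragment_length: int = 1020,
    min_coverage: float = 0.35,
    min_score: int = 40,
) -> Optional[float]:
    """Exhaustive all-pairs mutual-argmax ANI oracle (no seeding, no caching).

    Aligns every query fragment against every reference fragment on both
    strands, keeps the per-pair best (forward strand on ties), applies the
    reporting score cutoff, picks each side's best partner (score, then
    identity, then smaller partner id), intersects mutually-best pairs,
    applies the ceil(min_coverage * fragment_length) rule on both
    directions, and averages the 2n directional identities. Returns None
    when no pair survives.
    """
    params = FragmentationParams(fragment_length=fragment_length)
    qf = filter_ambiguous(fragment_genome(query, params), params)
    rf = filter_ambiguous(fragment_genome(reference, params), params)

    def all_hits(frags_a, frags_b):
        table = {}
        for fa in frags_a:
            for fb in frags_b:
                fwd = builtin_align(fa.sequence, fb.sequence)
                rev = builtin_align(fa.sequence, revcomp(fb.sequence))
                hit = fwd
                if rev is not None and (hit is None or rev.bit_score > hit.bit_score):
                    hit = rev
                if hit is not None and hit.bit_score >= min_score:
                    table[(fa.fragment_id, fb.fragment_id)] = hit
        return table

    def best_partner(table, ids_a):
        best = {}
        for (qa, sb), hit in table.items():
            cur = best.get(qa)
            key = (hit.bit_score, hit.percent_identity)
            if (
                cur is None
                or key > cur[0]
                or (key == cur[0] and sb < cur[1])
            ):
                best[qa] = (key, sb, hit)
        return best

    fwd_table = all_hits(qf, rf)
    rev_table = all_hits(rf, qf)
    fwd_best = best_partner(fwd_table, qf)
    rev_best = best_partner(rev_table, rf)
    min_len = math.ceil(min_coverage * fragment_length)
    identities: List[float] = []
    for qa, (_, sb, fhit) in fwd_best.items():
        rb = rev_best.get(sb)
        if rb is None or rb[1] != qa:
            continue
        rhit = rb[2]
        if fhit.alignment_length < min_len or rhit.alignment_length < min_len:
            continue
        identities.extend([fhit.percent_identity, rhit.percent_identity])
    if not identities:
        return None
    return math.fsum(identities) / len(identities)


@pytest.fixture
def dp_oracle():
    return sw_oracle


@pytest.fixture
def ani_oracle():
    return brute_force_ani
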