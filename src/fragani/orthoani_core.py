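"""Reciprocal-best-hit orthology and the ANI average — the heart of the method.

Both genomes are fragmented; fragments are aligned in both directions
(query fragments vs reference fragments and vice versa); a fragment pair
is orthologous when each member is the other's best hit and both
directional alignments span at least 35% of the 1020-bp fragment length
(>= 357 columns at the defaults). The ANI is the arithmetic mean of the
directional identities of all reciprocal hits — both the forward and the
reverse identity of every pair enter the average with equal weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

from .alignment_backends import BackendSpec, Hit, align_fragments
from .fragmenting import (
    FragmentationParams,
    coverage_threshold,
    filter_ambiguous,
    fragment_genome,
)
from .genome_io import Genome

__all__ = [
    "OrthologPair",
    "ANIResult",
    "DegenerateGenomeError",
    "NoOrthologousFragmentsError",
    "best_hit_per_query",
    "reciprocal_orthologs",
    "compute_ani",
    "orthoani",
]

DEFAULT_MIN_COVERAGE = 0.35


class DegenerateGenomeError(ValueError):
    """A genome yields no usable fragments (too short or too ambiguous)."""


class NoOrthologousFragmentsError(RuntimeError):
    """No reciprocal best-hit pairs survive: the ANI is undefined, not 0."""


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocal best-hit fragment pair with both directional identities."""

    query_fragment: str
    reference_fragment: str
    forward_identity: float
    reverse_identity: float
    forward_alignment_length: int
    reverse_alignment_length: int


@dataclass(frozen=True)
class ANIResult:
    """Final ANI (0-100 scale) plus the bookkeeping behind it."""

    ani: float
    n_pairs: int
    n_query_fragments: int
    n_reference_fragments: int
    params: Dict[str, object] = field(default_factory=dict)


def best_hit_per_query(hits: Sequence[Hit]) -> Dict[str, Hit]:
    """One best hit per query: highest bit score, deterministic tie-breaks.

    Ties resolve by lower e-value, then higher percent identity, then
    lexicographically smallest subject id.
    """
    best: Dict[str, Hit] = {}
    for hit in hits:
        cur = best.get(hit.query_id)
        if cur is None or _rank(hit) > _rank(cur):
            best[hit.query_id] = hit
    return best


def _rank(hit: Hit):
    # subject_id negated lexicographically via tuple trick: compare with a
    # key where smaller id wins, so invert by using a reverse-sortable form.
    return (
        hit.bit_score,
        -hit.evalue,
        hit.percent_identity,
        _ReverseStr(hit.subject_id),
    )


class _ReverseStr(str):
    """String whose ordering is reversed, so max() prefers the smaller id."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other) -> bool:  # type: ignore[override]
        return str.__lt__(self, other)


def reciprocal_orthologs(
    forward_best: Dict[str, Hit],
    reverse_best: Dict[str, Hit],
    fragment_length: int = 1020,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> List[OrthologPair]:
    """Mutual-best pairs whose alignments satisfy the coverage rule.

    Pair (q, s) is emitted iff forward_best[q] hits s, reverse_best[s]
    hits q, and *both* directions' alignment lengths reach
    ceil(min_coverage x fragment_length) (non-strict "at least"). The
    denominator is the nominal fragment length — every retained fragment
    has exactly that length. Output is sorted by query fragment id.
    """
    min_len = coverage_threshold(fragment_length, min_coverage)
    pairs: List[OrthologPair] = []
    for q, fwd in forward_best.items():
        s = fwd.subject_id
        rev = reverse_best.get(s)
        if rev is None or rev.subject_id != q:
            continue
        if fwd.alignment_length < min_len or rev.alignment_length < min_len:
            continue
        pairs.append(
            OrthologPair(
                query_fragment=q,
                reference_fragment=s,
                forward_identity=fwd.percent_identity,
                reverse_identity=rev.percent_identity,
                forward_alignment_length=fwd.alignment_length,
                reverse_alignment_length=rev.alignment_length,
            )
        )
    pairs.sort(key=lambda p: p.query_fragment)
    return pairs


def compute_ani(pairs: Sequence[OrthologPair]) -> float:
    """Mean of the 2n directional identities over all reciprocal pairs.

    Uses a correctly-rounded sum (math.fsum), so the value does not depend
    on pair ordering — this is what makes ANI(A,B) == ANI(B,A) exact.
    """
    if not pairs:
        raise NoOrthologousFragmentsError("no orthologous fragments: ANI is undefined")
    identities = [p.forward_identity for p in pairs] + [p.reverse_identity for p in pairs]
    return math.fsum(identities) / len(identities)


def orthoani(
    query: Genome,
    reference: Genome,
    params: FragmentationParams | None = None,
    coverage: float = DEFAULT_MIN_COVERAGE,
    backend: BackendSpec | None = None,
) -> ANIResult:
    """Full fragment-based ANI between a query and a reference genome.

    Pipeline: fragment both genomes -> drop ambiguity-dominated fragments
    -> align in both directions -> take each direction's best hits ->
    keep reciprocal pairs passing the coverage rule -> average the
    directional identities.

    Raises
    ------
    DegenerateGenomeError
        If either genome yields zero usable fragments.
    NoOrthologousFragmentsError
        If no reciprocal pairs survive (genomes too divergent).
    """
    params = params or FragmentationParams()
    backend = backend or BackendSpec()
    q_frags = filter_ambiguous(fragment_genome(query, params), params)
    r_frags = filter_ambiguous(fragment_genome(reference, params), params)
    for genome, frags in ((query, q_frags), (reference, r_frags)):
        if not frags:
            raise DegenerateGenomeError(
                f"genome {genome.id!r} too short or too ambiguous: no usable fragments"
            )
    forward = align_fragments(q_frags, r_frags, backend)
    reverse = align_fragments(r_frags, q_frags, backend)
    pairs = reciprocal_orthologs(
        best_hit_per_query(forward),
        best_hit_per_query(reverse),
        fragment_length=params.fragment_length,
        min_coverage=coverage,
    )
    ani = compute_ani(pairs)
    return ANIResult(
        ani=ani,
        n_pairs=len(pairs),
        n_query_fragments=len(q_frags),
        n_reference_fragments=len(r_frags),
        params={
            "fragment_length": params.fragment_length,
            "max_ambiguous_fraction": params.max_ambiguous_fraction,
            "min_coverage": coverage,
            "backend": backend.kind,
        },
    )
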