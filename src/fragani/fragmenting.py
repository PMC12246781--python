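"""Partition genomes into fixed-length fragments and filter ambiguous ones.

The fragment-based ANI algorithm cuts both genomes into consecutive,
non-overlapping 1020-bp windows (per contig, offset 0); the trailing
remainder of each contig is discarded, as is any fragment in which more
than 80% of positions are ambiguous. All coordinates are 0-based
half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List

from .genome_io import Genome, UNAMBIGUOUS

__all__ = [
    "Fragment",
    "FragmentationParams",
    "fragment_genome",
    "filter_ambiguous",
    "count_fragments",
]

DEFAULT_FRAGMENT_LENGTH = 1020
DEFAULT_MAX_AMBIGUOUS_FRACTION = 0.80


@dataclass(frozen=True)
class FragmentationParams:
    """Fragment length (bp) and the ambiguity discard threshold.

    A fragment is discarded when its ambiguous fraction strictly exceeds
    ``max_ambiguous_fraction``; at exactly the threshold it is retained.
    """

    fragment_length: int = DEFAULT_FRAGMENT_LENGTH
    max_ambiguous_fraction: float = DEFAULT_MAX_AMBIGUOUS_FRACTION

    def __post_init__(self) -> None:
        if self.fragment_length < 1:
            raise ValueError("fragment_length must be >= 1")
        if not 0.0 <= self.max_ambiguous_fraction <= 1.0:
            raise ValueError("max_ambiguous_fraction must be in [0, 1]")


@dataclass(frozen=True)
class Fragment:
    """A fixed-length window of a contig with provenance coordinates.

    ``fragment_id`` is ``"<genome_id>|<contig_id>|<start>"`` — deterministic
    and collision-free, so hits from the two alignment directions can be
    joined by id alone. ``sequence`` is the uppercased contig slice
    ``[start:end)``.
    """

    fragment_id: str
    source_contig: str
    start: int
    end: int
    sequence: str


def fragment_genome(genome: Genome, params: FragmentationParams | None = None) -> List[Fragment]:
    """Cut each contig independently into full-length windows.

    Windows start at offset 0 and never span contig junctions; a contig
    shorter than ``fragment_length`` contributes nothing. Output order is
    contig order, then ascending start. Sequences are uppercased so the
    ambiguity filter and the aligners treat 'a' and 'A' identically.
    """
    params = params or FragmentationParams()
    L = params.fragment_length
    fragments: List[Fragment] = []
    for contig_id, seq in genome.contigs:
        seq = seq.upper()
        for start in range(0, len(seq) - L + 1, L):
            fragments.append(
                Fragment(
                    fragment_id=f"{genome.id}|{contig_id}|{start}",
                    source_contig=contig_id,
                    start=start,
                    end=start + L,
                    sequence=seq[start : start + L],
                )
            )
    return fragments


def ambiguous_count(sequence: str) -> int:
    """Number of positions that are not an unambiguous A/C/G/T.

    Any IUPAC degeneracy code (N, R, Y, ...) counts as ambiguous: the
    identity computation cannot score those positions as matches either.
    """
    return sum(1 for ch in sequence if ch not in UNAMBIGUOUS)


def filter_ambiguous(
    fragments: List[Fragment], params: FragmentationParams | None = None
) -> List[Fragment]:
    """Drop fragments whose ambiguous fraction strictly exceeds the threshold.

    The comparison is strict (``>``): a 1020-bp fragment with exactly 816
    ambiguous positions (80.0%) is retained. Relative order is preserved,
    and the operation is idempotent.
    """
    params = params or FragmentationParams()
    limit = params.max_ambiguous_fraction * params.fragment_length
    return [f for f in fragments if ambiguous_count(f.sequence) <= limit]


def count_fragments(genome: Genome, params: FragmentationParams | None = None) -> int:
    """Fragment count before ambiguity filtering: sum of floor(len/L) over contigs."""
    params = params or FragmentationParams()
    return sum(len(seq) // params.fragment_length for _, seq in genome.contigs)


def coverage_threshold(fragment_length: int, min_coverage: float) -> int:
    """Minimum alignment length (bp) for the orthology coverage rule.

    "At least 35% of the total length of the fragment" is read as a
    non-strict bound on whole columns: ceil(0.35 x 1020) = 357 bp at the
    defaults.
    """
    return math.ceil(min_coverage * fragment_length)
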