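"""Synthetic draft genomes and mutants of known divergence.

Every pipeline stage is testable without downloads: genomes are i.i.d.
nucleotide strings of configurable GC content, mutants apply point
substitutions (and optionally short geometric-length indels) at stated
per-base rates, and ambiguity blocks exercise the N filter. A
substitutions-only mutant at rate p has expected nucleotide identity
100(1-p) to its parent, giving ANI-recovery tests a closed-form oracle.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .genome_io import Genome

__all__ = ["MutationSpec", "random_genome", "mutate_genome", "inject_ambiguity"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class MutationSpec:
    """Per-base mutation rates for deriving a mutant genome."""

    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    indel_length_mean: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "insertion_rate", "deletion_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 0.5:
                raise ValueError(f"{name} must be in [0, 0.5)")
        if self.substitution_rate + self.insertion_rate + self.deletion_rate >= 1.0:
            raise ValueError("mutation rates must sum to < 1")
        if self.indel_length_mean < 1.0:
            raise ValueError("indel_length_mean must be >= 1")


def random_genome(
    n_contigs: int,
    contig_lengths: Sequence[int],
    gc: float = 0.5,
    seed: int = 0,
    genome_id: str | None = None,
) -> Genome:
    """i.i.d. random genome: P(G) = P(C) = gc/2, P(A) = P(T) = (1-gc)/2."""
    if n_contigs != len(contig_lengths):
        raise ValueError("n_contigs must equal len(contig_lengths)")
    if any(L < 1 for L in contig_lengths):
        raise ValueError("contig lengths must be positive")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc) / 2.0
    probs = np.array([at, gc / 2.0, gc / 2.0, at])
    contigs = []
    for i, L in enumerate(contig_lengths, start=1):
        codes = rng.choice(4, size=L, p=probs)
        contigs.append((f"contig{i}", _BASES[codes].tobytes().decode("ascii")))
    return Genome(id=genome_id or f"synthetic-{seed}", contigs=contigs)


def _substitute(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0.0:
        return codes
    mask = rng.random(codes.size) < rate
    n = int(mask.sum())
    if n:
        # uniform over the three *other* bases
        codes = codes.copy()
        codes[mask] = (codes[mask] + rng.integers(1, 4, size=n)) % 4
    return codes


def mutate_genome(genome: Genome, spec: MutationSpec) -> Genome:
    """Derive a mutant of known divergence; the input genome is untouched.

    Substitutions hit each base independently and change it to a uniformly
    chosen different base. Insertions/deletions fire per base at their
    rates with geometric lengths of mean ``indel_length_mean``
    (substitutions are applied first, on the original coordinates).
    Ambiguous positions are left as-is by substitution draws that hit them.
    """
    rng = np.random.default_rng(spec.seed)
    contigs = []
    for cid, seq in genome.contigs:
        codes = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        acgt = np.full(256, -1, dtype=np.int8)
        for i, b in enumerate("ACGT"):
            acgt[ord(b)] = i
        base_codes = acgt[codes]
        valid = base_codes >= 0
        new_codes = _substitute(
            np.where(valid, base_codes, 0).astype(np.int64), spec.substitution_rate, rng
        )
        out = np.where(valid, _BASES[new_codes], codes).astype(np.uint8)
        if spec.deletion_rate > 0.0 or spec.insertion_rate > 0.0:
            out = _apply_indels(out, spec, rng)
        contigs.append((cid, out.tobytes().decode("ascii")))
    return Genome(id=f"{genome.id}-mut", contigs=contigs)


def _apply_indels(codes: np.ndarray, spec: MutationSpec, rng: np.random.Generator) -> np.ndarray:
    p_geom = 1.0 / spec.indel_length_mean
    n = codes.size
    u = rng.random(n)
    del_sites = np.flatnonzero(u < spec.deletion_rate)
    ins_sites = np.flatnonzero(
        (u >= spec.deletion_rate) & (u < spec.deletion_rate + spec.insertion_rate)
    )
    events = sorted(
        [(int(pos), "del") for pos in del_sites] + [(int(pos), "ins") for pos in ins_sites]
    )
    pieces: List[np.ndarray] = []
    cursor = 0
    for pos, kind in events:
        if pos < cursor:  # swallowed by a previous deletion
            continue
        pieces.append(codes[cursor:pos])
        length = int(rng.geometric(p_geom))
        if kind == "del":
            cursor = min(n, pos + length)
        else:
            pieces.append(_BASES[rng.integers(0, 4, size=length)].astype(np.uint8))
            cursor = pos
    pieces.append(codes[cursor:])
    return np.concatenate(pieces) if pieces else codes


def inject_ambiguity(
    genome: Genome, block_length: int, n_blocks: int, seed: int = 0
) -> Genome:
    """Replace ``n_blocks`` random non-overlapping stretches with 'N'.

    Raises ``ValueError`` when the blocks cannot be placed without overlap
    (after a bounded number of rejection-sampling attempts).
    """
    if block_length < 1:
        raise ValueError("block_length must be >= 1")
    if n_blocks == 0:
        return Genome(id=genome.id, contigs=list(genome.contigs))
    rng = np.random.default_rng(seed)
    eligible = [
        (ci, len(seq) - block_length)
        for ci, (_, seq) in enumerate(genome.contigs)
        if len(seq) >= block_length
    ]
    if not eligible:
        raise ValueError("no contig is long enough for the requested block_length")
    placed: dict[int, List[int]] = {}
    attempts = 0
    max_attempts = 1000 * n_blocks
    while sum(len(v) for v in placed.values()) < n_blocks:
        if attempts >= max_attempts:
            raise ValueError(
                f"could not place {n_blocks} non-overlapping blocks of {block_length} bp"
            )
        attempts += 1
        ci, max_start = eligible[int(rng.integers(0, len(eligible)))]
        start = int(rng.integers(0, max_start + 1))
        if any(abs(start - s) < block_length for s in placed.get(ci, [])):
            continue
        placed.setdefault(ci, []).append(start)
    contigs = []
    for ci, (cid, seq) in enumerate(genome.contigs):
        if ci in placed:
            arr = bytearray(seq.encode("ascii"))
            for start in placed[ci]:
                arr[start : start + block_length] = b"N" * block_length
            seq = arr.decode("ascii")
        contigs.append((cid, seq))
    return Genome(id=genome.id, contigs=contigs)
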