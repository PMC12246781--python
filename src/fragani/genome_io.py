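"""Reading and writing genome assemblies as ordered contig collections.

A :class:`Genome` is the unit every ANI computation operates on: an
identified, ordered list of contigs. Draft assemblies and MAGs are
multi-contig; contig order is preserved exactly as found in the file so
that downstream fragment identifiers are reproducible.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, List, Tuple, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = ["Genome", "FastaFormatError", "read_fasta", "write_fasta"]

# IUPAC nucleotide one-letter codes (uppercase); '-' and '.' are not sequence.
IUPAC_NUCLEOTIDES = frozenset("ACGTUNRYSWKMBDHV")

#: Unambiguous bases; everything else in the IUPAC set counts as ambiguous.
UNAMBIGUOUS = frozenset("ACGT")


class FastaFormatError(ValueError):
    """Raised when a FASTA file violates the format or the Genome invariants."""


@dataclass
class Genome:
    """An identified set of contig sequences.

    Parameters
    ----------
    id:
        Text label for the assembly (defaults to the file stem on load).
    contigs:
        Ordered ``(contig_id, sequence)`` pairs. Contig ids must be unique
        and sequences non-empty, drawn from the IUPAC nucleotide alphabet.
    """

    id: str
    contigs: List[Tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for cid, seq in self.contigs:
            if cid in seen:
                raise FastaFormatError(f"duplicate contig id {cid!r} in genome {self.id!r}")
            seen.add(cid)
            if not seq:
                raise FastaFormatError(f"contig {cid!r} in genome {self.id!r} has empty sequence")

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)

    def contig_ids(self) -> List[str]:
        return [cid for cid, _ in self.contigs]

    def __iter__(self) -> Iterator[Tuple[str, str]]:
        return iter(self.contigs)


def _open_text(path: Union[str, Path]) -> io.TextIOBase:
    """Open plain or gzip-compressed text, sniffing by extension."""
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, "r", encoding="ascii")


def _validate_sequence(seq: str, contig_id: str, record_no: int) -> None:
    for ch in seq:
        if ch.upper() not in IUPAC_NUCLEOTIDES:
            raise FastaFormatError(
                f"non-IUPAC character {ch!r} in record {record_no} ({contig_id!r})"
            )


def read_fasta(path: Union[str, Path], genome_id: str | None = None) -> Genome:
    """Load a (possibly gzip-compressed) FASTA file into a :class:`Genome`.

    One contig per record, in file order. The contig id is the header token
    before the first whitespace; the description is dropped. Sequence case
    is preserved here (fragmenting uppercases before any computation).

    Raises
    ------
    FileNotFoundError
        If the path does not exist.
    FastaFormatError
        On an empty file, an empty record, a duplicate contig id, or a
        character outside the IUPAC nucleotide alphabet.
    """
    path = Path(path)
    if genome_id is None:
        name = path.name
        for ext in (".gz", ".fasta", ".fa", ".fna"):
            if name.endswith(ext):
                name = name[: -len(ext)]
        genome_id = name or str(path)
    contigs: List[Tuple[str, str]] = []
    with _open_text(path) as handle:
        for record_no, (header, seq) in enumerate(SimpleFastaParser(handle), start=1):
            contig_id = header.split()[0] if header.split() else ""
            if not contig_id:
                raise FastaFormatError(f"record {record_no} in {path} has an empty header")
            if not seq:
                raise FastaFormatError(f"record {contig_id!r} in {path} has an empty sequence")
            _validate_sequence(seq, contig_id, record_no)
            contigs.append((contig_id, seq))
    if not contigs:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return Genome(id=genome_id, contigs=contigs)


def write_fasta(genome: Genome, path: Union[str, Path], line_width: int = 60) -> None:
    """Write a genome to FASTA; ``read_fasta`` of the result reproduces it."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    path = Path(path)
    opener = gzip.open(path, "wt") if path.suffix == ".gz" else open(path, "w")
    with opener as handle:
        for cid, seq in genome.contigs:
            handle.write(f">{cid}\n")
            for i in range(0, len(seq), line_width):
                handle.write(seq[i : i + line_width] + "\n")
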