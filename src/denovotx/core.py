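"""Shared sequence types and small numeric helpers.

A :class:`Contig` is the unit of annotation throughout the toolkit: an
assembled DNA sequence (contig or scaffold) over the alphabet {A,C,G,T,N},
where runs of N mark unsequenced gaps introduced during scaffolding.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass(frozen=True)
class Contig:
    """An assembled contig or scaffold.

    Attributes
    ----------
    id : str
        Unique identifier within a contig set.
    seq : str
        Upper-case DNA over {A,C,G,T,N}.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at ``ndigits`` decimals.

    Python's builtin rounds half-to-even; reported decimals here use the
    half-up convention, which is the only one consistent with the printed
    SNP-frequency values this toolkit mirrors.
    """
    q = Decimal(1).scaleb(-ndigits)
    v = Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP)
    return float(v)


def read_fasta(source: str | TextIO) -> list[Contig]:
    """Read contigs from a FASTA file path or open text handle."""
    handle = open(source) if isinstance(source, str) else source
    try:
        return [Contig(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
    finally:
        if isinstance(source, str):
            handle.close()


def write_fasta(contigs: Iterable[Contig], dest: str | TextIO) -> None:
    """Write contigs as FASTA wrapped at 60 columns."""
    records = (SeqRecord(Seq(c.seq), id=c.id, description="") for c in contigs)
    if isinstance(dest, str):
        with open(dest, "w") as fh:
            SeqIO.write(records, fh, "fasta")
    else:
        SeqIO.write(records, dest, "fasta")


def fasta_text(contigs: Iterable[Contig]) -> str:
    buf = io.StringIO()
    write_fasta(contigs, buf)
    return buf.getvalue()


def as_lines(source: str | TextIO | Iterable[str]) -> Iterator[str]:
    """Yield lines from a path, open handle, text blob, or line iterable."""
    if isinstance(source, str):
        if "\n" in source or "\t" in source:
            yield from io.StringIO(source)
        else:
            with open(source) as fh:
                yield from fh
    else:
        yield from source
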