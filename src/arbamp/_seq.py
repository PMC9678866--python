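"""Low-level DNA string utilities shared across modules."""

from __future__ import annotations

import gzip
import re
from pathlib import Path
from typing import Iterable, Iterator, Tuple

from .errors import CatalogParseError, InvalidSequenceError

DNA_ALPHABET = "ACGT"
_DNA_SET = frozenset(DNA_ALPHABET)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC nucleotide codes -> set of concrete bases they stand for.
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, *, name: str = "sequence", allow_empty: bool = False) -> str:
    """Return ``seq`` uppercased, or raise :class:`InvalidSequenceError`.

    Only the strict A/C/G/T alphabet is accepted; lowercase input is
    normalised, anything else (including N) is rejected.
    """
    if not seq:
        if allow_empty:
            return seq
        raise InvalidSequenceError(f"{name} must be nonempty")
    upper = seq.upper()
    if not _DNA_SET.issuperset(upper):
        bad = sorted(set(upper) - _DNA_SET)
        raise InvalidSequenceError(f"{name} contains non-ACGT characters: {bad}")
    return upper


def iupac_regex(consensus: str, *, motif_id: str = "") -> re.Pattern[str]:
    """Compile an IUPAC consensus string into a regex over A/C/G/T."""
    parts = []
    for ch in consensus.upper():
        bases = IUPAC_CODES.get(ch)
        if bases is None:
            label = f" in motif {motif_id!r}" if motif_id else ""
            raise CatalogParseError(f"malformed IUPAC code {ch!r}{label}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


FastaRecords = Iterable[Tuple[str, str]]


def iter_fasta(source) -> Iterator[Tuple[str, str]]:
    """Yield ``(record_id, uppercase_sequence)`` from a FASTA source.

    ``source`` may be a path (optionally gzip-compressed) or an iterable of
    ``(id, sequence)`` pairs, which is handy for synthetic genomes that never
    touch disk.
    """
    if isinstance(source, (str, Path)):
        from Bio import SeqIO

        path = Path(source)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as handle:
            for rec in SeqIO.parse(handle, "fasta"):
                yield rec.id, str(rec.seq).upper()
    else:
        for seq_id, seq in source:
            yield seq_id, seq.upper()


def write_fasta(records: FastaRecords, path, *, width: int = 70) -> None:
    """Write records as uncompressed FASTA with fixed line width."""
    with open(path, "w") as fh:
        for seq_id, seq in records:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
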