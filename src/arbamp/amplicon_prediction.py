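"""Primer-construct assembly and exact-match in-silico PCR.

A construct is adapter + N-spacer + target; only the target portion primes.
Amplicons are every (+ site, - site) ordered pair on the same sequence whose
primer-5'-to-primer-5' product length falls inside the allowed size window.
"""

from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ._seq import iter_fasta, revcomp, validate_dna
from .errors import CatalogParseError, InvalidParameterError

__all__ = [
    "PrimerConstruct",
    "PrimingSite",
    "Amplicon",
    "CocktailSpec",
    "AmpliconSummary",
    "assemble_construct",
    "find_priming_sites",
    "predict_amplicons",
    "amplicon_summary",
    "write_bed",
    "write_amplicon_fasta",
]

# Product-size windows: gel-selection default and SPRI library preset.
DEFAULT_MIN_LEN = 500
DEFAULT_MAX_LEN = 2000
SPRI_MIN_LEN = 600
SPRI_MAX_LEN = 1000


def assemble_construct(adapter: str, spacer_len: int, target: str) -> str:
    """Full primer string: adapter, ``spacer_len`` N bases, then target."""
    adapter = validate_dna(adapter, name="adapter")
    target = validate_dna(target, name="target")
    if spacer_len < 0:
        raise InvalidParameterError(f"spacer_len must be >= 0, got {spacer_len}")
    return adapter + "N" * spacer_len + target


@dataclass(frozen=True)
class PrimerConstruct:
    name: str
    adapter: str
    target: str
    spacer_len: int = 7

    def __post_init__(self):
        assemble_construct(self.adapter, self.spacer_len, self.target)  # validates

    @property
    def full_sequence(self) -> str:
        return assemble_construct(self.adapter, self.spacer_len, self.target)


@dataclass(frozen=True, order=True)
class PrimingSite:
    """Half-open genomic interval matching one construct's target."""

    seq_id: str
    start: int
    end: int
    strand: str
    primer: str


@dataclass(frozen=True, order=True)
class Amplicon:
    seq_id: str
    start: int
    end: int
    forward_primer: str
    reverse_primer: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CocktailSpec:
    """A set of constructs, each usable as forward and reverse primer."""

    constructs: tuple[PrimerConstruct, ...]
    min_len: int = DEFAULT_MIN_LEN
    max_len: int = DEFAULT_MAX_LEN
    max_mismatch: int = 0

    def __post_init__(self):
        if not self.constructs:
            raise InvalidParameterError("cocktail requires at least one construct")
        if not 0 < self.min_len <= self.max_len:
            raise InvalidParameterError(
                f"need 0 < min_len <= max_len, got {self.min_len}, {self.max_len}"
            )
        if self.max_mismatch < 0:
            raise InvalidParameterError("max_mismatch must be >= 0")

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "CocktailSpec":
        """TSV columns: name, adapter, spacer_len, target ('#' comments ok)."""
        constructs = []
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.lower().startswith("name\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise CatalogParseError(
                    f"{path}: line {lineno}: expected 4 tab-separated fields"
                )
            name, adapter, spacer, target = fields
            try:
                spacer_len = int(spacer)
            except ValueError as exc:
                raise CatalogParseError(
                    f"{path}: line {lineno}: spacer_len not an integer"
                ) from exc
            constructs.append(
                PrimerConstruct(
                    name=name, adapter=adapter, spacer_len=spacer_len, target=target
                )
            )
        return cls(constructs=tuple(constructs), **kwargs)


def _exact_matches(haystack: str, needle: str) -> Iterable[int]:
    pos = haystack.find(needle)
    while pos != -1:
        yield pos
        pos = haystack.find(needle, pos + 1)


def _mismatch_matches(haystack: str, needle: str, max_mismatch: int) -> Iterable[int]:
    # naive Hamming scan; only used when max_mismatch > 0
    n, m = len(haystack), len(needle)
    for i in range(n - m + 1):
        mism = 0
        for a, b in zip(haystack[i : i + m], needle):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            yield i


def find_priming_sites(genome, cocktail: CocktailSpec) -> list[PrimingSite]:
    """Every position matching a construct's target on either strand.

    Overlapping and repeated matches are all reported.  The result is sorted
    by (seq_id, start, strand, primer) for determinism.
    """
    sites: list[PrimingSite] = []
    n_records = 0
    for seq_id, seq in iter_fasta(genome):
        n_records += 1
        for construct in cocktail.constructs:
            target = construct.target
            for strand, probe in (("+", target), ("-", revcomp(target))):
                if cocktail.max_mismatch == 0:
                    matches = _exact_matches(seq, probe)
                else:
                    matches = _mismatch_matches(seq, probe, cocktail.max_mismatch)
                for pos in matches:
                    sites.append(
                        PrimingSite(
                            seq_id=seq_id,
                            start=pos,
                            end=pos + len(target),
                            strand=strand,
                            primer=construct.name,
                        )
                    )
    if n_records == 0:
        raise InvalidParameterError("genome source yielded no records")
    sites.sort(key=lambda s: (s.seq_id, s.start, s.strand, s.primer))
    return sites


def predict_amplicons(
    sites: Sequence[PrimingSite], spec: CocktailSpec
) -> list[Amplicon]:
    """All (+, -) site pairs on one sequence with an in-window product length.

    The product interval runs from the + site's 5' end (its start) to the
    - site's 5' end (its end), so both priming sites are inside the product.
    No competition model: nested and overlapping pairs all count.
    """
    by_seq: dict[str, tuple[list[PrimingSite], list[PrimingSite]]] = {}
    for site in sites:
        plus, minus = by_seq.setdefault(site.seq_id, ([], []))
        (plus if site.strand == "+" else minus).append(site)
    amplicons: list[Amplicon] = []
    for seq_id, (plus_sites, minus_sites) in by_seq.items():
        minus_sites.sort(key=lambda s: s.end)
        ends = [s.end for s in minus_sites]
        for p in plus_sites:
            lo = bisect.bisect_left(ends, p.start + spec.min_len)
            hi = bisect.bisect_right(ends, p.start + spec.max_len)
            for m in minus_sites[lo:hi]:
                amplicons.append(
                    Amplicon(
                        seq_id=seq_id,
                        start=p.start,
                        end=m.end,
                        forward_primer=p.primer,
                        reverse_primer=m.primer,
                    )
                )
    amplicons.sort(key=lambda a: (a.seq_id, a.start, a.end))
    return amplicons


@dataclass(frozen=True)
class AmpliconSummary:
    total: int
    per_pair: dict
    length_histogram: dict
    bin_width: int

    def __post_init__(self):
        if sum(self.per_pair.values()) != self.total:
            raise InvalidParameterError("pair counts do not sum to total")


def amplicon_summary(
    amplicons: Sequence[Amplicon], *, bin_width: int = 100
) -> AmpliconSummary:
    """Counts per primer pair plus a binned product-length histogram."""
    per_pair: Counter = Counter()
    hist: Counter = Counter()
    for a in amplicons:
        per_pair[(a.forward_primer, a.reverse_primer)] += 1
        hist[(a.length // bin_width) * bin_width] += 1
    return AmpliconSummary(
        total=len(amplicons),
        per_pair=dict(per_pair),
        length_histogram=dict(sorted(hist.items())),
        bin_width=bin_width,
    )


def write_bed(amplicons: Sequence[Amplicon], path) -> None:
    """BED6: name = forward|reverse primer pair, score = product length."""
    with open(path, "w") as fh:
        for a in amplicons:
            fh.write(
                f"{a.seq_id}\t{a.start}\t{a.end}\t"
                f"{a.forward_primer}|{a.reverse_primer}\t{a.length}\t+\n"
            )


def write_amplicon_fasta(amplicons: Sequence[Amplicon], genome, path) -> None:
    seqs = {seq_id: seq for seq_id, seq in iter_fasta(genome)}
    with open(path, "w") as fh:
        for a in amplicons:
            fh.write(
                f">{a.seq_id}:{a.start}-{a.end} {a.forward_primer}|{a.reverse_primer}\n"
            )
            fh.write(seqs[a.seq_id][a.start : a.end] + "\n")
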