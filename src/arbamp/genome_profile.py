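"""Per-species k-mer occurrence profiles and frequency-grade stratification."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Set

from ._seq import _DNA_SET, iter_fasta, revcomp
from .errors import ArbampError, InvalidParameterError
from .primer_filters import Grade, GradeBoundaries, grade_of

__all__ = [
    "SpeciesKmerProfile",
    "GradeProfile",
    "count_kmers",
    "stratify",
    "concordant_kmers",
    "write_profile_tsv",
    "read_profile_tsv",
    "write_grades_tsv",
]


@dataclass(frozen=True)
class SpeciesKmerProfile:
    """Occurrence counts of every observed k-mer in one species' genome."""

    species_id: str
    k: int
    counts: Mapping[str, int]
    total_windows: int

    def __post_init__(self):
        if self.k < 1:
            raise InvalidParameterError("k must be >= 1")
        if any(len(kmer) != self.k for kmer in self.counts):
            raise InvalidParameterError("profile keys must all have length k")
        if sum(self.counts.values()) > self.total_windows:
            raise InvalidParameterError("counts exceed total_windows")

    def count(self, kmer: str) -> int:
        return self.counts.get(kmer, 0)


@dataclass(frozen=True)
class GradeProfile:
    """Frequency grade of every observed k-mer; absent k-mers are LOW."""

    species_id: str
    k: int
    grades: Mapping[str, str]
    boundaries: GradeBoundaries = field(default_factory=GradeBoundaries)

    def grade(self, kmer: str) -> str:
        return self.grades.get(kmer, Grade.LOW)


def count_kmers(
    genome,
    k: int,
    *,
    species_id: str = "unknown",
    both_strands: bool = False,
) -> SpeciesKmerProfile:
    """Count overlapping k-length windows over a FASTA source.

    Counting is forward-strand only by default, matching the convention of
    per-record oligonucleotide frequency counters.  Windows containing any
    non-ACGT character are skipped and excluded from ``total_windows``;
    windows never span record boundaries.
    """
    if k < 1:
        raise InvalidParameterError(f"k must be >= 1, got {k}")
    counts: Counter[str] = Counter()
    total = 0
    n_records = 0
    for _, seq in iter_fasta(genome):
        n_records += 1
        strands = [seq, revcomp(seq)] if both_strands else [seq]
        for s in strands:
            n = len(s)
            last_bad = -1
            for i, ch in enumerate(s):
                if ch not in _DNA_SET:
                    last_bad = i
                if i >= k - 1 and last_bad <= i - k:
                    counts[s[i - k + 1 : i + 1]] += 1
                    total += 1
    if n_records == 0:
        raise ArbampError("empty or unreadable FASTA source")
    return SpeciesKmerProfile(
        species_id=species_id, k=k, counts=dict(counts), total_windows=total
    )


def stratify(
    profile: SpeciesKmerProfile, boundaries: GradeBoundaries | None = None
) -> GradeProfile:
    """Map every observed k-mer to its frequency grade; zero counts are LOW."""
    boundaries = boundaries or GradeBoundaries()
    grades = {
        kmer: grade_of(count, boundaries) for kmer, count in profile.counts.items()
    }
    return GradeProfile(
        species_id=profile.species_id,
        k=profile.k,
        grades=grades,
        boundaries=boundaries,
    )


def concordant_kmers(
    profiles: Sequence[GradeProfile], threshold: float = 0.8
) -> Set[str]:
    """k-mers whose modal grade strictly exceeds ``threshold`` of the species.

    Absent k-mers count as LOW in each species, so the universe scanned is
    the union of observed k-mers (anything observed nowhere is trivially
    concordant-LOW and uninteresting to enumerate).
    """
    if not profiles:
        raise InvalidParameterError("profiles must be nonempty")
    ks = {p.k for p in profiles}
    if len(ks) != 1:
        raise InvalidParameterError(f"profiles mix k values: {sorted(ks)}")
    bounds = {p.boundaries for p in profiles}
    if len(bounds) != 1:
        raise InvalidParameterError("profiles mix grade boundaries")
    if not 0 < threshold < 1:
        raise InvalidParameterError(f"threshold must be in (0,1), got {threshold}")
    n = len(profiles)
    universe: set[str] = set()
    for p in profiles:
        universe.update(p.grades)
    result = set()
    for kmer in universe:
        counts = Counter(p.grade(kmer) for p in profiles)
        if max(counts.values()) > threshold * n:
            result.add(kmer)
    return result


# ---------------------------------------------------------------------------
# TSV serialization (header comments carry the profile metadata)


def write_profile_tsv(profile: SpeciesKmerProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#species_id={profile.species_id}\n")
        fh.write(f"#k={profile.k}\n")
        fh.write(f"#total_windows={profile.total_windows}\n")
        fh.write("kmer\tcount\n")
        for kmer in sorted(profile.counts):
            fh.write(f"{kmer}\t{profile.counts[kmer]}\n")


def read_profile_tsv(path) -> SpeciesKmerProfile:
    meta: dict[str, str] = {}
    counts: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key] = value
            elif line != "kmer\tcount":
                kmer, count = line.split("\t")
                counts[kmer] = int(count)
    try:
        return SpeciesKmerProfile(
            species_id=meta["species_id"],
            k=int(meta["k"]),
            counts=counts,
            total_windows=int(meta["total_windows"]),
        )
    except KeyError as exc:
        raise ArbampError(f"profile TSV {path} missing header field {exc}") from exc


def write_grades_tsv(grade_profile: GradeProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#species_id={grade_profile.species_id}\n")
        fh.write(f"#k={grade_profile.k}\n")
        fh.write(f"#low_upper={grade_profile.boundaries.low_upper}\n")
        fh.write(f"#high_lower={grade_profile.boundaries.high_lower}\n")
        fh.write("kmer\tgrade\n")
        for kmer in sorted(grade_profile.grades):
            fh.write(f"{kmer}\t{grade_profile.grades[kmer]}\n")


def read_grades_tsv(path) -> GradeProfile:
    meta: dict[str, str] = {}
    grades: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key] = value
            elif line != "kmer\tgrade":
                kmer, grade = line.split("\t")
                grades[kmer] = grade
    try:
        return GradeProfile(
            species_id=meta["species_id"],
            k=int(meta["k"]),
            grades=grades,
            boundaries=GradeBoundaries(
                low_upper=int(meta["low_upper"]), high_lower=int(meta["high_lower"])
            ),
        )
    except KeyError as exc:
        raise ArbampError(f"grades TSV {path} missing header field {exc}") from exc
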