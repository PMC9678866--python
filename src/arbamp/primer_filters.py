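"""Candidate priming k-mer enumeration and the five-stage exclusion cascade.

The cascade enumerates every k-mer, then drops candidates that contain simple
sequence repeats, match a functional-motif catalog, show taxon-dependent
occurrence-frequency grades across reference genomes, or can self-pair into
primer dimers.  Survivors can be truncated into shorter primers by prefix.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from ._seq import DNA_ALPHABET, iupac_regex, revcomp, validate_dna
from .errors import CatalogParseError, ConfigurationError, InvalidParameterError

__all__ = [
    "KmerCatalog",
    "SsrPolicy",
    "MotifEntry",
    "MotifCatalog",
    "GradeBoundaries",
    "Grade",
    "SelfCompPolicy",
    "Verdict",
    "ConcordanceResult",
    "PrimerCandidate",
    "DesignConfig",
    "DesignResult",
    "enumerate_kmers",
    "ssr_filter",
    "motif_filter",
    "grade_of",
    "concordance_filter",
    "self_complementarity_filter",
    "derive_short_primers",
    "run_design_pipeline",
    "write_candidates_tsv",
]

MAX_K = 16

# Illumina-derived adapter halves used on the forward/reverse constructs.
DEFAULT_ADAPTER_FORWARD = "CGCTCTTCCGATCT"
DEFAULT_ADAPTER_REVERSE = "TGCTCTTCCGATCT"


@dataclass(frozen=True)
class Verdict:
    """Outcome of one filter on one sequence."""

    passed: bool
    evidence: Optional[str] = None

    def __post_init__(self):
        if not self.passed and not self.evidence:
            raise InvalidParameterError("failing verdict requires evidence")

    @property
    def status(self) -> str:
        return "pass" if self.passed else "fail"


PASS = Verdict(True)


def _read_text(source) -> str:
    """Accept a path, an open handle, or raw multi-line text."""
    if hasattr(source, "read"):
        return source.read()
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str) and "\n" not in source:
        return Path(source).read_text()
    return str(source)


@dataclass(frozen=True)
class KmerCatalog:
    """An ordered, duplicate-free collection of k-mers of a common length."""

    k: int
    sequences: tuple[str, ...]

    def __post_init__(self):
        if self.k < 1:
            raise InvalidParameterError(f"k must be >= 1, got {self.k}")
        seqs = self.sequences
        if any(len(s) != self.k for s in seqs):
            raise InvalidParameterError(f"all sequences must have length {self.k}")
        if not set("".join(seqs)) <= set(DNA_ALPHABET) and seqs:
            raise InvalidParameterError("sequences must be uppercase A/C/G/T")
        if len(set(seqs)) != len(seqs):
            raise InvalidParameterError("duplicate sequences in catalog")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def __contains__(self, item) -> bool:
        return item in set(self.sequences)

    @classmethod
    def _trusted(cls, k: int, sequences: tuple[str, ...]) -> "KmerCatalog":
        # bypasses validation for catalogs correct by construction
        obj = object.__new__(cls)
        object.__setattr__(obj, "k", k)
        object.__setattr__(obj, "sequences", sequences)
        return obj


def enumerate_kmers(k: int) -> KmerCatalog:
    """All ``4**k`` k-mers over A/C/G/T in lexicographic order.

    ``k`` is capped at 16 to keep the full enumeration tractable.
    """
    if not isinstance(k, int) or not 1 <= k <= MAX_K:
        raise InvalidParameterError(f"k must be an integer in [1, {MAX_K}], got {k!r}")
    seqs = tuple("".join(p) for p in itertools.product(DNA_ALPHABET, repeat=k))
    return KmerCatalog._trusted(k, seqs)


# ---------------------------------------------------------------------------
# Simple-sequence-repeat filter


@dataclass(frozen=True)
class SsrPolicy:
    """What counts as a disqualifying simple sequence repeat.

    A mononucleotide run strictly longer than ``max_mono_run`` fails; a
    tandem repeat of a unit of length 2-4 repeated at least
    ``min_repeats_by_unit[len(unit)]`` times fails; any ``extra_motifs``
    entry occurring as a substring on either strand fails.
    """

    max_mono_run: int = 5
    min_repeats_by_unit: Mapping[int, int] = field(
        default_factory=lambda: {2: 3, 3: 3, 4: 2}
    )
    extra_motifs: tuple[str, ...] = ()

    def __post_init__(self):
        if self.max_mono_run < 1:
            raise InvalidParameterError("max_mono_run must be >= 1")
        for unit_len, reps in self.min_repeats_by_unit.items():
            if unit_len not in (2, 3, 4):
                raise InvalidParameterError("repeat unit lengths must be in {2,3,4}")
            if reps < 2:
                raise InvalidParameterError("repeat-count thresholds must be >= 2")
        for m in self.extra_motifs:
            validate_dna(m, name="extra_motif")


def _longest_mono_run(seq: str) -> tuple[int, str, int]:
    """(run_length, base, start) of the longest homopolymer run."""
    best_len, best_base, best_pos = 0, "", -1
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i > best_len:
            best_len, best_base, best_pos = j - i, seq[i], i
        i = j
    return best_len, best_base, best_pos


def _max_tandem(seq: str, unit_len: int) -> tuple[int, str, int]:
    """(repeat_count, unit, start) of the best tandem array of ``unit_len``-mers."""
    best = (0, "", -1)
    n = len(seq)
    for i in range(n - unit_len + 1):
        unit = seq[i : i + unit_len]
        count = 1
        j = i + unit_len
        while seq[j : j + unit_len] == unit:
            count += 1
            j += unit_len
        if count > best[0]:
            best = (count, unit, i)
    return best


def ssr_filter(seq: str, policy: SsrPolicy | None = None) -> Verdict:
    """Fail sequences containing simple sequence repeats.

    Checks, in order: mononucleotide runs, tandem repeats of units of
    length 2-4, and explicit extra motifs (either strand).
    """
    policy = policy or SsrPolicy()
    seq = validate_dna(seq)
    run_len, base, pos = _longest_mono_run(seq)
    if run_len > policy.max_mono_run:
        return Verdict(False, f"mononucleotide run {base}x{run_len} at {pos}")
    for unit_len in sorted(policy.min_repeats_by_unit):
        threshold = policy.min_repeats_by_unit[unit_len]
        count, unit, pos = _max_tandem(seq, unit_len)
        if count >= threshold:
            return Verdict(False, f"tandem repeat unit={unit} repeats={count} at {pos}")
    for motif in policy.extra_motifs:
        for strand, probe in (("+", motif), ("-", revcomp(motif))):
            pos = seq.find(probe)
            if pos != -1:
                return Verdict(
                    False, f"extra motif {motif} strand={strand} at {pos}"
                )
    return PASS


# ---------------------------------------------------------------------------
# Functional-motif filter


@dataclass(frozen=True)
class MotifEntry:
    """One motif: identifier plus IUPAC consensus (PFM kept if available)."""

    motif_id: str
    consensus: str
    pfm: Optional[tuple[tuple[float, ...], ...]] = None  # rows A, C, G, T

    def __post_init__(self):
        if not self.motif_id:
            raise CatalogParseError("motif entry requires an identifier")
        if not self.consensus:
            raise CatalogParseError(f"motif {self.motif_id}: empty consensus")
        iupac_regex(self.consensus, motif_id=self.motif_id)  # validates codes


@dataclass(frozen=True)
class MotifCatalog:
    motifs: tuple[MotifEntry, ...] = ()
    scan_both_strands: bool = True

    def __post_init__(self):
        ids = [m.motif_id for m in self.motifs]
        if len(set(ids)) != len(ids):
            raise CatalogParseError("duplicate motif identifiers in catalog")

    @classmethod
    def from_consensus_lines(cls, source, **kwargs) -> "MotifCatalog":
        """Plain text: one consensus per line, optional ``id<TAB>consensus``."""
        text = _read_text(source)
        motifs = []
        for i, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 2:
                motif_id, consensus = fields[0], fields[1]
            else:
                motif_id, consensus = f"motif{i}", fields[0]
            motifs.append(MotifEntry(motif_id=motif_id, consensus=consensus.upper()))
        return cls(motifs=tuple(motifs), **kwargs)

    @classmethod
    def from_jaspar(cls, source, *, consensus_min_freq: float = 0.25, **kwargs) -> "MotifCatalog":
        """Read JASPAR PFM text (``>ID NAME`` header + 4 base rows).

        The consensus letter of each column is the IUPAC union of bases whose
        relative frequency is at least ``consensus_min_freq``.
        """
        text = _read_text(source)
        motifs = []
        header = None
        rows: dict[str, list[float]] = {}
        lines = [ln for ln in text.splitlines() if ln.strip()]

        def flush():
            if header is None:
                return
            if set(rows) != {"A", "C", "G", "T"}:
                raise CatalogParseError(f"motif {header}: expected 4 base rows A/C/G/T")
            lens = {len(v) for v in rows.values()}
            if len(lens) != 1:
                raise CatalogParseError(f"motif {header}: ragged PFM rows")
            pfm = tuple(tuple(rows[b]) for b in "ACGT")
            motifs.append(
                MotifEntry(
                    motif_id=header,
                    consensus=_pfm_consensus(pfm, consensus_min_freq),
                    pfm=pfm,
                )
            )

        for line in lines:
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0]
                rows = {}
            else:
                if header is None:
                    raise CatalogParseError("PFM rows before any '>' header")
                stripped = line.replace("[", " ").replace("]", " ").split()
                base = stripped[0].upper()
                if base not in "ACGT":
                    raise CatalogParseError(f"motif {header}: unexpected row label {base!r}")
                try:
                    rows[base] = [float(x) for x in stripped[1:]]
                except ValueError as exc:
                    raise CatalogParseError(f"motif {header}: non-numeric PFM value") from exc
        flush()
        return cls(motifs=tuple(motifs), **kwargs)


_IUPAC_FROM_BASES = {
    frozenset(bases): code
    for code, bases in {
        "A": "A", "C": "C", "G": "G", "T": "T",
        "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
        "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    }.items()
}


def _pfm_consensus(pfm: tuple[tuple[float, ...], ...], min_freq: float) -> str:
    letters = []
    ncol = len(pfm[0])
    for col in range(ncol):
        counts = [pfm[row][col] for row in range(4)]
        total = sum(counts) or 1.0
        chosen = frozenset(
            base for base, c in zip("ACGT", counts) if c / total >= min_freq
        )
        if not chosen:  # all below threshold -> take the max base
            chosen = frozenset({"ACGT"[counts.index(max(counts))]})
        letters.append(_IUPAC_FROM_BASES[chosen])
    return "".join(letters)


def motif_filter(seq: str, catalog: MotifCatalog) -> Verdict:
    """Fail if any catalog consensus matches ``seq`` (IUPAC-aware).

    Motifs longer than ``seq`` are skipped.  With ``scan_both_strands`` the
    reverse complement of the sequence is searched as well.  An empty catalog
    trivially passes, so an unconfigured motif stage is a no-op.
    """
    seq = validate_dna(seq)
    strands = [("+", seq)]
    if catalog.scan_both_strands:
        strands.append(("-", revcomp(seq)))
    for entry in catalog.motifs:
        if len(entry.consensus) > len(seq):
            continue
        pattern = iupac_regex(entry.consensus, motif_id=entry.motif_id)
        for strand, subject in strands:
            m = pattern.search(subject)
            if m:
                return Verdict(
                    False,
                    f"motif {entry.motif_id} strand={strand} at {m.start()}",
                )
    return PASS


# ---------------------------------------------------------------------------
# Frequency grades and taxon concordance


class Grade:
    LOW = "LOW"
    MID = "MID"
    HIGH = "HIGH"


@dataclass(frozen=True)
class GradeBoundaries:
    """count < low_upper -> LOW; low_upper <= count <= high_lower -> MID; else HIGH."""

    low_upper: int = 100
    high_lower: int = 1000

    def __post_init__(self):
        if not 0 < self.low_upper <= self.high_lower:
            raise InvalidParameterError(
                f"need 0 < low_upper <= high_lower, got {self.low_upper}, {self.high_lower}"
            )


def grade_of(count: int, boundaries: GradeBoundaries | None = None) -> str:
    """Frequency grade of an occurrence count under the stated boundaries."""
    boundaries = boundaries or GradeBoundaries()
    if count < 0:
        raise InvalidParameterError(f"count must be >= 0, got {count}")
    if count < boundaries.low_upper:
        return Grade.LOW
    if count <= boundaries.high_lower:
        return Grade.MID
    return Grade.HIGH


@dataclass(frozen=True)
class ConcordanceResult:
    keep: bool
    modal_grade: str
    modal_count: int
    n_species: int


def concordance_filter(
    grades_per_species: Sequence[str], threshold: float = 0.8
) -> ConcordanceResult:
    """Keep a k-mer iff its modal grade covers strictly more than
    ``threshold`` of the species.

    Ties between modal grades take the (shared) maximum count; the verdict
    does not depend on which tied grade is reported.
    """
    if not grades_per_species:
        raise InvalidParameterError("grades_per_species must be nonempty")
    if not 0 < threshold < 1:
        raise InvalidParameterError(f"threshold must be in (0,1), got {threshold}")
    counts = Counter(grades_per_species)
    modal_grade, modal_count = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    keep = modal_count > threshold * len(grades_per_species)
    return ConcordanceResult(
        keep=keep,
        modal_grade=modal_grade,
        modal_count=modal_count,
        n_species=len(grades_per_species),
    )


# ---------------------------------------------------------------------------
# Self-complementarity (primer-dimer) filter


@dataclass(frozen=True)
class SelfCompPolicy:
    """String-based primer-dimer screen.

    Two rules fail a target: (i) with ``end_dinucleotide_check``, a
    3'-terminal dinucleotide that is its own reverse complement (AT/TA/GC/CG)
    — such an end can seed a 3'-3' extension dimer against any copy of the
    primer; (ii) a ``window_check_len`` window of the target whose reverse
    complement occurs elsewhere in the evaluated sequence set: at a
    non-overlapping offset of the target itself (``self_only`` scope), or
    additionally anywhere in the adapters and the other cocktail targets
    (``pairwise_cocktail`` scope).
    """

    adapter_forward: str = DEFAULT_ADAPTER_FORWARD
    adapter_reverse: str = DEFAULT_ADAPTER_REVERSE
    end_dinucleotide_check: bool = True
    window_check_len: int = 3
    scope: str = "self_only"

    def __post_init__(self):
        validate_dna(self.adapter_forward, name="adapter_forward", allow_empty=True)
        validate_dna(self.adapter_reverse, name="adapter_reverse", allow_empty=True)
        if self.window_check_len < 2:
            raise InvalidParameterError("window_check_len must be >= 2")
        if self.scope not in ("self_only", "pairwise_cocktail"):
            raise InvalidParameterError(f"unknown scope {self.scope!r}")


def self_complementarity_filter(
    target: str,
    policy: SelfCompPolicy | None = None,
    cocktail_context: Iterable[str] | None = None,
) -> Verdict:
    """Screen one priming target for dimer-forming self-complementarity."""
    policy = policy or SelfCompPolicy()
    target = validate_dna(target, name="target")

    if policy.end_dinucleotide_check and len(target) >= 2:
        dinuc = target[-2:]
        if revcomp(dinuc) == dinuc:
            return Verdict(
                False, f"3'-terminal dinucleotide {dinuc} is self-complementary"
            )

    w = policy.window_check_len
    if len(target) >= w:
        others: list[tuple[str, str]] = []
        if policy.scope == "pairwise_cocktail":
            if policy.adapter_forward:
                others.append(("adapter_forward", policy.adapter_forward))
            if policy.adapter_reverse:
                others.append(("adapter_reverse", policy.adapter_reverse))
            for other in cocktail_context or ():
                other = validate_dna(other, name="cocktail target")
                if other != target:
                    others.append((f"target {other}", other))
        for i in range(len(target) - w + 1):
            window = target[i : i + w]
            rc = revcomp(window)
            j = target.find(rc)
            while j != -1:
                if j + w <= i or j >= i + w:  # non-overlapping only
                    return Verdict(
                        False,
                        f"window {window} at {i} pairs with {rc} at {j}",
                    )
                j = target.find(rc, j + 1)
            for label, other in others:
                pos = other.find(rc)
                if pos != -1:
                    return Verdict(
                        False,
                        f"window {window} at {i} pairs with {rc} in {label} at {pos}",
                    )
    return PASS


# ---------------------------------------------------------------------------
# Short-primer derivation and the full pipeline


def derive_short_primers(catalog: KmerCatalog, m: int) -> KmerCatalog:
    """Deduplicated ``m``-base prefixes of every catalog member."""
    if m >= catalog.k:
        raise InvalidParameterError(f"m must be < k ({catalog.k}), got {m}")
    if m < 1:
        raise InvalidParameterError(f"m must be >= 1, got {m}")
    seen: dict[str, None] = {}
    for seq in catalog.sequences:
        seen.setdefault(seq[:m])
    return KmerCatalog._trusted(m, tuple(seen))


@dataclass(frozen=True)
class PrimerCandidate:
    """A k-mer with one recorded verdict per applied filter."""

    target: str
    verdicts: Mapping[str, Verdict]

    @property
    def surviving(self) -> bool:
        return all(v.passed for v in self.verdicts.values())


@dataclass(frozen=True)
class DesignConfig:
    k: int = 10
    short_k: Optional[int] = 7
    ssr_policy: SsrPolicy = field(default_factory=SsrPolicy)
    motif_catalog: Optional[MotifCatalog] = None
    grade_profiles: tuple = ()  # genome_profile.GradeProfile instances
    concordance_threshold: float = 0.8
    self_comp_policy: SelfCompPolicy = field(default_factory=SelfCompPolicy)


@dataclass(frozen=True)
class DesignResult:
    candidates: tuple[PrimerCandidate, ...]
    survivors: KmerCatalog
    short_primers: Optional[KmerCatalog]


def run_design_pipeline(config: DesignConfig) -> DesignResult:
    """Run the full exclusion cascade and derive short primers.

    Every filter verdict is recorded for every k-mer, so the surviving set is
    by construction independent of filter order.
    """
    profiles = tuple(config.grade_profiles)
    for p in profiles:
        if p.k != config.k:
            raise ConfigurationError(
                f"grade profile {p.species_id!r} has k={p.k}, pipeline k={config.k}"
            )
    catalog = enumerate_kmers(config.k)
    candidates = []
    for kmer in catalog:
        verdicts: dict[str, Verdict] = {"ssr": ssr_filter(kmer, config.ssr_policy)}
        if config.motif_catalog is not None:
            verdicts["motif"] = motif_filter(kmer, config.motif_catalog)
        if profiles:
            grades = [p.grade(kmer) for p in profiles]
            res = concordance_filter(grades, config.concordance_threshold)
            verdicts["concordance"] = (
                PASS
                if res.keep
                else Verdict(
                    False,
                    f"modal grade {res.modal_grade} in {res.modal_count}/{res.n_species}",
                )
            )
        verdicts["self_complementarity"] = self_complementarity_filter(
            kmer, config.self_comp_policy
        )
        candidates.append(PrimerCandidate(target=kmer, verdicts=verdicts))
    survivors = KmerCatalog(
        k=config.k, sequences=tuple(c.target for c in candidates if c.surviving)
    )
    short = None
    if config.short_k is not None and len(survivors):
        short = derive_short_primers(survivors, config.short_k)
    elif config.short_k is not None:
        short = KmerCatalog(k=config.short_k, sequences=())
    return DesignResult(
        candidates=tuple(candidates), survivors=survivors, short_primers=short
    )


def write_candidates_tsv(candidates: Iterable[PrimerCandidate], path) -> None:
    """TSV: target, per-filter verdict and evidence columns, surviving flag."""
    candidates = list(candidates)
    filter_names: list[str] = []
    for c in candidates:
        for name in c.verdicts:
            if name not in filter_names:
                filter_names.append(name)
    with open(path, "w") as fh:
        cols = ["target"]
        for name in filter_names:
            cols += [name, f"{name}_evidence"]
        cols.append("surviving")
        fh.write("\t".join(cols) + "\n")
        for c in candidates:
            row = [c.target]
            for name in filter_names:
                v = c.verdicts.get(name)
                if v is None:
                    row += ["NA", ""]
                else:
                    row += [v.status, v.evidence or ""]
            row.append("true" if c.surviving else "false")
            fh.write("\t".join(row) + "\n")
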