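"""Synthetic genomes, amplicon truth tables, biased read sets, and cohorts.

Everything here is seed-deterministic and emits machine-readable truth, so
the prediction and evaluation modules can be tested closed-loop without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from ._seq import revcomp, validate_dna
from .errors import InvalidSpecError
from .sequencing_eval import DepthProfile, ReadPlacementSet

__all__ = [
    "SyntheticGenomeSpec",
    "SimulatedGenome",
    "TruthAmplicon",
    "TruthAmpliconTable",
    "ReadSimSpec",
    "CohortSpec",
    "simulate_genome",
    "plant_amplicon_pair",
    "simulate_reads",
    "simulate_cohort",
    "expected_common_bases",
    "write_fastq",
]

CORE_SEQ_ID = "core"  # dedicated reference sequence holding always-retained bases


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    length: int
    gc: float = 0.5
    seed: int = 0
    plants: Tuple[Tuple[str, int], ...] = ()
    seq_id: str = "chr1"

    def __post_init__(self):
        if self.length < 1:
            raise InvalidSpecError("length must be >= 1")
        if not 0.0 <= self.gc <= 1.0:
            raise InvalidSpecError("gc must be in [0,1]")
        intervals = []
        for seq, pos in self.plants:
            validate_dna(seq, name="plant")
            if pos < 0 or pos + len(seq) > self.length:
                raise InvalidSpecError(
                    f"plant at {pos} (len {len(seq)}) exceeds genome length {self.length}"
                )
            intervals.append((pos, pos + len(seq)))
        intervals.sort()
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            if s2 < e1:
                raise InvalidSpecError(f"overlapping plants at [{s1},{e1}) and [{s2},{e2})")


@dataclass(frozen=True)
class SimulatedGenome:
    seq_id: str
    sequence: str
    plants: Tuple[Tuple[str, int], ...]

    def records(self):
        return [(self.seq_id, self.sequence)]


def simulate_genome(spec: SyntheticGenomeSpec) -> SimulatedGenome:
    """i.i.d. bases at the requested GC content, plants overwritten in place."""
    rng = np.random.default_rng(spec.seed)
    p_gc = spec.gc / 2.0
    p_at = (1.0 - spec.gc) / 2.0
    bases = rng.choice(
        np.array(list("ACGT")), size=spec.length, p=[p_at, p_gc, p_gc, p_at]
    )
    seq = list("".join(bases))
    for plant, pos in spec.plants:
        seq[pos : pos + len(plant)] = plant
    return SimulatedGenome(
        seq_id=spec.seq_id, sequence="".join(seq), plants=tuple(spec.plants)
    )


# ---------------------------------------------------------------------------
# Amplicon truth tables


@dataclass(frozen=True)
class TruthAmplicon:
    seq_id: str
    start: int
    end: int
    forward_primer: str
    reverse_primer: str
    efficiency: float = 1.0

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise InvalidSpecError("truth amplicon needs 0 <= start < end")
        if self.efficiency <= 0:
            raise InvalidSpecError("efficiency weights must be > 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TruthAmpliconTable:
    rows: Tuple[TruthAmplicon, ...] = ()

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("seq_id\tstart\tend\tforward_primer\treverse_primer\tefficiency\n")
            for r in self.rows:
                fh.write(
                    f"{r.seq_id}\t{r.start}\t{r.end}\t{r.forward_primer}\t"
                    f"{r.reverse_primer}\t{r.efficiency}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "TruthAmpliconTable":
        rows = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "seq_id\t")):
                continue
            seq_id, start, end, fwd, rev, eff = line.split("\t")
            rows.append(
                TruthAmplicon(
                    seq_id=seq_id, start=int(start), end=int(end),
                    forward_primer=fwd, reverse_primer=rev, efficiency=float(eff),
                )
            )
        return cls(rows=tuple(rows))


def plant_amplicon_pair(
    genome: SimulatedGenome,
    forward_target: str,
    reverse_target: str,
    start: int,
    product_len: int,
    table: TruthAmpliconTable = TruthAmpliconTable(),
    *,
    forward_name: Optional[str] = None,
    reverse_name: Optional[str] = None,
    efficiency: float = 1.0,
) -> Tuple[SimulatedGenome, TruthAmpliconTable]:
    """Write a forward site and a downstream reverse-complement site.

    The forward target lands at ``start``; the reverse-complemented reverse
    target is written so the 5'-to-5' product interval is exactly
    ``[start, start + product_len)``.  The two written site intervals must
    not collide with previously planted sites (product intervals may nest).
    """
    forward_target = validate_dna(forward_target, name="forward_target")
    reverse_target = validate_dna(reverse_target, name="reverse_target")
    end = start + product_len
    site_f = (start, start + len(forward_target))
    site_r = (end - len(reverse_target), end)
    if start < 0 or end > len(genome.sequence):
        raise InvalidSpecError(
            f"product [{start},{end}) exceeds genome length {len(genome.sequence)}"
        )
    if site_f[1] > site_r[0]:
        raise InvalidSpecError("product too short: priming sites would overlap")
    existing = [(p, p + len(s)) for s, p in genome.plants]
    for s, e in (site_f, site_r):
        for es, ee in existing:
            if s < ee and es < e:
                raise InvalidSpecError(
                    f"planted site [{s},{e}) collides with existing plant [{es},{ee})"
                )
    seq = list(genome.sequence)
    seq[site_f[0] : site_f[1]] = forward_target
    seq[site_r[0] : site_r[1]] = revcomp(reverse_target)
    new_genome = SimulatedGenome(
        seq_id=genome.seq_id,
        sequence="".join(seq),
        plants=genome.plants
        + ((forward_target, site_f[0]), (revcomp(reverse_target), site_r[0])),
    )
    row = TruthAmplicon(
        seq_id=genome.seq_id,
        start=start,
        end=end,
        forward_primer=forward_name or forward_target,
        reverse_primer=reverse_name or reverse_target,
        efficiency=efficiency,
    )
    return new_genome, TruthAmpliconTable(rows=table.rows + (row,))


# ---------------------------------------------------------------------------
# Amplification-biased read simulation


@dataclass(frozen=True)
class ReadSimSpec:
    n_reads: int
    read_len: int = 150
    bias_sdlog: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_reads < 0:
            raise InvalidSpecError("n_reads must be >= 0")
        if self.read_len < 1:
            raise InvalidSpecError("read_len must be >= 1")
        if self.bias_sdlog < 0:
            raise InvalidSpecError("bias_sdlog must be >= 0")


def simulate_reads(
    truth: TruthAmpliconTable,
    spec: ReadSimSpec,
    *,
    individual_id: str = "sim",
) -> Tuple[ReadPlacementSet, np.ndarray]:
    """Allocate reads to amplicons with log-normal efficiency weights.

    Per-amplicon weight = efficiency * LogNormal(0, bias_sdlog); reads are
    assigned multinomially and each read is placed at one end of its
    amplicon (paired-end geometry, length ``read_len``).  Returns the
    placements plus the per-amplicon read counts (which sum to ``n_reads``
    exactly).
    """
    if spec.n_reads > 0 and len(truth) == 0:
        raise InvalidSpecError("cannot simulate reads without amplicons")
    rng = np.random.default_rng(spec.seed)
    amps = list(truth)
    for a in amps:
        if spec.read_len > a.length:
            raise InvalidSpecError(
                f"read_len {spec.read_len} exceeds amplicon length {a.length}"
            )
    if not amps:
        return ReadPlacementSet(individual_id=individual_id, placements=()), np.zeros(0, dtype=np.int64)
    weights = np.array([a.efficiency for a in amps], dtype=float)
    if spec.bias_sdlog > 0:
        weights = weights * rng.lognormal(mean=0.0, sigma=spec.bias_sdlog, size=len(amps))
    probs = weights / weights.sum()
    counts = rng.multinomial(spec.n_reads, probs)
    placements = []
    for a, c in zip(amps, counts):
        if c == 0:
            continue
        ends = rng.integers(0, 2, size=c)  # 0 = forward end, 1 = reverse end
        for e in ends:
            if e == 0:
                placements.append((a.seq_id, a.start, a.start + spec.read_len))
            else:
                placements.append((a.seq_id, a.end - spec.read_len, a.end))
    return (
        ReadPlacementSet(individual_id=individual_id, placements=tuple(placements)),
        counts.astype(np.int64),
    )


def write_fastq(
    placements: ReadPlacementSet, genome: SimulatedGenome, path, *, quality: str = "I"
) -> None:
    """Optional FASTQ emission with a fixed Phred-33 quality character."""
    seqs = {genome.seq_id: genome.sequence}
    with open(path, "w") as fh:
        for i, (seq_id, start, end) in enumerate(placements.placements):
            read = seqs[seq_id][start:end]
            fh.write(f"@{placements.individual_id}_read{i} {seq_id}:{start}-{end}\n")
            fh.write(read + "\n+\n" + quality * len(read) + "\n")


# ---------------------------------------------------------------------------
# Multi-individual cohorts with per-locus dropout


@dataclass(frozen=True)
class CohortSpec:
    """Shared loci retained independently per individual with probability p.

    Retained loci receive uniform depth ``locus_depth``.  ``core_bases``
    always-retained positions live on a dedicated sequence (never colliding
    with loci), realizing a nonzero asymptote: the expected common-base
    count over x individuals is  total_locus_bases * p**x + core_bases.
    """

    n_individuals: int
    retention: float
    truth: TruthAmpliconTable
    genome_length: int
    core_bases: int = 0
    locus_depth: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1:
            raise InvalidSpecError("n_individuals must be >= 1")
        if not 0.0 < self.retention <= 1.0:
            raise InvalidSpecError("retention must be in (0,1]")
        if self.core_bases < 0:
            raise InvalidSpecError("core_bases must be >= 0")
        if self.locus_depth < 1:
            raise InvalidSpecError("locus_depth must be >= 1")
        locus_bases = sum(r.length for r in self.truth)
        if self.genome_length < locus_bases + self.core_bases:
            raise InvalidSpecError(
                "genome_length smaller than locus bases + core bases"
            )
        # disjoint loci are required for the closed-form expectation
        by_seq: Dict[str, list] = {}
        for r in self.truth:
            by_seq.setdefault(r.seq_id, []).append((r.start, r.end))
        for intervals in by_seq.values():
            intervals.sort()
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                if s2 < e1:
                    raise InvalidSpecError(
                        f"cohort loci overlap: [{s1},{e1}) and [{s2},{e2})"
                    )

    @property
    def total_locus_bases(self) -> int:
        return sum(r.length for r in self.truth)


def simulate_cohort(spec: CohortSpec) -> list[DepthProfile]:
    """One DepthProfile per individual under independent per-locus dropout."""
    loci = list(spec.truth)
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_individuals)
    profiles = []
    for i, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        keep = rng.random(len(loci)) < spec.retention
        depths: Dict[str, Dict[int, int]] = {}
        for locus, kept in zip(loci, keep):
            if not kept:
                continue
            per_pos = depths.setdefault(locus.seq_id, {})
            for pos in range(locus.start + 1, locus.end + 1):  # 1-based
                per_pos[pos] = spec.locus_depth
        if spec.core_bases:
            depths[CORE_SEQ_ID] = {
                pos: spec.locus_depth for pos in range(1, spec.core_bases + 1)
            }
        profiles.append(
            DepthProfile(
                individual_id=f"ind{i:03d}",
                depths=depths,
                genome_length=spec.genome_length,
            )
        )
    return profiles


def expected_common_bases(spec: CohortSpec, x: int) -> float:
    """Closed form: total_locus_bases * p**x + core_bases."""
    return spec.total_locus_bases * spec.retention ** x + spec.core_bases


def build_amplicon_genome(
    length: int,
    targets: Sequence[Tuple[str, str]],
    n_amplicons: int,
    *,
    gc: float = 0.5,
    seed: int = 0,
    product_len_range: Tuple[int, int] = (600, 1500),
    seq_id: str = "chr1",
    scrub: bool = True,
) -> Tuple[SimulatedGenome, TruthAmpliconTable]:
    """Random genome with ``n_amplicons`` planted, evenly spaced with jitter.

    ``targets`` is a list of (name, target) priming sequences; forward and
    reverse targets for each amplicon are drawn from it at random.  With
    ``scrub`` (default), chance occurrences of any target in the random
    background are mutated away, so the truth table is exactly the predicted
    amplicon set for any size window covering ``product_len_range``.
    """
    if n_amplicons < 1:
        raise InvalidSpecError("n_amplicons must be >= 1")
    lo, hi = product_len_range
    slot = length // n_amplicons
    # one product per slot, jitter capped so consecutive products stay at
    # least lo + 2*hi apart: no cross-amplicon pair can fall inside any size
    # window bounded by lo + 2*hi
    if slot < 2 * hi:
        raise InvalidSpecError(
            f"genome length {length} too small for {n_amplicons} products up to {hi} bp"
        )
    rng = np.random.default_rng(seed)
    genome = simulate_genome(
        SyntheticGenomeSpec(length=length, gc=gc, seed=seed, seq_id=seq_id)
    )
    table = TruthAmpliconTable()
    for i in range(n_amplicons):
        product_len = int(rng.integers(lo, hi + 1))
        start = i * slot + int(rng.integers(0, slot - 2 * hi + 1))
        fwd_name, fwd = targets[rng.integers(0, len(targets))]
        rev_name, rev = targets[rng.integers(0, len(targets))]
        genome, table = plant_amplicon_pair(
            genome, fwd, rev, start, product_len, table,
            forward_name=fwd_name, reverse_name=rev_name,
        )
    if scrub:
        genome = _scrub_spurious_sites(genome, [t for _, t in targets])
    return genome, table


def _scrub_spurious_sites(
    genome: SimulatedGenome, targets: Sequence[str], max_rounds: int = 50
) -> SimulatedGenome:
    """Mutate away chance target matches outside the planted site intervals."""
    planted = [(p, p + len(s)) for s, p in genome.plants]

    def in_planted(pos: int) -> bool:
        return any(s <= pos < e for s, e in planted)

    seq = list(genome.sequence)
    probes = {t for t in targets} | {revcomp(t) for t in targets}
    for _ in range(max_rounds):
        dirty = False
        text = "".join(seq)
        for probe in probes:
            pos = text.find(probe)
            while pos != -1:
                span = range(pos, pos + len(probe))
                free = [i for i in span if not in_planted(i)]
                if free:  # a fully-planted occurrence is truth, leave it
                    i = free[len(free) // 2]
                    seq[i] = "ACGT"[("ACGT".index(seq[i]) + 1) % 4]
                    dirty = True
                pos = text.find(probe, pos + 1)
        if not dirty:
            return SimulatedGenome(
                seq_id=genome.seq_id, sequence="".join(seq), plants=genome.plants
            )
    raise InvalidSpecError("could not scrub spurious priming sites")
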