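"""Sequencing-efficiency indicators for reduced-representation read sets.

Implements depth-stratified coverage fractions, read-count standardization,
saturation curves, cross-individual common-base intersection, and the
exponential-decay reduction-curve model  Y = C1 * a**x + C2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .errors import DepthParseError, InvalidParameterError

__all__ = [
    "DepthProfile",
    "CoverageFractionTable",
    "ReadPlacementSet",
    "SaturationPoint",
    "ReductionCurveFit",
    "DEFAULT_THRESHOLDS",
    "load_depth",
    "write_depth_tsv",
    "coverage_fractions",
    "standardize_reads",
    "depth_from_placements",
    "saturation_curve",
    "common_bases",
    "reduction_curve",
    "fit_reduction_model",
]

DEFAULT_THRESHOLDS = (1, 3, 10, 30, 100, 500, 1000)
DEFAULT_MIN_DEPTH = 10

Position = Tuple[str, int]


@dataclass(frozen=True)
class DepthProfile:
    """Sparse per-base depth for one individual over a fixed reference.

    ``depths`` maps seq_id -> {1-based position -> depth > 0}; every other
    position is depth 0.  ``genome_length`` is the denominator used for
    coverage fractions, supplied explicitly (e.g. from a FASTA index) rather
    than inferred from observed positions.
    """

    individual_id: str
    depths: Dict[str, Dict[int, int]]
    genome_length: int

    def __post_init__(self):
        if self.genome_length <= 0:
            raise InvalidParameterError("genome_length must be > 0")
        for seq_id, per_pos in self.depths.items():
            for pos, depth in per_pos.items():
                if pos < 1:
                    raise InvalidParameterError(
                        f"{seq_id}:{pos}: positions are 1-based"
                    )
                if depth < 0:
                    raise InvalidParameterError(f"{seq_id}:{pos}: negative depth")

    def covered_positions(self, min_depth: int = 1) -> FrozenSet[Position]:
        """Set of (seq_id, position) with depth >= ``min_depth``."""
        return frozenset(
            (seq_id, pos)
            for seq_id, per_pos in self.depths.items()
            for pos, depth in per_pos.items()
            if depth >= min_depth
        )

    def n_covered(self, min_depth: int = 1) -> int:
        return sum(
            1
            for per_pos in self.depths.values()
            for depth in per_pos.values()
            if depth >= min_depth
        )


def load_depth(source, genome_length: int, *, individual_id: str = "unknown") -> DepthProfile:
    """Read a three-column depth table (seq, 1-based pos, depth).

    Compatible with ``samtools depth`` output.  Duplicate positions and
    malformed rows raise :class:`DepthParseError` with the line number.
    """
    if isinstance(source, (str, Path)):
        lines = Path(source).read_text().splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in source]
    depths: Dict[str, Dict[int, int]] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise DepthParseError("expected 3 tab-separated columns", lineno)
        seq_id, pos_s, depth_s = fields
        try:
            pos, depth = int(pos_s), int(depth_s)
        except ValueError:
            raise DepthParseError("position and depth must be integers", lineno)
        if pos < 1:
            raise DepthParseError("positions are 1-based (>= 1)", lineno)
        if depth < 0:
            raise DepthParseError("negative depth", lineno)
        per_pos = depths.setdefault(seq_id, {})
        if pos in per_pos:
            raise DepthParseError(f"duplicate position {seq_id}:{pos}", lineno)
        if depth > 0:
            per_pos[pos] = depth
    depths = {s: p for s, p in depths.items() if p}
    return DepthProfile(
        individual_id=individual_id, depths=depths, genome_length=genome_length
    )


def write_depth_tsv(profile: DepthProfile, path) -> None:
    with open(path, "w") as fh:
        for seq_id in sorted(profile.depths):
            per_pos = profile.depths[seq_id]
            for pos in sorted(per_pos):
                fh.write(f"{seq_id}\t{pos}\t{per_pos[pos]}\n")


@dataclass(frozen=True)
class CoverageFractionTable:
    """Percentage of the genome at or above each depth threshold."""

    thresholds: Tuple[int, ...]
    fractions: Dict[int, float]  # threshold -> percentage of genome_length

    def __post_init__(self):
        vals = [self.fractions[t] for t in self.thresholds]
        if any(not 0.0 <= v <= 100.0 for v in vals):
            raise InvalidParameterError("fractions must be percentages in [0,100]")
        if any(a < b - 1e-12 for a, b in zip(vals, vals[1:])):
            raise InvalidParameterError("fractions must be nonincreasing in threshold")


def coverage_fractions(
    profile: DepthProfile, thresholds: Sequence[int] = DEFAULT_THRESHOLDS
) -> CoverageFractionTable:
    """fraction(t) = 100 * |{positions with depth >= t}| / genome_length."""
    thresholds = tuple(thresholds)
    if not thresholds or any(t <= 0 for t in thresholds):
        raise InvalidParameterError("thresholds must be positive")
    if any(a >= b for a, b in zip(thresholds, thresholds[1:])):
        raise InvalidParameterError("thresholds must be strictly increasing")
    all_depths = np.fromiter(
        (d for per_pos in profile.depths.values() for d in per_pos.values()),
        dtype=np.int64,
    )
    fractions = {}
    for t in thresholds:
        n = int((all_depths >= t).sum()) if all_depths.size else 0
        fractions[t] = 100.0 * n / profile.genome_length
    return CoverageFractionTable(thresholds=thresholds, fractions=fractions)


# ---------------------------------------------------------------------------
# Read placements, standardization, saturation


@dataclass(frozen=True)
class ReadPlacementSet:
    """One half-open interval per retained read."""

    individual_id: str
    placements: Tuple[Tuple[str, int, int], ...]

    def __post_init__(self):
        for seq_id, start, end in self.placements:
            if start < 0 or start >= end:
                raise InvalidParameterError(
                    f"bad placement {seq_id}:{start}-{end} (need 0 <= start < end)"
                )

    def __len__(self) -> int:
        return len(self.placements)

    @classmethod
    def from_bed(cls, path, *, individual_id: str = "unknown") -> "ReadPlacementSet":
        placements = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            placements.append((fields[0], int(fields[1]), int(fields[2])))
        return cls(individual_id=individual_id, placements=tuple(placements))

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for seq_id, start, end in self.placements:
                fh.write(f"{seq_id}\t{start}\t{end}\n")


def standardize_reads(
    placements: ReadPlacementSet, n: int, seed: int = 0
) -> ReadPlacementSet:
    """Uniform subsample of ``n`` reads without replacement, seed-deterministic.

    Input order is preserved so ``n == len(placements)`` is the identity.
    """
    total = len(placements)
    if not 0 <= n <= total:
        raise InvalidParameterError(f"n must be in [0, {total}], got {n}")
    if n == total:
        return placements
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(total, size=n, replace=False))
    return ReadPlacementSet(
        individual_id=placements.individual_id,
        placements=tuple(placements.placements[i] for i in idx),
    )


def depth_from_placements(
    placements: Iterable[Tuple[str, int, int]],
    *,
    individual_id: str = "unknown",
    genome_length: Optional[int] = None,
) -> DepthProfile:
    """Per-base depth implied by read intervals (0-based half-open input;
    1-based positions in the resulting profile)."""
    events: Dict[str, list] = {}
    max_end: Dict[str, int] = {}
    items = list(placements)
    for seq_id, start, end in items:
        events.setdefault(seq_id, []).append((start, end))
        max_end[seq_id] = max(max_end.get(seq_id, 0), end)
    depths: Dict[str, Dict[int, int]] = {}
    total_span = 0
    for seq_id, intervals in events.items():
        arr = np.zeros(max_end[seq_id] + 1, dtype=np.int64)
        starts = np.array([iv[0] for iv in intervals])
        ends = np.array([iv[1] for iv in intervals])
        np.add.at(arr, starts, 1)
        np.add.at(arr, ends, -1)
        cov = np.cumsum(arr)[:-1]  # cov[i] = depth at 0-based position i
        nz = np.nonzero(cov)[0]
        depths[seq_id] = {int(i) + 1: int(cov[i]) for i in nz}
        total_span += max_end[seq_id]
    if genome_length is None:
        genome_length = max(total_span, 1)
    return DepthProfile(
        individual_id=individual_id, depths=depths, genome_length=genome_length
    )


@dataclass(frozen=True)
class SaturationPoint:
    n_reads: int
    covered_bases: int


def saturation_curve(
    placements: ReadPlacementSet,
    subsample_sizes: Sequence[int],
    min_depth: int = DEFAULT_MIN_DEPTH,
    seed: int = 0,
) -> list[SaturationPoint]:
    """Covered bases (depth >= ``min_depth``) at each subsample size.

    Each size draws an independent subsample from a seed stream spawned off
    ``seed``, so the whole curve is reproducible.
    """
    total = len(placements)
    if any(s <= 0 or s > total for s in subsample_sizes):
        raise InvalidParameterError(
            f"subsample sizes must be in [1, {total}]"
        )
    child_seeds = np.random.SeedSequence(seed).spawn(len(subsample_sizes))
    points = []
    for size, child in zip(subsample_sizes, child_seeds):
        sub = standardize_reads(
            placements, size, seed=int(child.generate_state(1)[0])
        )
        profile = depth_from_placements(
            sub.placements, individual_id=placements.individual_id
        )
        points.append(
            SaturationPoint(n_reads=size, covered_bases=profile.n_covered(min_depth))
        )
    return points


# ---------------------------------------------------------------------------
# Common bases across individuals and the reduction curve


def common_bases(
    profiles: Sequence[DepthProfile], min_depth: int = DEFAULT_MIN_DEPTH
) -> int:
    """Number of positions with depth >= ``min_depth`` in *every* individual."""
    if not profiles:
        raise InvalidParameterError("profiles must be nonempty")
    lengths = {p.genome_length for p in profiles}
    if len(lengths) != 1:
        raise InvalidParameterError(
            f"profiles reference different genomes (lengths {sorted(lengths)})"
        )
    sets = sorted(
        (p.covered_positions(min_depth) for p in profiles), key=len
    )
    common = set(sets[0])
    for s in sets[1:]:
        common &= s
        if not common:
            break
    return len(common)


def reduction_curve(
    profiles: Sequence[DepthProfile],
    n_grid: Sequence[int],
    n_replicates: int = 20,
    min_depth: int = DEFAULT_MIN_DEPTH,
    seed: int = 0,
) -> list[Tuple[int, float]]:
    """Mean common-base count over random x-subsets of individuals.

    For each x in ``n_grid``, draws ``n_replicates`` independent
    without-replacement subsets (replicates collapse when x equals the
    cohort size) and averages the intersection size.
    """
    if not profiles:
        raise InvalidParameterError("profiles must be nonempty")
    n = len(profiles)
    if any(x < 1 or x > n for x in n_grid):
        raise InvalidParameterError(f"n_grid values must be in [1, {n}]")
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    covered = [p.covered_positions(min_depth) for p in profiles]
    rng = np.random.default_rng(seed)
    curve = []
    for x in n_grid:
        reps = 1 if x == n else n_replicates
        totals = 0
        for _ in range(reps):
            idx = rng.choice(n, size=x, replace=False)
            subset = sorted((covered[i] for i in idx), key=len)
            common = set(subset[0])
            for s in subset[1:]:
                common &= s
                if not common:
                    break
            totals += len(common)
        curve.append((x, totals / reps))
    return curve


# ---------------------------------------------------------------------------
# Reduction-model fit: Y = C1 * a**x + C2


@dataclass(frozen=True)
class ReductionCurveFit:
    c1: float
    c2: float
    a: float
    rss: float
    converged: bool
    degenerate: bool
    message: str
    points: Tuple[Tuple[float, float], ...]

    def predict(self, x) -> np.ndarray:
        return self.c1 * np.power(self.a, np.asarray(x, dtype=float)) + self.c2


_A_LO, _A_HI = 1e-6, 1.0 - 1e-6


def fit_reduction_model(points: Sequence[Tuple[float, float]]) -> ReductionCurveFit:
    """Bounded nonlinear least squares for Y = C1 * a**x + C2.

    Initialization: a0 = 0.7, C2_0 = min(Y), C1_0 = (max(Y) - C2_0) / a0.
    Constraints: C1 >= 0, C2 >= 0, a in (0, 1).  Failure to converge and
    degenerate solutions (C1 ~ 0 or a pinned at a bound) are reported via
    flags rather than exceptions.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 4:
        raise InvalidParameterError("need at least 4 points to fit")
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if len(set(xs.tolist())) != len(xs):
        raise InvalidParameterError("x values must be distinct")

    a0 = 0.7
    c2_0 = float(ys.min())
    c1_0 = max((float(ys.max()) - c2_0) / a0, 0.0)

    def residuals(theta):
        c1, c2, a = theta
        return c1 * np.power(a, xs) + c2 - ys

    def jacobian(theta):
        c1, c2, a = theta
        ax = np.power(a, xs)
        return np.column_stack([ax, np.ones_like(xs), c1 * xs * np.power(a, xs - 1)])

    try:
        result = least_squares(
            residuals,
            x0=[c1_0, c2_0, a0],
            jac=jacobian,
            bounds=([0.0, 0.0, _A_LO], [np.inf, np.inf, _A_HI]),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            x_scale=[max(c1_0, 1.0), max(c2_0, 1.0), 1.0],
        )
    except Exception as exc:  # pragma: no cover - defensive
        return ReductionCurveFit(
            c1=float("nan"), c2=float("nan"), a=float("nan"), rss=float("nan"),
            converged=False, degenerate=False, message=str(exc), points=tuple(pts),
        )

    c1, c2, a = (float(v) for v in result.x)
    rss = float(np.sum(result.fun ** 2))
    scale = max(float(ys.max()), 1.0)
    degenerate = c1 <= 1e-9 * scale or a <= _A_LO * 1.01 or a >= _A_HI * 0.999999
    return ReductionCurveFit(
        c1=c1, c2=c2, a=a, rss=rss,
        converged=bool(result.success),
        degenerate=bool(degenerate),
        message=result.message,
        points=tuple(pts),
    )
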