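"""Per-site temporal behavior across the ordered time points of one series.

A series is one (matrix, condition) pair — e.g. blood stored dry — sampled
at increasing storage times starting at day 0, the truth reference.  Each
site's ordered genotype calls and PRVs form a :class:`SiteTrajectory`,
classified into transition patterns (heterozygote gain/loss, homozygote
switches, failed-call onset), and its (ref, alt) pair into the substitution
spectrum (type 1 / type 2 transitions, transversions, spanning deletions).
Hydrolytic deamination drives type 2 transitions (G>A, C>T), so their share
of the spectrum is the damage signature of interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .core import SiteKey
from .genotyping import CallMatrix, GenotypeCall

# ---------------------------------------------------------------------------
# trajectory container


@dataclass(frozen=True)
class SiteTrajectory:
    """Ordered calls and PRVs for one site within one (matrix, condition) series."""

    site: SiteKey
    series: tuple[str, str]
    time_days: tuple[int, ...]
    calls: tuple[GenotypeCall, ...]
    prvs: tuple[float | None, ...]

    def __post_init__(self) -> None:
        n = len(self.time_days)
        if n < 2:
            raise ValueError("a trajectory needs at least two time points")
        if len(self.calls) != n or len(self.prvs) != n:
            raise ValueError("time_days, calls and prvs must share length")
        if any(b <= a for a, b in zip(self.time_days, self.time_days[1:])):
            raise ValueError("time points must be strictly increasing")
        if self.time_days[0] != 0:
            raise ValueError("first time point must be day 0 (truth reference)")


class TrajectoryClass(Enum):
    """Named temporal patterns of a genotype-call trajectory."""

    STABLE = "STABLE"
    GAIN_HET = "GAIN_HET"  # 0/0 -> 0/1
    LOSS_HET = "LOSS_HET"  # 1/1 -> 0/1
    RESOLVE_TO_HOM = "RESOLVE_TO_HOM"  # 0/1 -> 0/0 or 0/1 -> 1/1
    HOM_SWITCH_UP = "HOM_SWITCH_UP"  # 0/0 -> 0/1 -> 1/1
    HOM_SWITCH_DOWN = "HOM_SWITCH_DOWN"  # 1/1 -> 0/1 -> 0/0
    FAILED_ONSET = "FAILED_ONSET"  # coverage lost at a later time point
    OTHER = "OTHER"


class Day0FailedError(ValueError):
    """Raised when the day-0 call is FAILED: no truth reference exists."""


def classify_trajectory(traj: SiteTrajectory) -> TrajectoryClass:
    """Classify one trajectory into a :class:`TrajectoryClass`.

    The day-0 call must be non-FAILED (otherwise :class:`Day0FailedError`).
    Coverage loss at any later time point pre-empts every genotype pattern
    (FAILED_ONSET).  The three-point homozygote-switch patterns are matched
    exactly; all remaining trajectories are labelled by their (day-0, last)
    call pair, and pairs outside the named patterns are OTHER.
    """
    return _classify_calls(traj.calls)


def _classify_calls(calls: Sequence[GenotypeCall]) -> TrajectoryClass:
    if calls[0] is GenotypeCall.FAILED:
        raise Day0FailedError("day-0 call is FAILED; no truth reference")
    if any(c is GenotypeCall.FAILED for c in calls[1:]):
        return TrajectoryClass.FAILED_ONSET
    G = GenotypeCall
    if len(calls) == 3:
        triple = tuple(calls)
        if triple == (G.HOM_REF, G.HET, G.HOM_ALT):
            return TrajectoryClass.HOM_SWITCH_UP
        if triple == (G.HOM_ALT, G.HET, G.HOM_REF):
            return TrajectoryClass.HOM_SWITCH_DOWN
    first, last = calls[0], calls[-1]
    if first is last:
        return TrajectoryClass.STABLE
    if first is G.HOM_REF and last is G.HET:
        return TrajectoryClass.GAIN_HET
    if first is G.HOM_ALT and last is G.HET:
        return TrajectoryClass.LOSS_HET
    if first is G.HET and last in (G.HOM_REF, G.HOM_ALT):
        return TrajectoryClass.RESOLVE_TO_HOM
    return TrajectoryClass.OTHER


def classify_call_matrix(
    calls: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Classify every row of an (n_sites, n_times) call-code matrix.

    Returns (labels, day0_failed_mask); labels is an object array of
    TrajectoryClass (None where day 0 failed).  Time columns must be in
    increasing time order with column 0 the day-0 truth.
    """
    n_sites, n_times = calls.shape
    labels = np.empty(n_sites, dtype=object)
    day0_failed = calls[:, 0] == GenotypeCall.FAILED
    # only 4**n_times distinct rows; classify each pattern once
    base = np.array([4**k for k in range(n_times)][::-1])
    codes = calls.astype(np.int64) @ base
    for code in np.unique(codes[~day0_failed]):
        digits = []
        c = int(code)
        for _ in range(n_times):
            digits.append(GenotypeCall(c % 4))
            c //= 4
        pattern = tuple(reversed(digits))
        labels[codes == code] = _classify_calls(pattern)
    labels[day0_failed] = None
    return labels, day0_failed


# ---------------------------------------------------------------------------
# failed calls and transition matrices


def count_failed_calls(calls: Iterable[GenotypeCall] | np.ndarray) -> int:
    """Number of FAILED (no-coverage) calls at one time point across sites."""
    arr = np.asarray([int(c) for c in calls] if not isinstance(calls, np.ndarray) else calls)
    return int((arr == int(GenotypeCall.FAILED)).sum())


def genotype_transition_counts(
    day0_calls: Sequence[GenotypeCall] | np.ndarray,
    later_calls: Sequence[GenotypeCall] | np.ndarray,
) -> np.ndarray:
    """4x4 transition-count matrix over {0/0, 0/1, 1/1, FAILED}.

    Rows index the day-0 call, columns the later call; entries sum to the
    number of sites.
    """
    a = np.asarray([int(c) for c in day0_calls])
    b = np.asarray([int(c) for c in later_calls])
    if a.shape != b.shape:
        raise ValueError("day-0 and later call vectors must cover the same sites")
    m = np.zeros((4, 4), dtype=np.int64)
    np.add.at(m, (a, b), 1)
    return m


# ---------------------------------------------------------------------------
# base-change spectrum


class BaseChangeClass(Enum):
    TYPE1_TRANSITION = "TYPE1_TRANSITION"  # A>G, T>C
    TYPE2_TRANSITION = "TYPE2_TRANSITION"  # G>A, C>T (deamination signature)
    TRANSVERSION = "TRANSVERSION"
    SPANNING_DELETION = "SPANNING_DELETION"


_TYPE1 = {("A", "G"), ("T", "C")}
_TYPE2 = {("G", "A"), ("C", "T")}


def classify_base_change(site: SiteKey) -> BaseChangeClass:
    """Map a site's (ref, alt) pair to its base-change class (reference strand)."""
    if site.is_spanning_deletion:
        return BaseChangeClass.SPANNING_DELETION
    pair = (site.ref, site.alt)
    if pair in _TYPE2:
        return BaseChangeClass.TYPE2_TRANSITION
    if pair in _TYPE1:
        return BaseChangeClass.TYPE1_TRANSITION
    return BaseChangeClass.TRANSVERSION


#: the 12 base substitutions, reference strand, plus the spanning deletion
SUBSTITUTION_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (r, a) for r in "ACGT" for a in "ACGT" if r != a
)


def spectrum_counts(
    sites: Iterable[SiteKey],
) -> tuple[dict[tuple[str, str], int], dict[BaseChangeClass, int]]:
    """Count substitution pairs and base-change classes over a site set.

    Returns (per-(ref, alt) counts over the 12 substitution categories plus
    ("*", "*") for spanning deletions, per-class counts).  Class counts sum
    to the number of input sites.
    """
    pair_counts: dict[tuple[str, str], int] = {p: 0 for p in SUBSTITUTION_PAIRS}
    pair_counts[("*", "*")] = 0
    class_counts: dict[BaseChangeClass, int] = {c: 0 for c in BaseChangeClass}
    for site in sites:
        cls = classify_base_change(site)
        class_counts[cls] += 1
        key = ("*", "*") if site.is_spanning_deletion else (site.ref, site.alt)
        pair_counts[key] += 1
    return pair_counts, class_counts


def type2_fraction(class_counts: dict[BaseChangeClass, int]) -> float:
    """Fraction (in %) of substitutions that are type 2 transitions (G>A, C>T).

    Spanning deletions are excluded from the denominator (they are not base
    substitutions).
    """
    subs = sum(
        v for k, v in class_counts.items() if k is not BaseChangeClass.SPANNING_DELETION
    )
    if subs == 0:
        raise ValueError("no substitutions to compute a spectrum fraction over")
    return 100.0 * class_counts[BaseChangeClass.TYPE2_TRANSITION] / subs


# ---------------------------------------------------------------------------
# gradual (monotone) PRV drift


@dataclass(frozen=True)
class MonotoneConfig:
    """What counts as a 'gradual' PRV change over time.

    direction
        required drift direction; "either" accepts both.
    min_total_delta
        minimum |last - first| PRV change, in percentage points.  This is
        the operational proxy for an "ideally distributed" PRV profile.
    per_step_tolerance
        allowed backsliding per step, in percentage points, so sampling
        noise at finite depth does not break monotonicity.
    """

    direction: str = "either"
    min_total_delta: float = 20.0
    per_step_tolerance: float = 2.0

    def __post_init__(self) -> None:
        if self.direction not in ("increasing", "decreasing", "either"):
            raise ValueError("direction must be increasing, decreasing or either")
        if self.min_total_delta <= 0:
            raise ValueError("min_total_delta must be > 0")
        if self.per_step_tolerance < 0:
            raise ValueError("per_step_tolerance must be >= 0")


DEFAULT_MONOTONE = MonotoneConfig()


def _monotone(prvs: Sequence[float], sign: int, tol: float, delta: float) -> bool:
    steps_ok = all(
        sign * (b - a) >= -tol for a, b in zip(prvs, prvs[1:])
    )
    return steps_ok and sign * (prvs[-1] - prvs[0]) >= delta


def is_gradual(
    traj: SiteTrajectory, cfg: MonotoneConfig = DEFAULT_MONOTONE
) -> tuple[bool, str | None]:
    """Is the PRV trajectory gradually monotone?

    Returns (flag, direction); direction is "increasing" or "decreasing"
    when the flag is true, else None.  Requires PRVs defined (no FAILED
    call) at every time point.
    """
    if any(p is None or (isinstance(p, float) and math.isnan(p)) for p in traj.prvs):
        raise ValueError(
            f"undefined PRV in trajectory at {traj.site.chrom}:{traj.site.pos} "
            f"series {traj.series}"
        )
    prvs = [float(p) for p in traj.prvs]  # type: ignore[arg-type]
    tol, delta = cfg.per_step_tolerance, cfg.min_total_delta
    if cfg.direction in ("increasing", "either") and _monotone(prvs, 1, tol, delta):
        return True, "increasing"
    if cfg.direction in ("decreasing", "either") and _monotone(prvs, -1, tol, delta):
        return True, "decreasing"
    return False, None


def gradual_mask(
    prv: np.ndarray, cfg: MonotoneConfig = DEFAULT_MONOTONE
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`is_gradual` over an (n_sites, n_times) PRV matrix.

    Rows containing NaN are never gradual.  Returns (mask, direction) where
    direction is +1 / -1 / 0 per row.
    """
    finite = np.isfinite(prv).all(axis=1)
    steps = np.diff(prv, axis=1)
    total = prv[:, -1] - prv[:, 0]
    up = finite & (steps >= -cfg.per_step_tolerance).all(axis=1) & (
        total >= cfg.min_total_delta
    )
    down = finite & (steps <= cfg.per_step_tolerance).all(axis=1) & (
        -total >= cfg.min_total_delta
    )
    if cfg.direction == "increasing":
        down[:] = False
    elif cfg.direction == "decreasing":
        up[:] = False
    direction = np.where(up, 1, np.where(down, -1, 0))
    return (up | down), direction


# ---------------------------------------------------------------------------
# series extraction


@dataclass
class SeriesTrajectories:
    """All per-site trajectories of one (matrix, condition) series, as matrices.

    ``calls`` and ``prv`` are (n_sites, n_times) in increasing time order;
    ``depth`` holds total read counts.  Sites follow the StudyTable order.
    """

    series: tuple[str, str]
    time_days: tuple[int, ...]
    sites: list[SiteKey]
    calls: np.ndarray
    prv: np.ndarray
    depth: np.ndarray
    alt_reads: np.ndarray

    def trajectory(self, i: int) -> SiteTrajectory:
        calls = tuple(GenotypeCall(int(c)) for c in self.calls[i])
        prvs = tuple(
            None if c is GenotypeCall.FAILED else float(p)
            for c, p in zip(calls, self.prv[i])
        )
        return SiteTrajectory(self.sites[i], self.series, self.time_days, calls, prvs)

    def __iter__(self):
        return (self.trajectory(i) for i in range(len(self.sites)))


def extract_series(calls: CallMatrix) -> dict[tuple[str, str], SeriesTrajectories]:
    """Split a study-wide CallMatrix into per-series trajectory matrices."""
    table = calls.table
    depth = table.total_depth()
    out: dict[tuple[str, str], SeriesTrajectories] = {}
    for series in table.series_keys():
        members = table.series_samples(series)
        if members[0].time_days != 0:
            raise ValueError(f"series {series} lacks a day-0 sample")
        cols = [table.sample_index(s.sample_id) for s in members]
        out[series] = SeriesTrajectories(
            series=series,
            time_days=tuple(s.time_days for s in members),
            sites=table.sites,
            calls=calls.calls[:, cols],
            prv=calls.prv[:, cols],
            depth=depth[:, cols],
            alt_reads=table.counts[:, cols, 1],
        )
    return out
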