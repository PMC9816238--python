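"""Stepwise selection of time-since-deposition (TsD) candidate markers.

The candidate search restricts to the hydrolytic-deamination signature
(G>A and C>T changes), removes observations explainable as sequencing error
with a read-count threshold, requires a homozygous day-0 genotype, and keeps
only sites whose PRV drifts gradually in the same direction in every
required (matrix, condition) series — a marker should behave the same in
blood and saliva, wet or dry, if it is to report elapsed time rather than
the storage environment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import SiteKey
from .genotyping import GenotypeCall
from .trajectories import (
    DEFAULT_MONOTONE,
    MonotoneConfig,
    SeriesTrajectories,
    TrajectoryClass,
    classify_call_matrix,
    gradual_mask,
)

#: the deamination pair on the reference strand, both orientations
DEAMINATION_CHANGES = frozenset({("G", "A"), ("C", "T")})


@dataclass(frozen=True)
class FilterConfig:
    """Gates applied before gradual-PRV candidate selection.

    min_total_reads
        inclusive read-count threshold applied to every sample of every
        retained series at a site; eliminates changes explainable by
        sequencing error.  ``depth_mode`` selects whether it thresholds
        total depth (default) or variant reads.
    allowed_changes
        (ref, alt) pairs retained; defaults to the deamination signature.
    require_day0_homozygous
        keep only sites whose day-0 call is homozygous in every series.
    """

    min_total_reads: int = 10
    allowed_changes: frozenset[tuple[str, str]] = DEAMINATION_CHANGES
    require_day0_homozygous: bool = True
    depth_mode: str = "total"

    def __post_init__(self) -> None:
        if self.min_total_reads < 1:
            raise ValueError("min_total_reads must be >= 1")
        if self.depth_mode not in ("total", "alt"):
            raise ValueError("depth_mode must be 'total' or 'alt'")


DEFAULT_FILTERS = FilterConfig()


@dataclass(frozen=True)
class CandidateMarker:
    """A site passing every gate, with its per-series PRV profile."""

    site: SiteKey
    direction: str  # "increasing" or "decreasing", identical across series
    per_series_prv: dict[tuple[str, str], tuple[float, ...]]
    day0_genotype: GenotypeCall


@dataclass
class FilterAttrition:
    """Per-gate attrition bookkeeping: removed counts + survivors = input."""

    n_input: int = 0
    removed_by_spectrum: int = 0
    removed_by_day0_genotype: int = 0
    removed_by_depth: int = 0
    n_surviving: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------


def changed_sites(
    series_trajs: Mapping[tuple[str, str], SeriesTrajectories],
    prv_tolerance: float = 5.0,
    z_threshold: float = 4.9,
) -> tuple[set[SiteKey], set[SiteKey]]:
    """Sites that differ between day 0 and any stored sample.

    A site counts as changed when, in any series, a stored time point's
    genotype call differs from the day-0 call, or its PRV differs from the
    day-0 PRV by more than ``prv_tolerance`` percentage points AND beyond
    what binomial read sampling at the observed depths explains (two-
    proportion z-score above ``z_threshold``; at ~30x depth a heterozygous
    site's PRV wobbles by around ten points between undamaged aliquots, and
    such wobble is sampling noise, not change).  Sites whose only difference
    is coverage loss are returned separately as the failed-onset set.  Sites
    FAILED at day 0 in a series are ignored in that series (no truth
    reference).
    """
    changed: set[SiteKey] = set()
    failed_onset: set[SiteKey] = set()
    for st in series_trajs.values():
        day0_ok = st.calls[:, 0] != int(GenotypeCall.FAILED)
        later = st.calls[:, 1:]
        later_failed = later == int(GenotypeCall.FAILED)
        call_diff = (later != st.calls[:, [0]]) & ~later_failed

        # PRV drift that sampling noise cannot explain
        n0 = st.depth[:, [0]].astype(float)
        nt = st.depth[:, 1:].astype(float)
        a0 = st.alt_reads[:, [0]].astype(float)
        at = st.alt_reads[:, 1:].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            pooled = (a0 + at) / (n0 + nt)
            se = np.sqrt(pooled * (1 - pooled) * (1 / n0 + 1 / nt))
            z = np.abs(at / nt - a0 / n0) / se
        prv_diff = np.abs(st.prv[:, 1:] - st.prv[:, [0]]) > prv_tolerance
        prv_diff &= np.isfinite(z) & (z > z_threshold)
        prv_diff &= np.isfinite(st.prv[:, 1:]) & np.isfinite(st.prv[:, [0]])

        is_changed = day0_ok & (call_diff | prv_diff).any(axis=1)
        has_failed = day0_ok & later_failed.any(axis=1)
        for i in np.nonzero(is_changed)[0]:
            changed.add(st.sites[i])
        for i in np.nonzero(has_failed & ~is_changed)[0]:
            failed_onset.add(st.sites[i])
    return changed, failed_onset - changed


def apply_filters(
    series_trajs: Mapping[tuple[str, str], SeriesTrajectories],
    cfg: FilterConfig = DEFAULT_FILTERS,
    candidate_sites: Iterable[SiteKey] | None = None,
) -> tuple[list[SiteKey], FilterAttrition]:
    """Apply the spectrum, day-0 genotype and depth gates, in that order.

    Returns surviving sites (genomic order) and per-gate attrition counts.
    ``candidate_sites`` restricts the input set (default: all sites).
    """
    trajs = list(series_trajs.values())
    if not trajs:
        raise ValueError("no series provided")
    sites = trajs[0].sites
    index = {s: i for i, s in enumerate(sites)}
    if candidate_sites is None:
        idx = np.arange(len(sites))
    else:
        idx = np.array(sorted(index[s] for s in candidate_sites), dtype=np.int64)

    att = FilterAttrition(n_input=len(idx))

    # (b) spectrum gate
    keep = np.array(
        [(sites[i].ref, sites[i].alt) in cfg.allowed_changes for i in idx], dtype=bool
    )
    att.removed_by_spectrum = int((~keep).sum())
    idx = idx[keep]

    # (c) day-0 homozygosity in every series
    if cfg.require_day0_homozygous:
        hom = np.ones(len(idx), dtype=bool)
        for st in trajs:
            day0 = st.calls[idx, 0]
            hom &= (day0 == int(GenotypeCall.HOM_REF)) | (
                day0 == int(GenotypeCall.HOM_ALT)
            )
        att.removed_by_day0_genotype = int((~hom).sum())
        idx = idx[hom]

    # (a) read-count threshold in every sample of every series (inclusive)
    deep = np.ones(len(idx), dtype=bool)
    for st in trajs:
        reads = st.depth if cfg.depth_mode == "total" else st.alt_reads
        deep &= (reads[idx] >= cfg.min_total_reads).all(axis=1)
    att.removed_by_depth = int((~deep).sum())
    idx = idx[deep]

    att.n_surviving = len(idx)
    return [sites[i] for i in idx], att


def select_candidates(
    surviving: Sequence[SiteKey],
    series_trajs: Mapping[tuple[str, str], SeriesTrajectories],
    monotone: MonotoneConfig = DEFAULT_MONOTONE,
    required_series: Iterable[tuple[str, str]] | None = None,
) -> list[CandidateMarker]:
    """Keep sites gradually monotone in the same direction in every series.

    ``required_series`` defaults to every series present.  A site missing a
    required series, or with any undefined PRV (coverage loss) in one, is
    skipped.  Output is sorted by genomic position.
    """
    required = list(required_series) if required_series is not None else list(series_trajs)
    missing = [s for s in required if s not in series_trajs]
    if missing:
        raise ValueError(f"required series absent from input: {missing}")
    if not surviving:
        return []
    trajs = [series_trajs[s] for s in required]
    index = {s: i for i, s in enumerate(trajs[0].sites)}
    idx = np.array([index[s] for s in surviving], dtype=np.int64)

    directions = np.zeros((len(idx), len(required)), dtype=np.int64)
    for k, st in enumerate(trajs):
        ok, direction = gradual_mask(st.prv[idx], monotone)
        directions[:, k] = np.where(ok, direction, 0)
    concordant = (directions != 0).all(axis=1) & (
        np.abs(directions.sum(axis=1)) == directions.shape[1]
    )

    markers: list[CandidateMarker] = []
    for row, i in zip(np.nonzero(concordant)[0], idx[concordant]):
        site = trajs[0].sites[i]
        per_series = {
            st.series: tuple(float(p) for p in st.prv[i]) for st in trajs
        }
        markers.append(
            CandidateMarker(
                site=site,
                direction="increasing" if directions[row, 0] > 0 else "decreasing",
                per_series_prv=per_series,
                day0_genotype=GenotypeCall(int(trajs[0].calls[i, 0])),
            )
        )
    markers.sort(key=lambda m: (m.site.chrom, m.site.pos, m.site.alt))
    return markers


def homozygote_switches(
    series_trajs: Mapping[tuple[str, str], SeriesTrajectories],
) -> tuple[dict[tuple[str, str], list[tuple[SiteKey, str]]], set[SiteKey]]:
    """Full homozygote switches (0/0->0/1->1/1 or the reverse) per series.

    Returns (per-series lists of (site, direction), the set of sites that
    switch in every series) — the cross-condition intersection mirrors how
    concordant switch positions are identified between storage conditions.
    """
    per_series: dict[tuple[str, str], list[tuple[SiteKey, str]]] = {}
    site_sets: list[set[SiteKey]] = []
    for key, st in series_trajs.items():
        labels, _ = classify_call_matrix(st.calls)
        entries: list[tuple[SiteKey, str]] = []
        for i, lab in enumerate(labels):
            if lab is TrajectoryClass.HOM_SWITCH_UP:
                entries.append((st.sites[i], "up"))
            elif lab is TrajectoryClass.HOM_SWITCH_DOWN:
                entries.append((st.sites[i], "down"))
        per_series[key] = entries
        site_sets.append({s for s, _ in entries})
    intersection = set.intersection(*site_sets) if site_sets else set()
    return per_series, intersection
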