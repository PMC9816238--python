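"""Changed-site detection, stepwise filters, candidate concordance, switches."""

from __future__ import annotations

import numpy as np
import pytest

from snvdrift.core import SampleMeta, SiteKey, StudyTable
from snvdrift.genotyping import GenotypeCall, call_study
from snvdrift.marker_selection import (
    FilterConfig,
    apply_filters,
    changed_sites,
    homozygote_switches,
    select_candidates,
)
from snvdrift.trajectories import MonotoneConfig, extract_series

from conftest import make_series_samples, table_from_counts

G = GenotypeCall


def two_series_table(site_counts: dict[SiteKey, dict[str, list[tuple[int, int, int]]]]):
    """Build a StudyTable with blood/dry and blood/humid series at 0/22/92 days.

    site_counts maps site -> {"dry": [(r,a,o) x3], "humid": [(r,a,o) x3]}.
    """
    samples = make_series_samples("blood", "dry") + make_series_samples("blood", "humid")
    sites = list(site_counts)
    counts = [
        [*site_counts[s]["dry"], *site_counts[s]["humid"]] for s in sites
    ]
    return table_from_counts(sites, samples, counts)


STABLE = [(30, 0, 0)] * 3
GRADUAL_UP = [(30, 0, 0), (24, 6, 0), (12, 18, 0)]  # PRV 0 -> 20 -> 60
GRADUAL_DOWN = [(0, 30, 0), (6, 24, 0), (18, 12, 0)]  # PRV 100 -> 80 -> 40
SHALLOW = [(30, 0, 0), (29, 1, 0), (27, 3, 0)]  # PRV 0 -> 3.3 -> 10 (< delta)


def series_of(table):
    return extract_series(call_study(table))


class TestChangedSites:
    def test_identical_counts_yield_empty_set(self):
        site = SiteKey("chr1", 100, "C", "T")
        table = two_series_table({site: {"dry": STABLE, "humid": STABLE}})
        changed, failed = changed_sites(series_of(table))
        assert changed == set() and failed == set()

    def test_genotype_change_is_detected(self):
        site = SiteKey("chr1", 100, "C", "T")
        table = two_series_table(
            {site: {"dry": [(30, 0, 0), (15, 15, 0), (15, 15, 0)], "humid": STABLE}}
        )
        changed, _ = changed_sites(series_of(table))
        assert changed == {site}

    def test_failed_only_site_reported_separately(self):
        site = SiteKey("chr1", 100, "C", "T")
        table = two_series_table(
            {site: {"dry": [(30, 0, 0), (30, 0, 0), (0, 0, 0)], "humid": STABLE}}
        )
        changed, failed = changed_sites(series_of(table))
        assert changed == set()
        assert failed == {site}

    def test_sampling_noise_at_het_sites_not_flagged(self):
        """A het PRV wobble explainable by binomial depth-30 sampling is no change."""
        site = SiteKey("chr1", 100, "C", "T")
        wobble = [(15, 15, 0), (18, 12, 0), (12, 18, 0)]  # PRV 50 / 40 / 60
        table = two_series_table({site: {"dry": wobble, "humid": wobble}})
        changed, _ = changed_sites(series_of(table))
        assert changed == set()

    def test_large_prv_drift_within_het_band_is_flagged(self):
        site = SiteKey("chr1", 100, "C", "T")
        drift = [(160, 40, 0), (120, 80, 0), (60, 140, 0)]  # PRV 20 -> 40 -> 70, deep
        table = two_series_table({site: {"dry": drift, "humid": drift}})
        changed, _ = changed_sites(series_of(table))
        assert changed == {site}


class TestApplyFilters:
    def build(self):
        sites = {
            SiteKey("chr1", 100, "C", "T"): {"dry": GRADUAL_UP, "humid": GRADUAL_UP},
            SiteKey("chr1", 200, "A", "C"): {"dry": GRADUAL_UP, "humid": GRADUAL_UP},
            SiteKey("chr1", 300, "G", "A"): {
                "dry": [(9, 0, 0), (7, 2, 0), (4, 5, 0)],  # depth 9 < 10
                "humid": GRADUAL_UP,
            },
            SiteKey("chr1", 400, "C", "T"): {
                "dry": [(15, 15, 0), (12, 18, 0), (6, 24, 0)],  # day-0 het
                "humid": [(15, 15, 0), (12, 18, 0), (6, 24, 0)],
            },
            SiteKey("chr1", 500, "G", "A"): {
                "dry": [(10, 0, 0), (8, 2, 0), (5, 5, 0)],  # depth exactly 10
                "humid": [(10, 0, 0), (8, 2, 0), (5, 5, 0)],
            },
        }
        return two_series_table(sites)

    def test_gate_order_and_attrition(self):
        table = self.build()
        surviving, att = apply_filters(series_of(table))
        assert att.n_input == 5
        assert att.removed_by_spectrum == 1  # the A>C site
        assert att.removed_by_day0_genotype == 1  # the day-0 het site
        assert att.removed_by_depth == 1  # the depth-9 site
        assert att.n_surviving == 2
        assert att.n_input == (
            att.removed_by_spectrum
            + att.removed_by_day0_genotype
            + att.removed_by_depth
            + att.n_surviving
        )
        assert {s.pos for s in surviving} == {100, 500}

    def test_threshold_is_inclusive(self):
        table = self.build()
        surviving, _ = apply_filters(series_of(table))
        assert SiteKey("chr1", 500, "G", "A") in surviving  # total exactly 10 kept

    def test_relaxing_threshold_never_shrinks_survivors(self):
        table = self.build()
        trajs = series_of(table)
        strict, _ = apply_filters(trajs, FilterConfig(min_total_reads=10))
        relaxed, _ = apply_filters(trajs, FilterConfig(min_total_reads=5))
        assert set(strict) <= set(relaxed)

    def test_day0_homozygosity_gate_optional(self):
        table = self.build()
        surviving, _ = apply_filters(
            series_of(table), FilterConfig(require_day0_homozygous=False)
        )
        assert SiteKey("chr1", 400, "C", "T") in surviving

    def test_alt_depth_mode(self):
        table = self.build()
        surviving, _ = apply_filters(
            series_of(table), FilterConfig(min_total_reads=2, depth_mode="alt")
        )
        # every site has a day-0 sample with 0 alt reads except the het one,
        # which fails the day-0 homozygosity gate
        assert surviving == []


class TestSelectCandidates:
    def test_concordant_gradual_site_selected(self):
        site = SiteKey("chr1", 100, "C", "T")
        table = two_series_table({site: {"dry": GRADUAL_UP, "humid": GRADUAL_UP}})
        trajs = series_of(table)
        markers = select_candidates([site], trajs)
        assert len(markers) == 1
        m = markers[0]
        assert m.site == site and m.direction == "increasing"
        assert m.day0_genotype is G.HOM_REF
        assert m.per_series_prv[("blood", "dry")] == pytest.approx((0.0, 20.0, 60.0))

    def test_gradual_in_one_series_only_rejected(self):
        site = SiteKey("chr1", 100, "C", "T")
        table = two_series_table({site: {"dry": GRADUAL_UP, "humid": STABLE}})
        assert select_candidates([site], series_of(table)) == []

    def test_direction_mismatch_rejected(self):
        site = SiteKey("chr1", 100, "C", "T")
        table = two_series_table({site: {"dry": GRADUAL_UP, "humid": GRADUAL_DOWN}})
        assert select_candidates([site], series_of(table)) == []

    def test_shallow_drift_below_delta_rejected(self):
        site = SiteKey("chr1", 100, "C", "T")
        table = two_series_table({site: {"dry": SHALLOW, "humid": SHALLOW}})
        assert select_candidates([site], series_of(table)) == []

    def test_missing_required_series_is_error(self):
        site = SiteKey("chr1", 100, "C", "T")
        table = two_series_table({site: {"dry": GRADUAL_UP, "humid": GRADUAL_UP}})
        with pytest.raises(ValueError, match="saliva"):
            select_candidates(
                [site], series_of(table), required_series=[("saliva", "dry")]
            )

    def test_selection_order_is_genomic_and_input_order_invariant(self):
        s1 = SiteKey("chr1", 200, "C", "T")
        s2 = SiteKey("chr1", 100, "G", "A")
        table = two_series_table(
            {s1: {"dry": GRADUAL_UP, "humid": GRADUAL_UP},
             s2: {"dry": GRADUAL_UP, "humid": GRADUAL_UP}}
        )
        trajs = series_of(table)
        a = select_candidates([s1, s2], trajs)
        b = select_candidates([s2, s1], trajs)
        assert [m.site for m in a] == [m.site for m in b] == [s2, s1]


class TestHomozygoteSwitches:
    SWITCH_UP = [(30, 0, 0), (15, 15, 0), (0, 30, 0)]
    SWITCH_DOWN = [(0, 30, 0), (15, 15, 0), (30, 0, 0)]

    def test_switches_found_per_series_and_intersection(self):
        both = SiteKey("chr1", 100, "C", "T")
        dry_only = SiteKey("chr1", 200, "G", "A")
        table = two_series_table(
            {
                both: {"dry": self.SWITCH_UP, "humid": self.SWITCH_UP},
                dry_only: {"dry": self.SWITCH_DOWN, "humid": STABLE},
            }
        )
        per_series, intersection = homozygote_switches(series_of(table))
        assert (both, "up") in per_series[("blood", "dry")]
        assert (dry_only, "down") in per_series[("blood", "dry")]
        assert per_series[("blood", "humid")] == [(both, "up")]
        assert intersection == {both}

    def test_empty_input(self):
        site = SiteKey("chr1", 100, "C", "T")
        table = two_series_table({site: {"dry": STABLE, "humid": STABLE}})
        per_series, intersection = homozygote_switches(series_of(table))
        assert all(v == [] for v in per_series.values())
        assert intersection == set()
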