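"""Trajectory classification, spectra, failed-call counting, gradual drift."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snvdrift.core import SiteKey
from snvdrift.genotyping import GenotypeCall
from snvdrift.trajectories import (
    BaseChangeClass,
    Day0FailedError,
    MonotoneConfig,
    SiteTrajectory,
    TrajectoryClass,
    classify_base_change,
    classify_call_matrix,
    classify_trajectory,
    count_failed_calls,
    genotype_transition_counts,
    is_gradual,
    spectrum_counts,
)

from conftest import make_site

G = GenotypeCall
C = TrajectoryClass


def traj(calls, prvs=None, times=(0, 22, 92)) -> SiteTrajectory:
    if prvs is None:
        prvs = tuple(
            None if c is G.FAILED else {G.HOM_REF: 0.0, G.HET: 50.0, G.HOM_ALT: 100.0}[c]
            for c in calls
        )
    return SiteTrajectory(make_site(), ("blood", "dry"), tuple(times), tuple(calls), tuple(prvs))


def oracle_label(calls: tuple[GenotypeCall, ...]) -> TrajectoryClass:
    """Independent brute-force labeler, straight from the classification rules."""
    assert calls[0] is not G.FAILED
    if G.FAILED in calls[1:]:
        return C.FAILED_ONSET
    if calls == (G.HOM_REF, G.HET, G.HOM_ALT):
        return C.HOM_SWITCH_UP
    if calls == (G.HOM_ALT, G.HET, G.HOM_REF):
        return C.HOM_SWITCH_DOWN
    pair = (calls[0], calls[-1])
    if pair[0] == pair[1]:
        return C.STABLE
    if pair == (G.HOM_REF, G.HET):
        return C.GAIN_HET
    if pair == (G.HOM_ALT, G.HET):
        return C.LOSS_HET
    if pair[0] is G.HET and pair[1] in (G.HOM_REF, G.HOM_ALT):
        return C.RESOLVE_TO_HOM
    return C.OTHER


class TestClassifyTrajectory:
    def test_exhaustive_64_triple_truth_table(self):
        """Every call triple classifies identically to brute-force enumeration."""
        n_checked = 0
        for calls in itertools.product(list(G), repeat=3):
            if calls[0] is G.FAILED:
                with pytest.raises(Day0FailedError):
                    classify_trajectory(traj(calls))
                continue
            assert classify_trajectory(traj(calls)) is oracle_label(calls)
            n_checked += 1
        assert n_checked == 48  # 3 day-0 states x 4 x 4

    @pytest.mark.parametrize(
        "calls,expected",
        [
            ((G.HOM_REF, G.HET, G.HOM_ALT), C.HOM_SWITCH_UP),
            ((G.HOM_ALT, G.HET, G.HOM_REF), C.HOM_SWITCH_DOWN),
            ((G.HOM_REF, G.HOM_REF, G.HOM_REF), C.STABLE),
            ((G.HOM_REF, G.FAILED, G.HOM_REF), C.FAILED_ONSET),
            ((G.HOM_REF, G.HOM_REF, G.HET), C.GAIN_HET),
            ((G.HOM_ALT, G.HOM_ALT, G.HET), C.LOSS_HET),
            ((G.HET, G.HET, G.HOM_ALT), C.RESOLVE_TO_HOM),
            ((G.HOM_REF, G.HOM_REF, G.HOM_ALT), C.OTHER),  # switch without het step
        ],
    )
    def test_named_patterns(self, calls, expected):
        assert classify_trajectory(traj(calls)) is expected

    def test_partition_property(self):
        """Each non-FAILED-day-0 site gets exactly one label; counts conserve."""
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 4, size=(500, 3)).astype(np.int8)
        labels, day0_failed = classify_call_matrix(calls)
        n_classified = sum(1 for lab in labels if lab is not None)
        assert n_classified + int(day0_failed.sum()) == 500
        for i in range(500):
            if not day0_failed[i]:
                assert labels[i] is oracle_label(tuple(G(int(c)) for c in calls[i]))

    def test_two_point_series_supported(self):
        t = traj((G.HOM_REF, G.HET), times=(0, 21))
        assert classify_trajectory(t) is C.GAIN_HET

    def test_day0_must_be_time_zero(self):
        with pytest.raises(ValueError):
            traj((G.HOM_REF, G.HET), times=(1, 21))


class TestFailedCallsAndTransitions:
    def test_count_failed(self):
        calls = [G.HOM_REF] * 7 + [G.FAILED] * 3
        assert count_failed_calls(calls) == 3
        assert count_failed_calls([G.HET, G.HOM_ALT]) == 0

    def test_transition_matrix_diagonal_for_identical_vectors(self):
        calls = [G.HOM_REF, G.HET, G.HOM_ALT, G.FAILED, G.HOM_REF]
        m = genotype_transition_counts(calls, calls)
        assert m.sum() == 5
        assert (m == np.diag(np.diag(m))).all()
        assert m[0, 0] == 2

    def test_single_off_diagonal_block(self):
        m = genotype_transition_counts([G.HOM_REF] * 5, [G.HET] * 5)
        assert m[0, 1] == 5 and m.sum() == 5

    def test_conservation_and_row_sums(self):
        rng = np.random.default_rng(1)
        a = [G(int(x)) for x in rng.integers(0, 4, 100)]
        b = [G(int(x)) for x in rng.integers(0, 4, 100)]
        m = genotype_transition_counts(a, b)
        assert m.sum() == 100
        for g in range(4):
            assert m[g].sum() == sum(1 for c in a if int(c) == g)

    def test_site_set_mismatch_is_error(self):
        with pytest.raises(ValueError):
            genotype_transition_counts([G.HOM_REF], [G.HET, G.HET])


COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class TestBaseChangeSpectrum:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("C", "T", BaseChangeClass.TYPE2_TRANSITION),
            ("G", "A", BaseChangeClass.TYPE2_TRANSITION),
            ("A", "G", BaseChangeClass.TYPE1_TRANSITION),
            ("T", "C", BaseChangeClass.TYPE1_TRANSITION),
            ("C", "G", BaseChangeClass.TRANSVERSION),
            ("A", "T", BaseChangeClass.TRANSVERSION),
            ("G", "T", BaseChangeClass.TRANSVERSION),
            ("C", "*", BaseChangeClass.SPANNING_DELETION),
        ],
    )
    def test_classification(self, ref, alt, expected):
        assert classify_base_change(SiteKey("chr1", 1, ref, alt)) is expected

    def test_spectrum_counts_sum_to_input(self):
        sites = [
            SiteKey("chr1", 1, "C", "T"),
            SiteKey("chr1", 2, "G", "A"),
            SiteKey("chr1", 3, "A", "G"),
            SiteKey("chr1", 4, "T", "C"),
            SiteKey("chr1", 5, "C", "*"),
        ]
        pairs, classes = spectrum_counts(sites)
        assert sum(classes.values()) == 5
        assert classes[BaseChangeClass.TYPE2_TRANSITION] == 2
        assert pairs[("C", "T")] == 1 and pairs[("*", "*")] == 1
        assert len([p for p in pairs if p != ("*", "*")]) == 12

    def test_empty_input_all_zero(self):
        pairs, classes = spectrum_counts([])
        assert all(v == 0 for v in pairs.values())
        assert all(v == 0 for v in classes.values())

    def test_reverse_complement_symmetry(self):
        """Complementing every (ref, alt) swaps G>A with C>T and keeps class totals."""
        rng = np.random.default_rng(2)
        bases = "ACGT"
        sites, comp_sites = [], []
        for i in range(300):
            r, a = rng.choice(4, size=2, replace=False)
            sites.append(SiteKey("chr1", i + 1, bases[r], bases[a]))
            comp_sites.append(
                SiteKey("chr1", i + 1, COMPLEMENT[bases[r]], COMPLEMENT[bases[a]])
            )
        pairs, classes = spectrum_counts(sites)
        cpairs, cclasses = spectrum_counts(comp_sites)
        assert classes == cclasses
        assert pairs[("G", "A")] == cpairs[("C", "T")]
        assert pairs[("C", "T")] == cpairs[("G", "A")]


class TestIsGradual:
    def test_exemplar_increasing_profile(self):
        t = traj((G.HOM_REF, G.HET, G.HOM_ALT), prvs=(0.0, 20.0, 98.0))
        ok, direction = is_gradual(t, MonotoneConfig(direction="increasing"))
        assert ok and direction == "increasing"

    def test_non_monotone_rejected(self):
        t = traj((G.HOM_REF, G.HET, G.HET), prvs=(0.0, 50.0, 30.0))
        ok, _ = is_gradual(t, MonotoneConfig(direction="increasing"))
        assert not ok

    def test_flat_profile_below_delta_rejected(self):
        t = traj((G.HET, G.HET, G.HET), prvs=(10.0, 10.0, 10.0))
        ok, direction = is_gradual(t, MonotoneConfig(direction="either"))
        assert not ok and direction is None

    def test_backsliding_within_tolerance_allowed(self):
        t = traj((G.HOM_REF, G.HET, G.HET), prvs=(0.0, 30.0, 28.5))
        ok, _ = is_gradual(t, MonotoneConfig(direction="increasing", per_step_tolerance=2.0))
        assert ok

    def test_decreasing_direction(self):
        t = traj((G.HOM_ALT, G.HET, G.HOM_REF), prvs=(100.0, 60.0, 5.0))
        ok, direction = is_gradual(t)
        assert ok and direction == "decreasing"

    def test_undefined_prv_is_error(self):
        t = traj((G.HOM_REF, G.FAILED, G.HET))
        with pytest.raises(ValueError, match="undefined PRV"):
            is_gradual(t)

    @settings(derandomize=True, max_examples=200)
    @given(prvs=st.lists(st.integers(0, 100), min_size=3, max_size=3))
    def test_zero_tolerance_reduces_to_strict_monotonicity(self, prvs):
        """With no tolerance and vanishing delta, gradual == monotone non-flat."""
        cfg = MonotoneConfig(direction="either", min_total_delta=1e-9, per_step_tolerance=0.0)
        t = traj((G.HET,) * 3, prvs=tuple(float(p) for p in prvs))
        ok, _ = is_gradual(t, cfg)
        inc = all(b >= a for a, b in zip(prvs, prvs[1:])) and prvs[-1] > prvs[0]
        dec = all(b <= a for a, b in zip(prvs, prvs[1:])) and prvs[-1] < prvs[0]
        assert ok == (inc or dec)
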