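"""Shared fixtures: tiny hand-built study tables and seeded simulations."""

from __future__ import annotations

import numpy as np
import pytest

from snvdrift.core import SampleMeta, SiteKey, StudyTable
from snvdrift.synthetic_data import DamageModel, SimDesign, simulate_counts, simulate_truth


def make_site(pos: int = 100, ref: str = "C", alt: str = "T") -> SiteKey:
    return SiteKey("chr1", pos, ref, alt)


def make_series_samples(
    matrix: str = "blood", condition: str = "dry", times=(0, 22, 92)
) -> list[SampleMeta]:
    return [SampleMeta(f"{matrix}_{condition}_d{t}", matrix, condition, t) for t in times]


def table_from_counts(sites, samples, counts) -> StudyTable:
    """Build a StudyTable from a nested list of (ref, alt, other) triples."""
    return StudyTable(sites, samples, np.asarray(counts, dtype=np.int64))


@pytest.fixture(scope="session")
def default_sim():
    """One seeded default-parameter simulation shared across tests."""
    design = SimDesign(n_sites=20_000, seed=20260926)
    model = DamageModel()
    truth = simulate_truth(design, model)
    table = simulate_counts(truth, design, model)
    return design, model, truth, table


@pytest.fixture(scope="session")
def nodamage_sim():
    """All rates zero, no sequencing error: the no-damage identity fixture."""
    design = SimDesign(n_sites=5_000, seed=42)
    model = DamageModel(
        deam_rate=0.0,
        marker_deam_rate=0.0,
        switch_deam_rate=0.0,
        cov_decay_rate=0.0,
        fragile_decay_rate=0.0,
        fragile_fraction=0.0,
        seq_error_rate=0.0,
        spandel_rate=0.0,
    )
    truth = simulate_truth(design, model)
    table = simulate_counts(truth, design, model)
    return design, model, truth, table
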