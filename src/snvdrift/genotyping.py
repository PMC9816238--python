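"""PRV computation and genotype allocation from read counts.

PRV (percentage reads of variant) is 100 x alt_reads / total_reads, the
denominator covering all detected alleles at the position.  Genotypes are
allocated from PRV with an error-tolerant band: PRV near 0 is homozygous
reference (0/0), near 100 homozygous alternative (1/1), and anything in
between heterozygous (0/1).  A position with no coverage at all has no call
(FAILED).  The literal rule — exactly 0% is 0/0, exactly 100% is 1/1,
anything else 0/1 — is the limiting case of the band caller with the band
edges at 0/100 and the minimum-read guard at one read.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .core import ReadObservation, SiteKey, StudyTable


class GenotypeCall(IntEnum):
    """Diploid genotype call relative to the reference genome."""

    HOM_REF = 0  # 0/0
    HET = 1  # 0/1
    HOM_ALT = 2  # 1/1
    FAILED = 3  # no coverage

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return {0: "0/0", 1: "0/1", 2: "1/1", 3: "FAILED"}[int(self)]


GENOTYPE_LABELS = ("0/0", "0/1", "1/1", "FAILED")


@dataclass(frozen=True)
class CallingConfig:
    """Thresholds for the PRV-band genotype caller.

    het_band_low / het_band_high
        PRV percentages delimiting the heterozygous band; outside the band
        the call collapses to the nearer homozygote.
    min_alt_reads_for_het
        minimum minor-allele reads before a non-reference (or non-alternative)
        signal is believed; below it the observation is treated as sequencing
        error.  Applies symmetrically to alt reads (guarding 0/0) and ref
        reads (guarding 1/1).
    coverage_floor
        minimum total reads for a call; below it the call is FAILED.  The
        default 1 makes FAILED mean exactly "no coverage".
    """

    het_band_low: float = 5.0
    het_band_high: float = 95.0
    min_alt_reads_for_het: int = 2
    coverage_floor: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.het_band_low < self.het_band_high < 100):
            raise ValueError("need 0 < het_band_low < het_band_high < 100")
        if self.min_alt_reads_for_het < 1:
            raise ValueError("min_alt_reads_for_het must be >= 1")
        if self.coverage_floor < 1:
            raise ValueError("coverage_floor must be >= 1")


DEFAULT_CALLING = CallingConfig()


def compute_prv(obs: ReadObservation) -> float:
    """PRV of one observation: 100 x alt / (ref + alt + other).

    Raises ValueError when total reads are zero (PRV is undefined; callers
    must branch on FAILED first).
    """
    total = obs.total_reads
    if total == 0:
        raise ValueError(
            f"PRV undefined at {obs.site.chrom}:{obs.site.pos} sample "
            f"{obs.sample_id}: no coverage"
        )
    return 100.0 * obs.alt_reads / total


def allocate_genotype(
    obs: ReadObservation, cfg: CallingConfig = DEFAULT_CALLING
) -> GenotypeCall:
    """Allocate a genotype call from one read observation."""
    total = obs.total_reads
    if total < cfg.coverage_floor:
        return GenotypeCall.FAILED
    prv = 100.0 * obs.alt_reads / total
    if prv < cfg.het_band_low or obs.alt_reads < cfg.min_alt_reads_for_het:
        return GenotypeCall.HOM_REF
    if prv > cfg.het_band_high and obs.ref_reads < cfg.min_alt_reads_for_het:
        return GenotypeCall.HOM_ALT
    return GenotypeCall.HET


class CallMatrix:
    """Genotype calls and PRVs for every (site, sample) of a StudyTable.

    ``calls`` is an (n_sites, n_samples) int8 array of GenotypeCall codes;
    ``prv`` a float array with NaN where the call is FAILED.
    """

    def __init__(self, table: StudyTable, calls: np.ndarray, prv: np.ndarray) -> None:
        self.table = table
        self.calls = calls
        self.prv = prv

    def __getitem__(
        self, key: tuple[SiteKey, str]
    ) -> tuple[GenotypeCall, float | None]:
        site, sample_id = key
        i = self.table.site_index(site)
        j = self.table.sample_index(sample_id)
        call = GenotypeCall(int(self.calls[i, j]))
        value = None if call is GenotypeCall.FAILED else float(self.prv[i, j])
        return call, value


def call_study(table: StudyTable, cfg: CallingConfig = DEFAULT_CALLING) -> CallMatrix:
    """Vectorized genotype allocation over a whole StudyTable.

    Equivalent to applying :func:`allocate_genotype` and :func:`compute_prv`
    observation by observation.
    """
    ref = table.counts[:, :, 0]
    alt = table.counts[:, :, 1]
    total = table.counts.sum(axis=2)
    covered = total >= cfg.coverage_floor

    with np.errstate(divide="ignore", invalid="ignore"):
        prv = np.where(covered, 100.0 * alt / np.maximum(total, 1), np.nan)

    calls = np.full(total.shape, GenotypeCall.HET, dtype=np.int8)
    hom_ref = (prv < cfg.het_band_low) | (alt < cfg.min_alt_reads_for_het)
    hom_alt = (prv > cfg.het_band_high) & (ref < cfg.min_alt_reads_for_het)
    calls[covered & hom_ref] = GenotypeCall.HOM_REF
    calls[covered & ~hom_ref & hom_alt] = GenotypeCall.HOM_ALT
    calls[~covered] = GenotypeCall.FAILED
    prv = np.where(covered, prv, np.nan)
    return CallMatrix(table, calls, prv)
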