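"""Core domain types for storage-induced SNV analysis.

The pipeline works on read counts at biallelic single-nucleotide variant
sites observed in the same donor across storage time points.  A
:class:`StudyTable` holds one :class:`ReadObservation` per (site, sample)
pair; zero counts encode absence of sequencing coverage ("failed" calls
downstream), so the table is always dense.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

CANONICAL_BASES = ("A", "C", "G", "T")
SPANNING_DELETION = "*"

#: valid alt alleles: a canonical base or the VCF spanning-deletion allele
VALID_ALTS = CANONICAL_BASES + (SPANNING_DELETION,)


@dataclass(frozen=True, order=True, slots=True)
class SiteKey:
    """One biallelic variant site: chromosome, 1-based position, ref and alt.

    ``alt == "*"`` marks a spanning deletion (reads whose alignment deletes
    through the position); such sites are excluded from base-substitution
    spectra but tracked in their own category.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (got {self.pos})")
        if self.ref not in CANONICAL_BASES:
            raise ValueError(f"ref must be one of {CANONICAL_BASES} (got {self.ref!r})")
        if self.alt not in VALID_ALTS:
            raise ValueError(f"alt must be one of {VALID_ALTS} (got {self.alt!r})")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def is_spanning_deletion(self) -> bool:
        return self.alt == SPANNING_DELETION


MATRICES = ("blood", "saliva")
CONDITIONS = ("dry", "humid", "none")


@dataclass(frozen=True, order=True, slots=True)
class SampleMeta:
    """Metadata for one sequenced sample.

    ``time_days == 0`` samples are the truth reference: the unstored
    sample's genotype is treated as the donor's true genotype and every
    later difference is attributed to storage.
    """

    sample_id: str
    matrix: str
    condition: str
    time_days: int

    def __post_init__(self) -> None:
        if self.matrix not in MATRICES:
            raise ValueError(f"matrix must be one of {MATRICES} (got {self.matrix!r})")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS} (got {self.condition!r})"
            )
        if self.time_days < 0:
            raise ValueError("time_days must be >= 0")

    @property
    def series(self) -> tuple[str, str]:
        """The (matrix, condition) series this sample belongs to."""
        return (self.matrix, self.condition)


@dataclass(frozen=True, slots=True)
class ReadObservation:
    """Per-sample read counts at one site.

    ``other_reads`` are reads supporting neither the reference nor the
    recorded alternative allele (remaining alternatives of a decomposed
    multi-allelic record, or sequencing-error bases).
    """

    site: SiteKey
    sample_id: str
    ref_reads: int
    alt_reads: int
    other_reads: int = 0

    def __post_init__(self) -> None:
        for name in ("ref_reads", "alt_reads", "other_reads"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer (got {v!r})")

    @property
    def total_reads(self) -> int:
        return self.ref_reads + self.alt_reads + self.other_reads


def genomic_sort_key(site: SiteKey) -> tuple[str, int, str]:
    return (site.chrom, site.pos, site.alt)


class StudyTable:
    """Dense read-count table: sites x samples x (ref, alt, other).

    Counts are stored in a single ``(n_sites, n_samples, 3)`` integer array;
    a (site, sample) cell of all zeros encodes absence of coverage.  Sites
    are kept in genomic order (chrom, pos, alt).
    """

    def __init__(
        self,
        sites: Sequence[SiteKey],
        samples: Sequence[SampleMeta],
        counts: np.ndarray,
    ) -> None:
        counts = np.asarray(counts)
        if counts.shape != (len(sites), len(samples), 3):
            raise ValueError(
                f"counts shape {counts.shape} != ({len(sites)}, {len(samples)}, 3)"
            )
        if counts.size and counts.min() < 0:
            raise ValueError("read counts must be non-negative")
        if len({s.sample_id for s in samples}) != len(samples):
            raise ValueError("duplicate sample_id")
        if len(set(sites)) != len(sites):
            raise ValueError("duplicate site")
        order = sorted(range(len(sites)), key=lambda i: genomic_sort_key(sites[i]))
        self.sites: list[SiteKey] = [sites[i] for i in order]
        self.samples: list[SampleMeta] = list(samples)
        self.counts: np.ndarray = counts[order].astype(np.int64, copy=False)
        self._site_index = {s: i for i, s in enumerate(self.sites)}
        self._sample_index = {s.sample_id: j for j, s in enumerate(self.samples)}

    # -- construction -----------------------------------------------------

    @classmethod
    def from_observations(
        cls,
        sites: Iterable[SiteKey],
        samples: Iterable[SampleMeta],
        observations: Iterable[ReadObservation],
    ) -> "StudyTable":
        sites = list(sites)
        samples = list(samples)
        site_idx = {s: i for i, s in enumerate(sites)}
        samp_idx = {s.sample_id: j for j, s in enumerate(samples)}
        counts = np.zeros((len(sites), len(samples), 3), dtype=np.int64)
        seen: set[tuple[SiteKey, str]] = set()
        for obs in observations:
            key = (obs.site, obs.sample_id)
            if key in seen:
                raise ValueError(f"duplicate observation for {key}")
            seen.add(key)
            i = site_idx[obs.site]
            j = samp_idx[obs.sample_id]
            counts[i, j] = (obs.ref_reads, obs.alt_reads, obs.other_reads)
        return cls(sites, samples, counts)

    # -- access -----------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_index(self, site: SiteKey) -> int:
        return self._site_index[site]

    def sample_index(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def sample_meta(self, sample_id: str) -> SampleMeta:
        return self.samples[self._sample_index[sample_id]]

    def observation(self, site: SiteKey, sample_id: str) -> ReadObservation:
        i = self._site_index[site]
        j = self._sample_index[sample_id]
        ref, alt, other = (int(v) for v in self.counts[i, j])
        return ReadObservation(site, sample_id, ref, alt, other)

    def iter_observations(self) -> Iterator[ReadObservation]:
        for i, site in enumerate(self.sites):
            for j, samp in enumerate(self.samples):
                ref, alt, other = (int(v) for v in self.counts[i, j])
                yield ReadObservation(site, samp.sample_id, ref, alt, other)

    def total_depth(self) -> np.ndarray:
        """(n_sites, n_samples) array of total read counts."""
        return self.counts.sum(axis=2)

    def series_keys(self) -> list[tuple[str, str]]:
        """Distinct (matrix, condition) series, in first-seen order."""
        seen: list[tuple[str, str]] = []
        for s in self.samples:
            if s.series not in seen:
                seen.append(s.series)
        return seen

    def series_samples(self, series: tuple[str, str]) -> list[SampleMeta]:
        """Samples of one series, ordered by time; requires a day-0 sample."""
        members = sorted(
            (s for s in self.samples if s.series == series),
            key=lambda s: s.time_days,
        )
        if not members:
            raise KeyError(f"no samples for series {series}")
        return members

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StudyTable):
            return NotImplemented
        return (
            self.sites == other.sites
            and self.samples == other.samples
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return f"StudyTable(n_sites={self.n_sites}, n_samples={self.n_samples})"
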