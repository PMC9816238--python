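"""Readers and writers for the pipeline's file formats.

Supported inputs are a multi-sample VCF with GATK-style per-genotype AD/DP
fields, or an equivalent TSV counts table.  Multi-allelic VCF records are
decomposed into one biallelic record per alternative allele; depth on the
remaining alternatives is carried as ``other_reads`` so PRV denominators
cover all detected alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    CANONICAL_BASES,
    SPANNING_DELETION,
    SampleMeta,
    SiteKey,
    StudyTable,
)

logger = logging.getLogger(__name__)

COUNTS_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "sample_id",
    "ref_reads",
    "alt_reads",
    "other_reads",
]

META_COLUMNS = ["sample_id", "matrix", "condition", "time_days"]


@dataclass
class VcfReadStats:
    """Counts of records handled while reading a VCF."""

    records: int = 0
    biallelic_emitted: int = 0
    skipped_symbolic: int = 0
    skipped_non_snv: int = 0


def read_vcf(
    path: str | Path,
    sample_meta: Mapping[str, SampleMeta],
    return_stats: bool = False,
) -> StudyTable | tuple[StudyTable, VcfReadStats]:
    """Read a multi-sample VCF with AD/DP into a :class:`StudyTable`.

    Every VCF sample must appear in ``sample_meta``.  Multi-allelic records
    are decomposed per alternative allele; symbolic alleles other than the
    spanning-deletion ``*`` are skipped (counted in the returned stats).
    Samples with missing genotype data at a record get (0, 0, 0) counts,
    the absence-of-coverage encoding.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    unknown = [s for s in vcf_samples if s not in sample_meta]
    if unknown:
        raise ValueError(f"VCF sample(s) not in sample metadata: {unknown}")
    samples = [sample_meta[s] for s in vcf_samples]
    if any(samples[j].sample_id != vcf_samples[j] for j in range(len(samples))):
        raise ValueError("sample_meta sample_id must match its mapping key")

    stats = VcfReadStats()
    sites: list[SiteKey] = []
    rows: list[np.ndarray] = []
    n = len(vcf_samples)

    for variant in vcf:
        stats.records += 1
        ref = variant.REF
        alts = list(variant.ALT)
        if ref not in CANONICAL_BASES:
            stats.skipped_non_snv += 1
            continue
        ad = variant.format("AD")
        if ad is None:
            raise ValueError(
                f"record {variant.CHROM}:{variant.POS} lacks the AD (allelic "
                "depth) FORMAT field"
            )
        ad = np.asarray(ad, dtype=np.int64)
        if ad.ndim == 1:
            ad = ad.reshape(n, -1)
        ad = np.where(ad < 0, 0, ad)  # missing-genotype fill values -> no coverage
        dp = variant.format("DP")
        if dp is None:
            total = ad.sum(axis=1)
        else:
            dp = np.asarray(dp, dtype=np.int64).reshape(n)
            total = np.maximum(np.where(dp < 0, 0, dp), ad.sum(axis=1))

        usable = []  # (alt allele, AD column index)
        for k, alt in enumerate(alts):
            if alt in CANONICAL_BASES or alt == SPANNING_DELETION:
                if len(alt) == 1 and len(ref) == 1:
                    usable.append((alt, k + 1))
                else:
                    stats.skipped_non_snv += 1
            elif alt.startswith("<") or any(c in alt for c in "[]"):
                stats.skipped_symbolic += 1
            else:
                stats.skipped_non_snv += 1
        if not usable:
            continue
        alt_depth_total = ad[:, 1:].sum(axis=1) if ad.shape[1] > 1 else np.zeros(n, int)
        for alt, col in usable:
            site = SiteKey(variant.CHROM, variant.POS, ref, alt)
            ref_reads = ad[:, 0]
            alt_reads = ad[:, col] if col < ad.shape[1] else np.zeros(n, int)
            # depth on remaining alternatives + any DP excess over the AD sum
            other = (alt_depth_total - alt_reads) + (total - ad.sum(axis=1))
            other = np.maximum(other, 0)
            sites.append(site)
            rows.append(np.stack([ref_reads, alt_reads, other], axis=1))
            stats.biallelic_emitted += 1

    if stats.skipped_symbolic:
        logger.info("skipped %d symbolic-allele records", stats.skipped_symbolic)
    counts = (
        np.stack(rows, axis=0)
        if rows
        else np.zeros((0, len(samples), 3), dtype=np.int64)
    )
    table = StudyTable(sites, samples, counts)
    return (table, stats) if return_stats else table


def write_counts_table(table: StudyTable, path: str | Path) -> None:
    """Write a StudyTable as a deterministic TSV (one row per observation).

    Fixed column order, genomic sort order, LF line endings; writing the
    same table twice produces byte-identical files.
    """
    records = []
    for i, site in enumerate(table.sites):
        for j, samp in enumerate(table.samples):
            ref, alt, other = (int(v) for v in table.counts[i, j])
            records.append(
                (site.chrom, site.pos, site.ref, site.alt, samp.sample_id, ref, alt, other)
            )
    df = pd.DataFrame.from_records(records, columns=COUNTS_COLUMNS)
    df = df.sort_values(["chrom", "pos", "alt", "sample_id"], kind="mergesort")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_counts_table(
    path: str | Path, sample_meta: Mapping[str, SampleMeta] | None = None
) -> StudyTable:
    """Read a TSV counts table written by :func:`write_counts_table`.

    Round-trips bit-exactly with the writer.  If ``sample_meta`` is not
    given, samples get placeholder metadata parsed from nothing (blood,
    condition "none", time 0) — supply metadata for any temporal analysis.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"counts table missing column(s): {missing}")

    sites: list[SiteKey] = []
    site_idx: dict[SiteKey, int] = {}
    sample_ids: list[str] = []
    samp_idx: dict[str, int] = {}
    seen: set[tuple[int, int]] = set()

    for pos_in_file, row in enumerate(df.itertuples(index=False)):
        line_no = pos_in_file + 2  # header is line 1
        try:
            site = SiteKey(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed row for {row.chrom}:{row.pos}: {exc}") from exc
        if site not in site_idx:
            site_idx[site] = len(sites)
            sites.append(site)
        sid = str(row.sample_id)
        if sid not in samp_idx:
            samp_idx[sid] = len(sample_ids)
            sample_ids.append(sid)
        key = (site_idx[site], samp_idx[sid])
        if key in seen:
            raise ValueError(
                f"duplicate (site, sample) row at line {line_no}: "
                f"{site.chrom}:{site.pos} {site.ref}>{site.alt} / {sid}"
            )
        seen.add(key)

    counts = np.zeros((len(sites), len(sample_ids), 3), dtype=np.int64)
    for row in df.itertuples(index=False):
        site = SiteKey(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        i, j = site_idx[site], samp_idx[str(row.sample_id)]
        for k, col in enumerate(("ref_reads", "alt_reads", "other_reads")):
            v = int(getattr(row, col))
            if v < 0:
                raise ValueError(f"negative {col} at {site.chrom}:{site.pos}/{row.sample_id}")
            counts[i, j, k] = v

    if sample_meta is None:
        samples = [SampleMeta(s, "blood", "none", 0) for s in sample_ids]
    else:
        try:
            samples = [sample_meta[s] for s in sample_ids]
        except KeyError as exc:
            raise ValueError(f"sample {exc} missing from sample metadata") from exc
    return StudyTable(sites, samples, counts)


def write_sample_meta(samples: list[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.sample_id, s.matrix, s.condition, s.time_days) for s in samples],
        columns=META_COLUMNS,
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_sample_meta(path: str | Path) -> dict[str, SampleMeta]:
    """Read the sample metadata TSV: sample_id, matrix, condition, time_days."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample metadata missing column(s): {missing}")
    out: dict[str, SampleMeta] = {}
    for row in df.itertuples(index=False):
        sid = str(row.sample_id)
        if sid in out:
            raise ValueError(f"duplicate sample_id {sid!r} in metadata")
        out[sid] = SampleMeta(sid, str(row.matrix), str(row.condition), int(row.time_days))
    return out
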