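"""Forward simulation of storage-induced DNA damage at variant sites.

The generator emulates the data-generating process the analysis assumes:
a single donor's true diploid genotype per site, time-dependent hydrolytic
deamination converting template molecules (C>T on one strand, G>A on the
other), coverage decay producing zero-coverage failed calls (stronger under
humid storage), a small per-read sequencing-error background, and spanning
deletions accumulating at a separate rate.

Damage acts on the per-read conversion probability, not on the genotype
state: a 0/0 site with conversion fraction d(t) = 1 - exp(-lambda * t) reads
as alt with probability ~d(t), so intermediate PRVs and gradual drift arise
naturally and full homozygote switches only occur when the rate is high
enough to saturate within the study window.

Planted ground truth (marker / switch roles per site) lets downstream
recovery be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import CANONICAL_BASES, SampleMeta, SiteKey, StudyTable
from .genotyping import GenotypeCall


class SiteRole(Enum):
    """Ground-truth role of a simulated site."""

    NULL = "null"  # background only (sequencing error)
    DAMAGE_PRONE = "damage_prone"  # deamination at the base rate
    PLANTED_MARKER = "planted_marker"  # elevated rate: gradual PRV drift
    PLANTED_SWITCH = "planted_switch"  # rate saturating within the window


@dataclass(frozen=True)
class TruthSite:
    """One simulated site with its ground truth.

    ``fragile`` marks depurination-prone loci whose coverage decays at the
    fast rate (the zero-coverage failure mechanism).
    """

    site: SiteKey
    true_genotype: GenotypeCall
    role: SiteRole
    fragile: bool = False

    def __post_init__(self) -> None:
        if self.role in (SiteRole.PLANTED_MARKER, SiteRole.PLANTED_SWITCH, SiteRole.DAMAGE_PRONE):
            if (self.site.ref, self.site.alt) not in {("C", "T"), ("G", "A")}:
                raise ValueError(
                    f"{self.role.value} requires a deamination-eligible (ref, alt); "
                    f"got {self.site.ref}>{self.site.alt}"
                )
        if self.true_genotype is GenotypeCall.FAILED:
            raise ValueError("true genotype cannot be FAILED")


@dataclass(frozen=True)
class DamageModel:
    """Rates of the hydrolytic-damage process (per day unless noted).

    deam_rate
        base per-day deamination rate at damage-prone sites; the fraction of
        converted templates after t days is 1 - exp(-rate * t).
    marker_deam_rate / switch_deam_rate
        elevated site-specific rates for planted markers (gradual drift,
        e.g. PRV ~0 -> ~20 -> ~60 over 0/22/92 days dry) and planted
        switches (saturating to ~100% by the last time point).
    cov_decay_rate / fragile_decay_rate / fragile_fraction
        exponential mean-coverage decay; most sites decay slowly, a small
        fragile (depurination-prone) fraction decays fast enough to drop to
        zero coverage within the study window.
    humid_multiplier
        factor >= 1 applied to all damage and decay rates under humid storage.
    seq_error_rate
        per-read probability of a miscall, spread uniformly over the three
        non-template bases.
    spandel_rate
        per-day rate at which reads at a spanning-deletion site convert to
        deletion evidence.
    saliva_prestorage_days
        optional effective pre-storage time added to saliva series (cell-free
        DNA in the oral cavity is effectively stored humid before sampling);
        disabled by default.
    """

    deam_rate: float = 0.005
    marker_deam_rate: float = 0.01
    switch_deam_rate: float = 0.05
    cov_decay_rate: float = 0.002
    fragile_decay_rate: float = 0.05
    fragile_fraction: float = 0.02
    humid_multiplier: float = 1.5
    seq_error_rate: float = 0.001
    spandel_rate: float = 0.002
    saliva_prestorage_days: float = 0.0

    def __post_init__(self) -> None:
        rates = (
            self.deam_rate,
            self.marker_deam_rate,
            self.switch_deam_rate,
            self.cov_decay_rate,
            self.fragile_decay_rate,
            self.spandel_rate,
        )
        if any(r < 0 for r in rates):
            raise ValueError("rates must be >= 0")
        if not 0 <= self.fragile_fraction <= 1:
            raise ValueError("fragile_fraction must be in [0, 1]")
        if self.humid_multiplier < 1:
            raise ValueError("humid_multiplier must be >= 1")
        if not 0 <= self.seq_error_rate < 0.01:
            raise ValueError("seq_error_rate must be in [0, 0.01)")


DEFAULT_MODEL = DamageModel()

DEFAULT_ROLE_FRACTIONS: Mapping[SiteRole, float] = {
    SiteRole.NULL: 0.80,
    SiteRole.DAMAGE_PRONE: 0.15,
    SiteRole.PLANTED_MARKER: 0.03,
    SiteRole.PLANTED_SWITCH: 0.02,
}

DEFAULT_GENOTYPE_FREQS: Mapping[GenotypeCall, float] = {
    GenotypeCall.HOM_REF: 0.70,
    GenotypeCall.HET: 0.20,
    GenotypeCall.HOM_ALT: 0.10,
}

DEFAULT_SERIES: tuple[tuple[str, str], ...] = (
    ("blood", "dry"),
    ("blood", "humid"),
    ("saliva", "dry"),
    ("saliva", "humid"),
)


@dataclass(frozen=True)
class SimDesign:
    """Study design of a simulation: sizes, time points, series, seed.

    Defaults mirror the follow-up study layout: blood and saliva stored dry
    and humid, sampled at 0, 22 and 92 days, ~30x day-0 coverage.  Role
    quotas are exact (quota sampling, not binomial).
    """

    n_sites: int = 20_000
    role_fractions: Mapping[SiteRole, float] = field(
        default_factory=lambda: dict(DEFAULT_ROLE_FRACTIONS)
    )
    genotype_freqs: Mapping[GenotypeCall, float] = field(
        default_factory=lambda: dict(DEFAULT_GENOTYPE_FREQS)
    )
    spandel_fraction: float = 0.02
    mean_coverage: float = 30.0
    time_points: tuple[int, ...] = (0, 22, 92)
    series: tuple[tuple[str, str], ...] = DEFAULT_SERIES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if abs(sum(self.role_fractions.values()) - 1) > 1e-9:
            raise ValueError("role fractions must sum to 1")
        if abs(sum(self.genotype_freqs.values()) - 1) > 1e-9:
            raise ValueError("genotype frequencies must sum to 1")
        if self.time_points[0] != 0 or any(
            b <= a for a, b in zip(self.time_points, self.time_points[1:])
        ):
            raise ValueError("time points must start at 0 and increase")
        if not 0 <= self.spandel_fraction <= 1:
            raise ValueError("spandel_fraction must be in [0, 1]")

    def sample_meta(self) -> list[SampleMeta]:
        """One sample per (series, time point), in design order."""
        out = []
        for matrix, condition in self.series:
            for t in self.time_points:
                out.append(
                    SampleMeta(f"{matrix}_{condition}_d{t}", matrix, condition, t)
                )
        return out


DEFAULT_DESIGN = SimDesign()

_GT_FRACTION = {GenotypeCall.HOM_REF: 0.0, GenotypeCall.HET: 0.5, GenotypeCall.HOM_ALT: 1.0}
_DEAM_PAIRS = (("C", "T"), ("G", "A"))


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic substream: one generator per stable integer key."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def simulate_truth(
    design: SimDesign = DEFAULT_DESIGN, model: DamageModel = DEFAULT_MODEL
) -> list[TruthSite]:
    """Draw ground-truth sites: positions, alleles, genotypes, roles, fragility.

    Role quotas are exact; planted roles are assigned only deamination-
    eligible (C>T / G>A) alleles and a homozygous-reference day-0 genotype
    (drift starts from PRV 0).  Null-site alleles are uniform over the 12
    substitutions, except a ``spandel_fraction`` share carrying the
    spanning-deletion allele.  Reproducible given the design seed.
    """
    rng = _rng(design.seed, 0)
    n = design.n_sites

    # exact role quotas, largest-remainder rounding, then shuffled
    quotas: dict[SiteRole, int] = {}
    remainders = []
    used = 0
    for role in SiteRole:
        frac = design.role_fractions.get(role, 0.0)
        q = int(frac * n)
        quotas[role] = q
        used += q
        remainders.append((frac * n - q, role.value, role))
    for _, _, role in sorted(remainders, reverse=True)[: n - used]:
        quotas[role] += 1
    roles = np.concatenate(
        [np.full(q, i) for i, (role, q) in enumerate(quotas.items())]
    )
    rng.shuffle(roles)
    role_list = list(quotas.keys())

    gts = list(design.genotype_freqs.keys())
    gt_probs = np.array([design.genotype_freqs[g] for g in gts])
    gt_draw = rng.choice(len(gts), size=n, p=gt_probs)
    # fragility is a persistent per-site property, so it is drawn with the
    # truth (design seed) even though its fraction lives in the damage model
    fragile = rng.random(n) < model.fragile_fraction

    truth: list[TruthSite] = []
    positions = np.arange(1, n + 1) * 100  # distinct, sorted, 1-based
    for i in range(n):
        role = role_list[int(roles[i])]
        if role is SiteRole.NULL:
            if rng.random() < design.spandel_fraction:
                ref = CANONICAL_BASES[int(rng.integers(4))]
                alt = "*"
            else:
                ref = CANONICAL_BASES[int(rng.integers(4))]
                alts = [b for b in CANONICAL_BASES if b != ref]
                alt = alts[int(rng.integers(3))]
            gt = gts[int(gt_draw[i])]
        elif role is SiteRole.DAMAGE_PRONE:
            ref, alt = _DEAM_PAIRS[int(rng.integers(2))]
            gt = gts[int(gt_draw[i])]
        else:  # planted marker or switch
            ref, alt = _DEAM_PAIRS[int(rng.integers(2))]
            gt = GenotypeCall.HOM_REF
        truth.append(
            TruthSite(
                site=SiteKey("chr1", int(positions[i]), ref, alt),
                true_genotype=gt,
                role=role,
                fragile=bool(fragile[i]),
            )
        )
    return truth


def _site_deam_rates(truth: Sequence[TruthSite], model: DamageModel) -> np.ndarray:
    rates = np.zeros(len(truth))
    for i, ts in enumerate(truth):
        if ts.site.is_spanning_deletion:
            rates[i] = model.spandel_rate
        elif ts.role is SiteRole.DAMAGE_PRONE:
            rates[i] = model.deam_rate
        elif ts.role is SiteRole.PLANTED_MARKER:
            rates[i] = model.marker_deam_rate
        elif ts.role is SiteRole.PLANTED_SWITCH:
            rates[i] = model.switch_deam_rate
    return rates


def simulate_counts(
    truth: Sequence[TruthSite],
    design: SimDesign = DEFAULT_DESIGN,
    model: DamageModel = DEFAULT_MODEL,
) -> StudyTable:
    """Draw read counts for every (site, series, time point).

    Depth is Poisson with mean ``mean_coverage * exp(-decay * m * t)`` (fast
    decay at fragile sites); given depth, reads are multinomial with per-read
    alt probability ``f (1-e) + (1-f) e/3`` where ``f = g + (1-g) d(t)`` is
    the template alt fraction after conversion ``d(t) = 1 - exp(-rate*m*t)``
    and ``e`` the sequencing-error rate.  ``m`` is the humid multiplier for
    humid series, 1 otherwise.  Depth 0 encodes a failed call.

    Substreams are derived per (series, time point) from the design seed, so
    adding series or time points leaves other draws unchanged.
    """
    n = len(truth)
    samples = design.sample_meta()
    counts = np.zeros((n, len(samples), 3), dtype=np.int64)

    g = np.array([_GT_FRACTION[ts.true_genotype] for ts in truth])
    deam = _site_deam_rates(truth, model)
    decay = np.where(
        [ts.fragile for ts in truth], model.fragile_decay_rate, model.cov_decay_rate
    )
    e = model.seq_error_rate

    col = 0
    for s_idx, (matrix, condition) in enumerate(design.series):
        m = model.humid_multiplier if condition == "humid" else 1.0
        pre = model.saliva_prestorage_days if matrix == "saliva" else 0.0
        for t_idx, t in enumerate(design.time_points):
            rng = _rng(design.seed, 1, s_idx, t_idx)
            te = t + pre
            d = 1.0 - np.exp(-deam * m * te)
            f = g + (1.0 - g) * d
            p_alt = f * (1 - e) + (1 - f) * e / 3
            p_other = np.full(n, 2 * e / 3)

            mu = design.mean_coverage * np.exp(-decay * m * t)
            depth = rng.poisson(mu)
            alt = rng.binomial(depth, p_alt)
            rest = depth - alt
            other = rng.binomial(rest, np.minimum(p_other / np.maximum(1 - p_alt, 1e-12), 1.0))
            counts[:, col, 0] = rest - other
            counts[:, col, 1] = alt
            counts[:, col, 2] = other
            col += 1

    return StudyTable([ts.site for ts in truth], samples, counts)


def estimate_deam_rate(
    prv: np.ndarray, time_days: Sequence[int], humid_multiplier: float = 1.0
) -> float:
    """Recover the deamination rate from PRV trajectories of 0/0 sites.

    Inverts the conversion curve at each stored time point t > 0:
    ``lambda_hat = -ln(1 - mean_PRV(t)/100) / (m * t)``, then averages the
    per-time-point estimates.  ``prv`` is (n_sites, n_times) with columns
    matching ``time_days``; rows with NaN (coverage loss) are ignored per
    column.
    """
    prv = np.atleast_2d(np.asarray(prv, dtype=float))
    estimates = []
    for j, t in enumerate(time_days):
        if t == 0:
            continue
        col = prv[:, j]
        mean_prv = np.nanmean(col)
        if not np.isfinite(mean_prv):
            continue
        if mean_prv >= 100.0:
            raise ValueError("mean PRV >= 100%: conversion curve saturated")
        estimates.append(-math.log(1.0 - mean_prv / 100.0) / (humid_multiplier * t))
    if not estimates:
        raise ValueError("no stored time points with defined PRV")
    return float(np.mean(estimates))


# ---------------------------------------------------------------------------
# VCF + truth sidecar output


def write_simulated_vcf(
    table: StudyTable,
    truth: Sequence[TruthSite],
    vcf_path: str | Path,
    truth_path: str | Path | None = None,
) -> None:
    """Write the simulated study as a multi-sample VCF with AD/DP fields.

    ``io.read_vcf`` on the output reproduces the StudyTable exactly.  A
    sidecar TSV with per-site ground truth (role, genotype, fragility) is
    written alongside when ``truth_path`` is given.
    """
    truth_by_site = {ts.site: ts for ts in truth}
    sample_ids = [s.sample_id for s in table.samples]
    chroms = []
    for site in table.sites:
        if site.chrom not in chroms:
            chroms.append(site.chrom)

    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids),
    ]
    for i, site in enumerate(table.sites):
        fields = [site.chrom, str(site.pos), ".", site.ref, site.alt, ".", "PASS", "."]
        fields.append("GT:AD:DP")
        for j in range(table.n_samples):
            ref, alt, other = (int(v) for v in table.counts[i, j])
            total = ref + alt + other
            if total == 0:
                gt = "./."
            elif alt / total < 0.05:
                gt = "0/0"
            elif alt / total > 0.95:
                gt = "1/1"
            else:
                gt = "0/1"
            fields.append(f"{gt}:{ref},{alt}:{total}")
        lines.append("\t".join(fields))
    Path(vcf_path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    if truth_path is not None:
        rows = ["chrom\tpos\tref\talt\ttrue_genotype\trole\tfragile"]
        for site in table.sites:
            ts = truth_by_site[site]
            rows.append(
                "\t".join(
                    [
                        site.chrom,
                        str(site.pos),
                        site.ref,
                        site.alt,
                        str(ts.true_genotype),
                        ts.role.value,
                        str(int(ts.fragile)),
                    ]
                )
            )
        Path(truth_path).write_text("\n".join(rows) + "\n", encoding="utf-8")
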