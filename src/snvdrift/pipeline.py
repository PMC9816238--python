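"""End-to-end orchestration and deterministic report generation.

The pipeline mirrors the stepwise analysis: genotype allocation first, then
temporal characterization (genotype distributions, failed calls, homozygote
switches, base-change spectra), then restriction to the deamination
signature with the read-count threshold, and finally gradual-PRV candidate
selection with cross-series concordance.  Every number in the report bundle
is a cell of one of the emitted tables; nothing is computed at print time.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import SiteKey, StudyTable
from .genotyping import CallingConfig, GenotypeCall, GENOTYPE_LABELS, call_study
from .marker_selection import (
    CandidateMarker,
    FilterConfig,
    apply_filters,
    changed_sites,
    homozygote_switches,
    select_candidates,
)
from .stats import anova_oneway, chi_square_counts, mann_whitney_u
from .trajectories import (
    MonotoneConfig,
    SeriesTrajectories,
    classify_call_matrix,
    count_failed_calls,
    extract_series,
    genotype_transition_counts,
    gradual_mask,
    spectrum_counts,
)

logger = logging.getLogger(__name__)


def _series_label(series: tuple[str, str]) -> str:
    return f"{series[0]}_{series[1]}"


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run."""

    calling: CallingConfig = field(default_factory=CallingConfig)
    monotone: MonotoneConfig = field(default_factory=MonotoneConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    required_series: list[tuple[str, str]] | None = None
    prv_change_tolerance: float = 5.0
    seed: int = 0

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["filters"]["allowed_changes"] = sorted(
            ">".join(p) for p in self.filters.allowed_changes
        )
        if self.required_series is not None:
            d["required_series"] = ["/".join(s) for s in self.required_series]
        return d


@dataclass
class ReportBundle:
    """All tables produced by one run, plus the candidate objects."""

    tables: dict[str, pd.DataFrame]
    candidates: list[CandidateMarker]
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        """Write every table as TSV plus the JSON manifest (deterministic)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            with open(outdir / f"{name}.tsv", "w", encoding="utf-8", newline="\n") as fh:
                df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
        with open(outdir / "run_manifest.json", "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(table: StudyTable, cfg: PipelineConfig | None = None) -> ReportBundle:
    """Run the full analysis on a StudyTable and return the report bundle.

    Stages run in order; a failure in any stage aborts the run before
    anything is written (the bundle is assembled in memory first).
    """
    cfg = cfg or PipelineConfig()
    tables: dict[str, pd.DataFrame] = {}

    # stage 1: genotype allocation
    calls = call_study(table, cfg.calling)
    series_trajs = extract_series(calls)
    required = cfg.required_series or list(series_trajs)

    # stage 2a: genotype distributions and failed calls per (series, time)
    dist_rows, failed_rows = [], []
    for key, st in series_trajs.items():
        for j, t in enumerate(st.time_days):
            col = st.calls[:, j]
            counts = [int((col == g).sum()) for g in range(4)]
            dist_rows.append([_series_label(key), t, *counts])
            failed_rows.append([_series_label(key), t, count_failed_calls(col)])
    tables["genotype_distribution"] = pd.DataFrame(
        dist_rows, columns=["series", "time_days", *GENOTYPE_LABELS]
    )
    tables["failed_calls"] = pd.DataFrame(
        failed_rows, columns=["series", "time_days", "n_failed"]
    )

    # stage 2b: genotype transition matrices (day 0 vs each stored time)
    trans_rows = []
    for key, st in series_trajs.items():
        for j, t in enumerate(st.time_days):
            if t == 0:
                continue
            m = genotype_transition_counts(st.calls[:, 0], st.calls[:, j])
            for a in range(4):
                for b in range(4):
                    trans_rows.append(
                        [_series_label(key), t, GENOTYPE_LABELS[a], GENOTYPE_LABELS[b], int(m[a, b])]
                    )
    tables["genotype_transitions"] = pd.DataFrame(
        trans_rows, columns=["series", "time_days", "day0_call", "later_call", "count"]
    )

    # stage 2c: trajectory classes and homozygote switches
    class_rows = []
    day0_failed_counts = {}
    for key, st in series_trajs.items():
        labels, day0_failed = classify_call_matrix(st.calls)
        day0_failed_counts[_series_label(key)] = int(day0_failed.sum())
        for i, lab in enumerate(labels):
            if lab is None:
                continue
            site = st.sites[i]
            prvs = [
                "" if not np.isfinite(p) else f"{p:.4f}" for p in st.prv[i]
            ]
            class_rows.append(
                [site.chrom, site.pos, site.ref, site.alt, _series_label(key), lab.value, *prvs]
            )
    n_times = len(next(iter(series_trajs.values())).time_days)
    tables["trajectory_classes"] = pd.DataFrame(
        class_rows,
        columns=["chrom", "pos", "ref", "alt", "series", "label"]
        + [f"prv_t{j}" for j in range(n_times)],
    )

    switches, switch_intersection = homozygote_switches(series_trajs)
    sw_rows = [
        [_series_label(key), s.chrom, s.pos, s.ref, s.alt, direction]
        for key, entries in switches.items()
        for s, direction in entries
    ]
    tables["homozygote_switches"] = pd.DataFrame(
        sw_rows, columns=["series", "chrom", "pos", "ref", "alt", "direction"]
    )
    tables["homozygote_switch_intersection"] = pd.DataFrame(
        sorted([s.chrom, s.pos, s.ref, s.alt] for s in switch_intersection),
        columns=["chrom", "pos", "ref", "alt"],
    )

    # stage 2d: base-change spectrum of changed sites, per series
    changed, failed_onset = changed_sites(series_trajs, cfg.prv_change_tolerance)
    spec_rows = []
    for key, st in series_trajs.items():
        day0_ok = st.calls[:, 0] != int(GenotypeCall.FAILED)
        later_ok = (st.calls[:, 1:] != int(GenotypeCall.FAILED)).all(axis=1)
        call_changed = day0_ok & later_ok & (st.calls[:, 1:] != st.calls[:, [0]]).any(axis=1)
        sites = [st.sites[i] for i in np.nonzero(call_changed)[0]]
        pair_counts, class_counts = spectrum_counts(sites)
        for (r, a), c in pair_counts.items():
            spec_rows.append([_series_label(key), f"{r}>{a}", c])
        for cls, c in class_counts.items():
            spec_rows.append([_series_label(key), cls.value, c])
    tables["spectrum"] = pd.DataFrame(spec_rows, columns=["series", "category", "count"])

    # stage 3: deamination-signature + depth + day-0 homozygosity filters
    surviving, attrition = apply_filters(series_trajs, cfg.filters, changed)
    tables["filter_attrition"] = pd.DataFrame(
        [attrition.as_dict()]
    )

    # stage 4: gradual-PRV candidate markers, concordant across series
    candidates = select_candidates(surviving, series_trajs, cfg.monotone, required)
    cand_rows = []
    for cand in candidates:
        row = [
            cand.site.chrom,
            cand.site.pos,
            cand.site.ref,
            cand.site.alt,
            cand.direction,
            GENOTYPE_LABELS[int(cand.day0_genotype)],
        ]
        for key in required:
            row.extend(f"{p:.4f}" for p in cand.per_series_prv[key])
        cand_rows.append(row)
    prv_cols = [
        f"prv_{_series_label(key)}_t{j}" for key in required for j in range(n_times)
    ]
    tables["candidate_markers"] = pd.DataFrame(
        cand_rows,
        columns=["chrom", "pos", "ref", "alt", "direction", "day0_genotype", *prv_cols],
    )

    # stage 5: statistics
    tables["stats_summary"] = _stats_summary(series_trajs, surviving, cfg)

    manifest = {
        "package": "snvdrift",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_jsonable(),
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.to_jsonable(), sort_keys=True).encode()
        ).hexdigest(),
        "n_sites": table.n_sites,
        "n_samples": table.n_samples,
        "n_changed_sites": len(changed),
        "n_failed_onset_only_sites": len(failed_onset),
        "day0_failed_sites": day0_failed_counts,
        "n_candidates": len(candidates),
    }
    return ReportBundle(tables=tables, candidates=candidates, manifest=manifest)


def _stats_summary(
    series_trajs: dict[tuple[str, str], SeriesTrajectories],
    surviving: list[SiteKey],
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """Statistical comparisons over the filtered gradual-PRV positions.

    PRVs are pooled across positions per series (per-position testing is
    underpowered at three time points): one-way ANOVA of PRV across time
    points, Mann-Whitney U between the two stored time points, and a
    chi-square test of spanning-deletion vs substitution changed-site counts
    between matrices (when both matrices are present).
    """
    rows = []
    for key, st in series_trajs.items():
        index = {s: i for i, s in enumerate(st.sites)}
        idx = np.array([index[s] for s in surviving], dtype=np.int64)
        if idx.size:
            ok, _ = gradual_mask(st.prv[idx], cfg.monotone)
            sel = idx[ok]
        else:
            sel = idx
        if sel.size >= 2:
            groups = {
                f"day{t}": st.prv[sel, j][np.isfinite(st.prv[sel, j])]
                for j, t in enumerate(st.time_days)
            }
            groups = {k: v for k, v in groups.items() if v.size}
            if len(groups) >= 2 and sum(v.size for v in groups.values()) > len(groups):
                res = anova_oneway(groups)
                rows.append(
                    [
                        f"PRV ~ time, gradual sites, {_series_label(key)}",
                        res.test,
                        res.statistic,
                        res.pvalue,
                        "unadjusted",
                        "|".join(str(x) for x in res.n),
                    ]
                )
            stored = [j for j, t in enumerate(st.time_days) if t > 0]
            if len(stored) >= 2:
                x = st.prv[sel, stored[-2]]
                y = st.prv[sel, stored[-1]]
                x, y = x[np.isfinite(x)], y[np.isfinite(y)]
                if x.size and y.size:
                    res = mann_whitney_u(x, y)
                    rows.append(
                        [
                            f"PRV day{st.time_days[stored[-2]]} vs day{st.time_days[stored[-1]]}, "
                            f"{_series_label(key)}",
                            res.test,
                            res.statistic,
                            res.pvalue,
                            "unadjusted",
                            "|".join(str(x_) for x_ in res.n),
                        ]
                    )

    # spanning deletions vs substitutions between matrices, pooled conditions
    matrices = sorted({key[0] for key in series_trajs})
    if len(matrices) == 2:
        counts = np.zeros((2, 2))
        for key, st in series_trajs.items():
            row = matrices.index(key[0])
            day0_ok = st.calls[:, 0] != int(GenotypeCall.FAILED)
            later_ok = (st.calls[:, 1:] != int(GenotypeCall.FAILED)).all(axis=1)
            chg = day0_ok & later_ok & (st.calls[:, 1:] != st.calls[:, [0]]).any(axis=1)
            for i in np.nonzero(chg)[0]:
                counts[row, 0 if st.sites[i].is_spanning_deletion else 1] += 1
        if (counts.sum(axis=1) > 0).all() and (counts.sum(axis=0) > 0).all():
            res = chi_square_counts(counts)
            rows.append(
                [
                    f"spanning-deletion share of changed sites, {matrices[0]} vs {matrices[1]}",
                    res.test,
                    res.statistic,
                    res.pvalue,
                    "unadjusted",
                    "|".join(str(int(c)) for c in counts.ravel()),
                ]
            )
    return pd.DataFrame(
        rows, columns=["comparison", "test", "statistic", "p", "p_note", "group_sizes"]
    )
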