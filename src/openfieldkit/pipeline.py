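"""End-to-end orchestration: tracks -> measures -> summaries -> fits -> stats.

The group coverage asymptote (for PGCA) is only computed after every track
has been standardized and measured, since it averages the individual
asymptotes of the whole group.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import (AnalysisConfig, CoverageAsymptoteSpec, DefaultsConfig,
                     ModelSpec, set_up_fits, validate_config, ConfigError)
from .fit_models import CohortFits, fit_cohort, format_group_params, format_params
from .measures import (CoverageState, activity, classify_transitions,
                       coverage_series, edge_mask,
                       individual_coverage_asymptote,
                       individual_probability_series, locate_sector_visits,
                       motion_probabilities, pgca, pica)
from .stats import StatReport, run_tests
from .summarize import (GroupSummary, export_summaries, summarize_by_coverage,
                        summarize_temporal)
from .track_io import TrackParseError, read_track_files, standardize

log = logging.getLogger("openfieldkit")

__all__ = [
    "TrackMeasures",
    "GroupMeasures",
    "AnalysisResult",
    "compute_track_measures",
    "analyze_tracks",
    "build_xy_dataset",
    "summarize_all",
    "run_pipeline",
]


@dataclass
class TrackMeasures:
    track: object
    act: object
    cov: CoverageState
    trans: object

    @property
    def uid(self) -> str:
        return self.track.uid

    @property
    def group(self) -> str:
        return self.track.group


@dataclass
class GroupMeasures:
    group: str
    members: list[TrackMeasures]
    A_grp: float | None = None
    prob_series: dict = field(default_factory=dict)


@dataclass
class AnalysisResult:
    groups: dict[str, GroupMeasures]
    config: AnalysisConfig
    defaults: DefaultsConfig

    def all_members(self) -> list[TrackMeasures]:
        return [m for g in self.groups.values() for m in g.members]


def compute_track_measures(track, config: AnalysisConfig,
                           defaults: DefaultsConfig,
                           asymptote_spec: CoverageAsymptoteSpec | None = None,
                           fit_asymptote: bool = True) -> TrackMeasures:
    """All per-track measures; PGCA is filled in later at the group stage."""
    M = int(round(360.0 / defaults.node_size))
    act = activity(track, config.inactivity_threshold)
    inband = edge_mask(track, config.edge_dist_cm)
    events, counts = locate_sector_visits(track, defaults.node_size,
                                          config.edge_dist_cm)
    eval_times = np.arange(0.0, track.t[-1] + 1e-9,
                           defaults.coverage_sample_period)
    C = coverage_series(events, M, track.t, eval_times)
    C_samples = coverage_series(events, M, track.t, track.t)
    cmax = C_samples[-1] if C_samples.size else 0.0
    percent = C / cmax if cmax > 0 else np.zeros_like(C)
    A_ind = None
    if fit_asymptote:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            A_ind = individual_coverage_asymptote(eval_times, C, asymptote_spec)
    cov = CoverageState(M=M, events=events, final_counts=counts,
                        sample_times=eval_times, C=C, C_at_samples=C_samples,
                        percent=percent, A_ind=A_ind,
                        pica=pica(C_samples, A_ind))
    trans = classify_transitions(track, act, in_edge=inband)
    return TrackMeasures(track=track, act=act, cov=cov, trans=trans)


def analyze_tracks(tracks, config: AnalysisConfig, defaults: DefaultsConfig,
                   asymptote_spec: CoverageAsymptoteSpec | None = None) -> AnalysisResult:
    by_group: dict[str, list] = {}
    for tr in tracks:
        by_group.setdefault(tr.group, []).append(tr)
    need_asym = defaults.enable_pica or defaults.enable_pgca
    groups = {}
    for g, trs in by_group.items():
        members = [compute_track_measures(tr, config, defaults, asymptote_spec,
                                          fit_asymptote=need_asym)
                   for tr in trs]
        gm = GroupMeasures(group=g, members=members)
        asyms = [m.cov.A_ind for m in members if m.cov.A_ind is not None]
        gm.A_grp = float(np.mean(asyms)) if asyms else None
        for m in members:
            m.cov.pgca = pgca(m.cov.C_at_samples, gm.A_grp)
        if defaults.enable_motion_probabilities and members:
            for variant in defaults.variants:
                gm.prob_series[variant] = motion_probabilities(
                    [m.trans for m in members], variant)
        groups[g] = gm
    return AnalysisResult(groups=groups, config=config, defaults=defaults)


def _x_at_samples(m: TrackMeasures, x_var: str) -> np.ndarray | None:
    """The x-axis value carried at every track sample."""
    if x_var == "time":
        return m.track.t
    C = m.cov.C_at_samples
    if x_var == "coverage":
        return C
    if x_var == "percent_coverage":
        cmax = C[-1] if C.size else 0.0
        return C / cmax if cmax > 0 else np.zeros_like(C)
    if x_var == "pica":
        return None if m.cov.A_ind is None else C / m.cov.A_ind
    if x_var == "pgca":
        return m.cov.pgca
    raise ValueError(f"unknown x variable {x_var!r}")


def _parse_prob_y(y_var: str):
    # "prob_pp_given_previous" -> ("pp", "given_previous")
    rest = y_var[len("prob_"):]
    token, variant = rest.split("_", 1)
    outcome = {"pp": "pp", "pm": "pm", "p0": "p0", "0p": "0p", "00": "00"}[token]
    return outcome, variant


def build_xy_dataset(result: AnalysisResult,
                     specs: dict[tuple[str, str], ModelSpec]):
    """Per-individual (x, y) arrays for every spec'd relationship.

    Activity lives at the n-1 step-start samples, decisions at the n-2
    interior samples; coverage-family x values are carried at the same
    samples so tuples pair the measure with the learning achieved then.
    """
    xy: dict[tuple, dict] = {}
    for key in specs:
        x_var, y_var = key
        per_ind = {}
        for m in [mm for g in result.groups.values() for mm in g.members]:
            if y_var == "coverage":
                if x_var != "time":
                    continue
                per_ind[m.uid] = (m.cov.sample_times, m.cov.C)
                continue
            xs = _x_at_samples(m, x_var)
            if xs is None:
                continue
            if y_var == "activity":
                per_ind[m.uid] = (xs[:-1], m.act.thresholded)
            else:
                outcome, variant = _parse_prob_y(y_var)
                y = individual_probability_series(m.trans, outcome, variant)
                per_ind[m.uid] = (xs[1:-1], y)
        xy[key] = per_ind
    return xy


def summarize_all(result: AnalysisResult, xy: dict) -> list[GroupSummary]:
    """Group mean/SEM for every relationship: temporal or pooled-and-binned."""
    summaries = []
    d = result.defaults
    uid_group = {m.uid: g for g, gm in result.groups.items() for m in gm.members}
    for (x_var, y_var), per_ind in xy.items():
        by_group: dict[str, list] = {}
        for uid, pair in per_ind.items():
            by_group.setdefault(uid_group[uid], []).append(pair)
        for g, pairs in by_group.items():
            if x_var == "time":
                tref = max((p[0] for p in pairs), key=len)
                summaries.append(summarize_temporal(
                    tref, [p[1] for p in pairs], g, y_var))
                s = summaries[-1]
                s.x_name = "time"
            else:
                summaries.append(summarize_by_coverage(
                    pairs, g, x_var, y_var, n_points=d.n_points,
                    n_bins=d.n_bins))
    return summaries


def _group_xy_from_summaries(summaries: list[GroupSummary]):
    out: dict[tuple, dict] = {}
    for s in summaries:
        out.setdefault((s.x_name, s.y_name), {})[s.group] = (s.centers, s.mean)
    return out


def export_individual_measures(result: AnalysisResult, outdir) -> list[Path]:
    """Per-group long CSV: one row per individual per sample, all measures."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for g, gm in result.groups.items():
        frames = []
        for m in gm.members:
            n = m.track.n_samples
            df = pd.DataFrame({
                "id": m.uid,
                "t_s": m.track.t,
                "x_cm": m.track.x,
                "y_cm": m.track.y,
                "activity": np.append(m.act.thresholded, np.nan),
                "coverage": m.cov.C_at_samples,
                "percent_coverage": (m.cov.C_at_samples / m.cov.C_at_samples[-1]
                                     if m.cov.C_at_samples[-1] > 0
                                     else np.zeros(n)),
                "pica": (m.cov.C_at_samples / m.cov.A_ind
                         if m.cov.A_ind else np.nan),
                "pgca": (m.cov.pgca if m.cov.pgca is not None else np.nan),
                "decision": np.concatenate([[np.nan], m.trans.codes, [np.nan]]),
            })
            frames.append(df)
        p = outdir / f"{g}__individual_measures.csv"
        pd.concat(frames, ignore_index=True).to_csv(p, index=False)
        paths.append(p)
    return paths


def read_input_tracks(config: AnalysisConfig, inputs: dict[str, list],
                      skip_bad: bool = True):
    """Read and standardize tracks; ``inputs`` maps group -> list of paths.

    Per-track failures are logged and skipped (the rest of the cohort is
    still analyzed) unless ``skip_bad`` is False.
    """
    tracks = []
    skipped = []
    for group, paths in inputs.items():
        dialect = config.groups_and_types.get(group)
        if dialect is None:
            raise ConfigError([f"group {group!r} not in groups_and_types"])
        for p in paths:
            try:
                raws = read_track_files([p], dialect, group, config)
                tracks.extend(standardize(r, config) for r in raws)
            except (TrackParseError, ValueError) as exc:
                if not skip_bad:
                    raise
                log.warning("skipping %s: %s", p, exc)
                skipped.append((str(p), str(exc)))
    return tracks, skipped


def run_pipeline(config: AnalysisConfig, defaults: DefaultsConfig,
                 inputs: dict[str, list] | None, outdir,
                 tracks=None, group_colors: dict[str, str] | None = None,
                 stages: set[str] | None = None, seed: int = 0,
                 alpha: float = 0.05) -> dict:
    """Run the full analysis and write every artifact under ``outdir``.

    ``stages`` limits the work (any of {"measures", "fit", "stats", "plot"});
    measures always run.  Returns a manifest dict (also saved as JSON).
    """
    errs = validate_config(config, defaults)
    if errs:
        raise ConfigError(errs)
    stages = stages or {"measures", "fit", "stats", "plot"}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    skipped = []
    if tracks is None:
        if not inputs:
            raise ValueError("no input tracks given")
        tracks, skipped = read_input_tracks(config, inputs)
    if not tracks:
        raise TrackParseError("no readable tracks")
    log.info("analyzing %d tracks", len(tracks))
    result = analyze_tracks(tracks, config, defaults)
    specs = set_up_fits(config, defaults)
    xy = build_xy_dataset(result, specs)
    summaries = summarize_all(result, xy)
    export_individual_measures(result, outdir / "measures")
    export_summaries(summaries, outdir / "summaries")
    manifest = {
        "version": __version__,
        "seed": seed,
        "n_tracks": len(tracks),
        "groups": {g: len(gm.members) for g, gm in result.groups.items()},
        "skipped": skipped,
        "config": {k: (v if not isinstance(v, dict) else dict(v))
                   for k, v in vars(config).items()},
        "defaults": {k: list(v) if isinstance(v, tuple) else v
                     for k, v in vars(defaults).items()},
        "relationships": [list(k) for k in specs],
    }
    fits = None
    if "fit" in stages or "stats" in stages or "plot" in stages:
        uid_group = {m.uid: m.group for m in result.all_members()}
        fits = fit_cohort(xy, specs, uid_group,
                          bound_level=config.bound_level,
                          group_xy=_group_xy_from_summaries(summaries))
        format_params(fits, outdir / "individual_params.csv")
        format_group_params(fits, outdir / "group_params.csv")
    report = None
    if "stats" in stages and fits is not None:
        param_df = format_params(fits)
        report = run_tests(param_df, alpha=alpha,
                           report_path=outdir / "stat_report.txt",
                           csv_dir=outdir / "stat_tables")
        manifest["n_significant"] = int(sum(report.significant.values()))
    if "plot" in stages and fits is not None:
        from .plotting import (PlotSettings, plot_group_comparison,
                               plot_solo_group, plot_traces)
        colors = dict(group_colors or {})
        palette = ["C0", "C1", "C2", "C3", "C4", "C5"]
        for i, g in enumerate(result.groups):
            colors.setdefault(g, palette[i % len(palette)])
        settings = PlotSettings(group_colors=colors,
                                outdir=str(outdir / "plots"))
        if "traces" in defaults.plot_categories:
            plot_traces(tracks, settings)
        gfits = {(f.x_var, f.y_var, f.group): f for f in fits.group}
        by_key: dict[tuple, list] = {}
        for s in summaries:
            by_key.setdefault((s.x_name, s.y_name), []).append(s)
        for key, ss in by_key.items():
            if "solo_group" in defaults.plot_categories:
                for s in ss:
                    plot_solo_group(s, gfits.get((key[0], key[1], s.group)),
                                    settings)
            if "group_comparison" in defaults.plot_categories:
                plot_group_comparison(
                    ss, {s.group: gfits.get((key[0], key[1], s.group))
                         for s in ss}, settings)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
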