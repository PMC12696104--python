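"""Figure generation: traces, individual fits, group summaries, comparisons.

All functions are pure consumers of measures/summaries/fits (nothing is
mutated) and write deterministic file names
``plots/<category>/<group>__<x>__<y>.<ext>``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .fit_models import get_form

__all__ = [
    "PlotSettings",
    "plot_traces",
    "plot_individuals",
    "plot_solo_group",
    "plot_group_components",
    "plot_group_comparison",
    "render_equation",
]


@dataclass
class PlotSettings:
    group_colors: dict[str, str]
    marker_size: float = 8.0
    show_model_curve: bool = True
    show_equation: bool = True
    show_sem: bool = True
    show_individual_fits: bool = False
    save: bool = True
    show: bool = False
    outdir: str = "plots"
    fmt: str = "png"
    dpi: int = 300
    extra_colors: dict = field(default_factory=dict)

    def color(self, group: str) -> str:
        if group not in self.group_colors:
            raise KeyError(f"no color assigned to group {group!r}")
        return self.group_colors[group]


def _sanitize(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]+", "-", str(name))


def _outpath(settings: PlotSettings, category: str, *parts: str) -> Path:
    d = Path(settings.outdir) / category
    d.mkdir(parents=True, exist_ok=True)
    return d / ("__".join(_sanitize(p) for p in parts) + f".{settings.fmt}")


def _finish(fig, settings: PlotSettings, path: Path) -> Path | None:
    if settings.save:
        fig.savefig(path, dpi=settings.dpi)
    if settings.show:  # pragma: no cover - interactive only
        plt.show()
    plt.close(fig)
    return path if settings.save else None


def render_equation(display_parts, params, sig=3) -> str:
    """Interleave display fragments with fitted parameters at 3 significant digits."""
    out = []
    for i, part in enumerate(display_parts):
        out.append(part)
        if i < len(params):
            out.append(f"{params[i]:.{sig}g}")
    return "".join(out)


def plot_traces(tracks, settings: PlotSettings) -> list[Path]:
    """One panel per track: trajectory polyline plus the arena boundary circle."""
    paths = []
    for tr in tracks:
        fig, ax = plt.subplots(figsize=(4, 4))
        ang = np.linspace(0, 2 * np.pi, 256)
        R = tr.arena_radius_cm
        ax.plot(R * np.cos(ang), R * np.sin(ang), color="0.4", lw=1)
        color = settings.group_colors.get(tr.group, "C0")
        ax.plot(tr.x, tr.y, color=color, lw=0.6)
        ax.set_aspect("equal")
        ax.set_title(f"{tr.group} / {tr.uid}")
        ax.set_xlabel("x (cm)")
        ax.set_ylabel("y (cm)")
        p = _finish(fig, settings, _outpath(settings, "traces", tr.group,
                                            tr.uid or tr.arena))
        if p:
            paths.append(p)
    return paths


def _fit_curve(ax, x, fit_params, form_name, color, settings, label=None):
    form = get_form(form_name)
    xs = np.linspace(np.nanmin(x), np.nanmax(x), 200)
    ax.plot(xs, form(xs, fit_params), color=color, lw=1.5, label=label)
    if settings.show_equation:
        eq = render_equation(form.display_parts, fit_params)
        ax.text(0.02, 0.98, eq, transform=ax.transAxes, va="top", fontsize=7)


def plot_individuals(xy_by_uid: dict, x_name: str, y_name: str,
                     fits_by_uid: dict, groups: dict[str, str],
                     settings: PlotSettings) -> list[Path]:
    """Scatter of one measure pair per individual, optional fitted curve."""
    import warnings as _w
    paths = []
    for uid, (x, y) in xy_by_uid.items():
        fig, ax = plt.subplots(figsize=(4, 3))
        color = settings.group_colors.get(groups.get(uid, ""), "C0")
        ax.scatter(x, y, s=settings.marker_size, color=color, alpha=0.6)
        fit = fits_by_uid.get(uid)
        if settings.show_model_curve:
            if fit is not None and fit.refit is not None:
                _fit_curve(ax, x, fit.refit, fit.form, "k", settings)
            else:
                _w.warn(f"no converged fit for {uid}; curve omitted")
        ax.set_xlabel(x_name)
        ax.set_ylabel(y_name)
        ax.set_title(uid)
        fig.tight_layout()
        p = _finish(fig, settings,
                    _outpath(settings, "individuals", uid, x_name, y_name))
        if p:
            paths.append(p)
    return paths


def _plot_summary(ax, summary, color, settings, label=None):
    ax.scatter(summary.centers, summary.mean, s=settings.marker_size,
               color=color, label=label)
    if settings.show_sem:
        sem = np.where(np.isfinite(summary.sem), summary.sem, 0.0)
        ax.errorbar(summary.centers, summary.mean, yerr=sem, fmt="none",
                    ecolor=color, alpha=0.5, lw=1)


def plot_solo_group(summary, group_fit, settings: PlotSettings) -> Path | None:
    """Binned group means +/- SEM with the group-level fitted curve."""
    fig, ax = plt.subplots(figsize=(4, 3))
    color = settings.color(summary.group)
    _plot_summary(ax, summary, color, settings)
    if settings.show_model_curve and group_fit is not None \
            and group_fit.refit is not None:
        _fit_curve(ax, summary.centers, group_fit.refit, group_fit.form,
                   "k", settings)
    ax.set_xlabel(summary.x_name)
    ax.set_ylabel(summary.y_name)
    ax.set_title(summary.group)
    fig.tight_layout()
    return _finish(fig, settings, _outpath(settings, "solo_group",
                                           summary.group, summary.x_name,
                                           summary.y_name))


def plot_group_components(summary, raw_tuples, group_fit, individual_fits,
                          settings: PlotSettings) -> Path | None:
    """Solo-group layers plus every individual's raw tuples (and fits)."""
    fig, ax = plt.subplots(figsize=(4, 3))
    color = settings.color(summary.group)
    for x, y in raw_tuples:
        ax.scatter(x, y, s=settings.marker_size / 3, color=color, alpha=0.15)
    if settings.show_individual_fits:
        for fit in individual_fits:
            if fit.refit is not None:
                xall = np.concatenate([np.asarray(x) for x, _ in raw_tuples])
                form = get_form(fit.form)
                xs = np.linspace(np.nanmin(xall), np.nanmax(xall), 100)
                ax.plot(xs, form(xs, fit.refit), color="0.7", lw=0.5)
    _plot_summary(ax, summary, color, settings)
    if settings.show_model_curve and group_fit is not None \
            and group_fit.refit is not None:
        _fit_curve(ax, summary.centers, group_fit.refit, group_fit.form,
                   "k", settings)
    ax.set_xlabel(summary.x_name)
    ax.set_ylabel(summary.y_name)
    ax.set_title(f"{summary.group} (components)")
    fig.tight_layout()
    return _finish(fig, settings, _outpath(settings, "group_components",
                                           summary.group, summary.x_name,
                                           summary.y_name))


def plot_group_comparison(summaries: list, group_fits: dict,
                          settings: PlotSettings) -> Path | None:
    """All groups' binned means and fits on one axis, colored per group."""
    if not summaries:
        return None
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    for s in summaries:
        color = settings.color(s.group)
        _plot_summary(ax, s, color, settings, label=s.group)
        fit = group_fits.get(s.group)
        if settings.show_model_curve and fit is not None \
                and fit.refit is not None:
            form = get_form(fit.form)
            xs = np.linspace(np.nanmin(s.centers), np.nanmax(s.centers), 200)
            ax.plot(xs, form(xs, fit.refit), color=color, lw=1.5)
    s0 = summaries[0]
    ax.set_xlabel(s0.x_name)
    ax.set_ylabel(s0.y_name)
    ax.legend(fontsize=7)
    fig.tight_layout()
    return _finish(fig, settings, _outpath(settings, "group_comparison",
                                           "all", s0.x_name, s0.y_name))
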