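"""Group-level aggregation of individual measures.

Temporal relationships share a common time grid, so the group mean and SEM
are taken per time point.  Coverage-domain relationships instead pool the
raw (x, y) tuples from every individual — averaging the individuals'
series directly would describe "average activity and average coverage at a
time point" rather than "average activity at a coverage level" — and bin
the pooled tuples either by tuple count (``n_points``, equal-count bins;
used for coverage, PICA and PGCA) or by equal-width ranges (``n_bins``;
used for percent coverage, whose [0, 1] support makes fixed ranges natural).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GroupSummary",
    "summarize_temporal",
    "summarize_by_coverage",
    "default_binning_method",
    "export_summaries",
    "summary_filename",
]


@dataclass
class GroupSummary:
    group: str
    x_name: str
    y_name: str
    centers: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.centers, "mean": self.mean,
                             "sem": self.sem, "n": self.n})


def _mean_sem(values: np.ndarray):
    """Column statistics ignoring NaN; SEM is missing when n < 2."""
    n = np.sum(np.isfinite(values), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(np.isfinite(values), values, np.nan), axis=0)
        sd = np.nanstd(np.where(np.isfinite(values), values, np.nan),
                       axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return mean, sem, n


def summarize_temporal(t, series: list[np.ndarray], group: str,
                       y_name: str) -> GroupSummary:
    """Mean and SEM over individuals at each shared time point."""
    T = min(len(s) for s in series)
    t = np.asarray(t, dtype=float)[:T]
    mat = np.vstack([np.asarray(s, dtype=float)[:T] for s in series])
    mean, sem, n = _mean_sem(mat)
    keep = n > 0
    return GroupSummary(group=group, x_name="time", y_name=y_name,
                        centers=t[keep], mean=mean[keep], sem=sem[keep],
                        n=n[keep], method="temporal")


def default_binning_method(x_name: str) -> str:
    return "n_bins" if x_name == "percent_coverage" else "n_points"


def summarize_by_coverage(xy_pairs: list[tuple[np.ndarray, np.ndarray]],
                          group: str, x_name: str, y_name: str,
                          method: str | None = None, n_points: int = 50,
                          n_bins: int = 50) -> GroupSummary:
    """Pool (x, y) tuples across individuals, sort by x, and bin.

    ``n_points``: consecutive runs of ``n_points`` tuples (the last bin may
    be smaller); bin center = mean x inside the bin.  ``n_bins``: equal-width
    bins spanning [min x, max x], empty bins omitted, centers at midpoints.
    Ties in x are broken by individual index then time, for determinism.
    """
    method = method or default_binning_method(x_name)
    xs, ys, inds, times = [], [], [], []
    for i, (x, y) in enumerate(xy_pairs):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        k = min(x.size, y.size)
        x, y = x[:k], y[:k]
        ok = np.isfinite(x) & np.isfinite(y)
        xs.append(x[ok])
        ys.append(y[ok])
        inds.append(np.full(ok.sum(), i))
        times.append(np.nonzero(ok)[0])
    x = np.concatenate(xs) if xs else np.array([])
    y = np.concatenate(ys) if ys else np.array([])
    ind = np.concatenate(inds) if inds else np.array([])
    tm = np.concatenate(times) if times else np.array([])
    if x.size == 0:
        return GroupSummary(group, x_name, y_name, np.array([]), np.array([]),
                            np.array([]), np.array([], dtype=int), method)
    order = np.lexsort((tm, ind, x))
    x, y = x[order], y[order]
    centers, means, sems, ns = [], [], [], []
    if method == "n_points":
        if x.size < n_points:
            warnings.warn(
                f"{group} {x_name} vs {y_name}: fewer tuples ({x.size}) than "
                f"one n_points bin ({n_points}); emitting a single bin")
        for start in range(0, x.size, n_points):
            xb = x[start:start + n_points]
            yb = y[start:start + n_points]
            centers.append(xb.mean())
            means.append(yb.mean())
            sems.append(yb.std(ddof=1) / np.sqrt(yb.size)
                        if yb.size > 1 else np.nan)
            ns.append(yb.size)
    elif method == "n_bins":
        edges = np.linspace(x.min(), x.max(), n_bins + 1)
        which = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
        for b in range(n_bins):
            sel = which == b
            if not sel.any():
                continue
            yb = y[sel]
            centers.append((edges[b] + edges[b + 1]) / 2.0)
            means.append(yb.mean())
            sems.append(yb.std(ddof=1) / np.sqrt(yb.size)
                        if yb.size > 1 else np.nan)
            ns.append(yb.size)
    else:
        raise ValueError(f"unknown binning method {method!r}")
    return GroupSummary(group=group, x_name=x_name, y_name=y_name,
                        centers=np.array(centers), mean=np.array(means),
                        sem=np.array(sems), n=np.array(ns, dtype=int),
                        method=method)


def _sanitize(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]+", "-", str(name))


def summary_filename(summary: GroupSummary) -> str:
    return (f"{_sanitize(summary.group)}__{_sanitize(summary.x_name)}__"
            f"{_sanitize(summary.y_name)}.csv")


def export_summaries(summaries: list[GroupSummary], outdir) -> list[Path]:
    """One CSV (columns x, mean, sem, n) per (group, x, y)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in summaries:
        p = outdir / summary_filename(s)
        s.to_frame().to_csv(p, index=False)
        paths.append(p)
    return paths
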