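"""Reading tracker exports and standardizing them into arena-centered tracks.

Four delimited-text dialects are supported, one generic dialect per tracker
family rather than every proprietary export variant:

* ``generic`` — header line, columns ``time,x,y`` (cm, seconds);
* ``ethovision-like`` — leading ``key: value`` metadata lines, then a header
  and columns; missing samples encoded as blank or ``-``; coordinates are
  treated as already smoothed by the tracker;
* ``anymaze-like`` — columns ``Time``, ``Centre position X``, ``Centre
  position Y`` (cm);
* ``buritrack-like`` — whitespace-delimited ``t x y`` in pixels, with the
  pixel scale in a leading ``# px_per_cm <v>`` comment or a ``<file>.meta``
  sidecar.

Standardization applies, in order: unit conversion, zero-centering on the
arena center (explicit metadata or the minimal enclosing circle of the
points), smoothing (centered moving average; skipped for pre-smoothed
dialects), nearest-frame subsampling to the target period, and linear
interpolation of interior gaps.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RawTrack",
    "StandardTrack",
    "TrackParseError",
    "read_track_files",
    "standardize",
    "infer_arena_center",
    "smooth_xy",
    "write_standard_track",
    "read_standard_track",
]

PRE_SMOOTHED_DIALECTS = {"ethovision-like"}


class TrackParseError(ValueError):
    pass


@dataclass
class RawTrack:
    source: str
    dialect: str
    group: str
    arena: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    missing: np.ndarray
    units: str = "cm"              # "cm" or "px"
    px_per_cm: float | None = None
    center: tuple[float, float] | None = None
    pre_smoothed: bool = False

    def __post_init__(self):
        if not (len(self.t) == len(self.x) == len(self.y) == len(self.missing)):
            raise TrackParseError(f"{self.source}: t/x/y lengths differ")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise TrackParseError(
                f"{self.source}: timestamps not strictly increasing at row {i + 2}")


@dataclass
class StandardTrack:
    """Uniformly sampled, gap-free, arena-centered track in cm and seconds."""

    group: str
    arena: str
    arena_radius_cm: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dialect: str = "generic"
    uid: str = ""

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def period(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else np.nan


def _float_or_nan(tok: str) -> float:
    tok = tok.strip()
    if tok in ("", "-", "NA", "nan", "NaN"):
        return np.nan
    return float(tok)


def _find_column(cols, *names):
    lowered = {str(c).strip().lower(): c for c in cols}
    for n in names:
        if n.lower() in lowered:
            return lowered[n.lower()]
    return None


def _read_generic(path: Path):
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    meta = {}
    return df, {"time": ("time", "t", "time_s", "t_s"),
                "x": ("x", "x_cm"), "y": ("y", "y_cm")}, meta


def _read_ethovision(path: Path):
    meta = {}
    lines = path.read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        m = re.match(r"^\s*([A-Za-z _]+)\s*:\s*(.*)$", line)
        if m and "," not in m.group(1):
            meta[m.group(1).strip().lower().replace(" ", "_")] = m.group(2).strip()
        else:
            body_start = i
            break
    df = pd.read_csv(io.StringIO("\n".join(lines[body_start:])), sep=None,
                     engine="python")
    for c in df.columns:
        df[c] = [_float_or_nan(str(v)) for v in df[c]]
    return df, {"time": ("trial time", "time", "t"),
                "x": ("x center", "x"), "y": ("y center", "y")}, meta


def _read_anymaze(path: Path):
    df = pd.read_csv(path, sep=None, engine="python")
    return df, {"time": ("time",), "x": ("centre position x", "center position x"),
                "y": ("centre position y", "center position y")}, {}


def _read_buritrack(path: Path):
    meta = {}
    lines = path.read_text().splitlines()
    data_lines = []
    for line in lines:
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            m = re.search(r"px[_ ]?per[_ ]?cm\s*[:=]?\s*([0-9.]+)", s)
            if m:
                meta["px_per_cm"] = m.group(1)
            continue
        data_lines.append(s)
    side = path.with_suffix(path.suffix + ".meta")
    if "px_per_cm" not in meta and side.exists():
        m = re.search(r"px[_ ]?per[_ ]?cm\s*[:=]?\s*([0-9.]+)", side.read_text())
        if m:
            meta["px_per_cm"] = m.group(1)
    rows = []
    for ln, s in enumerate(data_lines):
        toks = s.split()
        if len(toks) < 3:
            raise TrackParseError(f"{path}: unparseable row at data line {ln + 1}")
        rows.append(toks[:3])
    df = pd.DataFrame(rows, columns=["t", "x", "y"]).apply(
        lambda col: [_float_or_nan(v) for v in col])
    return df, {"time": ("t",), "x": ("x",), "y": ("y",)}, meta


_READERS = {
    "generic": _read_generic,
    "ethovision-like": _read_ethovision,
    "anymaze-like": _read_anymaze,
    "buritrack-like": _read_buritrack,
}


def read_track_files(paths, dialect: str, group: str, config=None) -> list[RawTrack]:
    """Parse one RawTrack per file.

    The arena identifier comes from header metadata when the dialect carries
    it (ethovision-like ``Arena:`` lines), else from the file stem.
    """
    if dialect not in _READERS:
        raise TrackParseError(
            f"unknown dialect {dialect!r}; known: {sorted(_READERS)}")
    tracks = []
    for p in map(Path, paths):
        if not p.exists():
            raise TrackParseError(f"{p}: file not found")
        try:
            df, colmap, meta = _READERS[dialect](p)
        except TrackParseError:
            raise
        except Exception as exc:
            raise TrackParseError(f"{p}: {exc}") from exc
        resolved = {}
        for key, names in colmap.items():
            col = _find_column(df.columns, *names)
            if col is None:
                raise TrackParseError(
                    f"{p}: missing required column {names[0]!r}")
            resolved[key] = np.asarray(df[col], dtype=float)
        t, x, y = resolved["time"], resolved["x"], resolved["y"]
        if np.any(~np.isfinite(t)):
            raise TrackParseError(f"{p}: non-numeric timestamp")
        missing = ~(np.isfinite(x) & np.isfinite(y))
        units = "px" if dialect == "buritrack-like" else "cm"
        px_per_cm = float(meta["px_per_cm"]) if "px_per_cm" in meta else None
        if units == "px" and px_per_cm is None:
            raise TrackParseError(
                f"{p}: pixel-unit dialect but no px_per_cm metadata found")
        center = None
        if "center_x" in meta and "center_y" in meta:
            center = (float(meta["center_x"]), float(meta["center_y"]))
        arena = meta.get("arena", p.stem)
        tracks.append(RawTrack(
            source=str(p), dialect=dialect, group=group, arena=str(arena),
            t=t, x=x, y=y, missing=missing, units=units, px_per_cm=px_per_cm,
            center=center, pre_smoothed=dialect in PRE_SMOOTHED_DIALECTS))
    return tracks


# ---------------------------------------------------------------------------
# geometry: minimal enclosing circle (Welzl), for arena-center inference


def _circle_two(a, b):
    c = (a + b) / 2.0
    return c, float(np.hypot(*(a - c)))


def _circumcircle(a, b, c):
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-14:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, float(np.hypot(*(a - center)))


def _in_circle(c, r, p, tol=1e-10):
    return np.hypot(*(p - c)) <= r * (1 + tol) + tol


def minimal_enclosing_circle(points: np.ndarray, seed: int = 0):
    """Welzl's randomized incremental algorithm, expected O(n)."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) == 0:
        raise ValueError("no points")
    if len(pts) == 1:
        return pts[0].copy(), 0.0
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pts))
    pts = pts[order]
    c, r = _circle_two(pts[0], pts[1])
    for i in range(2, len(pts)):
        if _in_circle(c, r, pts[i]):
            continue
        c, r = _circle_two(pts[i], pts[0])
        for j in range(1, i):
            if _in_circle(c, r, pts[j]):
                continue
            c, r = _circle_two(pts[i], pts[j])
            for k in range(j):
                if _in_circle(c, r, pts[k]):
                    continue
                res = _circumcircle(pts[i], pts[j], pts[k])
                if res is not None:
                    c, r = res
    return c, r


def infer_arena_center(raw: RawTrack | np.ndarray) -> tuple[float, float]:
    """Arena center as the center of the minimal enclosing circle.

    Falls back to the bounding-box center (with a warning) for degenerate,
    near-collinear point sets.
    """
    if isinstance(raw, RawTrack):
        pts = np.column_stack([raw.x[~raw.missing], raw.y[~raw.missing]])
    else:
        pts = np.asarray(raw, dtype=float)
    if len(pts) < 10:
        raise ValueError("need at least 10 samples to infer the arena center")
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = hi - lo
    if min(span) < 1e-9 * max(max(span), 1.0):
        warnings.warn("near-collinear track; falling back to bounding-box center")
        return tuple((lo + hi) / 2.0)
    c, _ = minimal_enclosing_circle(pts)
    return float(c[0]), float(c[1])


def smooth_xy(x, y, window: int, missing: np.ndarray | None = None):
    """Centered moving average on x and y independently.

    The window is forced odd (>= 3).  Missing samples are excluded from every
    window mean and stay missing afterwards.  Shift-equivariant: smoothing a
    translated track equals translating the smoothed track.
    """
    window = max(3, int(window))
    if window % 2 == 0:
        window += 1
    xs = pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    ys = pd.Series(y).rolling(window, center=True, min_periods=1).mean().to_numpy()
    if missing is not None:
        xs[missing] = np.nan
        ys[missing] = np.nan
    return xs, ys


def default_smoothing_window(sample_freq: float) -> int:
    w = int(round(sample_freq / 6.0))
    w = max(3, w)
    if w % 2 == 0:
        w += 1
    return w


def standardize(raw: RawTrack, config) -> StandardTrack:
    """RawTrack -> StandardTrack via the fixed pipeline.

    Order: unit conversion -> zero-centering -> smoothing (skipped for
    pre-smoothed dialects) -> nearest-frame subsampling to
    ``config.time_bin_size`` -> linear interpolation of interior gaps
    (leading/trailing gaps are trimmed, never extrapolated).
    """
    x = raw.x.astype(float).copy()
    y = raw.y.astype(float).copy()
    t = raw.t.astype(float) - raw.t[0]
    missing = raw.missing.copy()
    if np.mean(missing) > 0.5:
        raise TrackParseError(f"{raw.source}: more than 50% of samples missing")
    if raw.units == "px":
        x = x / raw.px_per_cm
        y = y / raw.px_per_cm
        center = (tuple(np.asarray(raw.center) / raw.px_per_cm)
                  if raw.center is not None else None)
    else:
        center = raw.center
    if center is None:
        center = infer_arena_center(
            np.column_stack([x[~missing], y[~missing]]))
    x -= center[0]
    y -= center[1]
    x[missing] = np.nan
    y[missing] = np.nan
    if not raw.pre_smoothed:
        window = (config.smoothing_window if config.smoothing_window is not None
                  else default_smoothing_window(config.sample_freq))
        x, y = smooth_xy(x, y, window, missing)
    # nearest-frame subsampling preserves the native step-length distribution
    period = float(config.time_bin_size)
    targets = np.arange(0.0, t[-1] + period / 2, period)
    idx = np.searchsorted(t, targets)
    idx = np.clip(idx, 0, len(t) - 1)
    left_closer = (idx > 0) & (np.abs(targets - t[np.maximum(idx - 1, 0)])
                               <= np.abs(t[idx] - targets))
    idx[left_closer] -= 1
    idx = np.unique(idx)
    ts = idx * 0.0 + np.arange(len(idx)) * period
    xs, ys = x[idx], y[idx]
    valid = np.isfinite(xs) & np.isfinite(ys)
    if valid.any():
        first, last = np.argmax(valid), len(valid) - 1 - np.argmax(valid[::-1])
        xs, ys, ts = xs[first:last + 1], ys[first:last + 1], ts[first:last + 1]
        valid = valid[first:last + 1]
    if len(xs) < 3:
        raise TrackParseError(
            f"{raw.source}: fewer than 3 samples after subsampling")
    if (~valid).any():
        xs = np.interp(ts, ts[valid], xs[valid])
        ys = np.interp(ts, ts[valid], ys[valid])
    ts = ts - ts[0]
    radius = config.radius_for(raw.arena) if _has_arena_radius(config, raw.arena) \
        else config.radius_for(None)
    rmax = float(np.hypot(xs, ys).max())
    if rmax > radius * 1.05:
        raise TrackParseError(
            f"{raw.source}: samples reach {rmax:.2f} cm from center, beyond "
            f"the arena radius {radius} cm (+5% tolerance); check calibration")
    return StandardTrack(group=raw.group, arena=raw.arena,
                         arena_radius_cm=radius, t=ts, x=xs, y=ys,
                         dialect=raw.dialect, uid=Path(raw.source).stem)


def _has_arena_radius(config, arena) -> bool:
    from collections.abc import Mapping
    return isinstance(config.arena_radius_cm, Mapping) and \
        arena in config.arena_radius_cm


def write_standard_track(track: StandardTrack, path) -> None:
    pd.DataFrame({"t_s": track.t, "x_cm": track.x, "y_cm": track.y}).to_csv(
        path, index=False)


def read_standard_track(path, group: str, arena_radius_cm: float,
                        arena: str = "") -> StandardTrack:
    df = pd.read_csv(path)
    return StandardTrack(group=group, arena=arena or Path(path).stem,
                         arena_radius_cm=arena_radius_cm,
                         t=df["t_s"].to_numpy(), x=df["x_cm"].to_numpy(),
                         y=df["y_cm"].to_numpy(), uid=Path(path).stem)
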