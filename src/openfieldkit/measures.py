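"""Per-track behavioral measures for circular-arena open field data.

The measures quantify novelty habituation during locomotor exploration:

* **activity** — Euclidean step length between consecutive samples, with a
  configurable inactivity threshold absorbing tracker jitter;
* **coverage** — a sector-based count of boundary "learning trials": divide
  the arena boundary into M equal angular sectors, count entry events into
  each, and report ``C(t) = v_min(t) + (1/M) * #{sectors with v > v_min}``,
  i.e. the number of visits every sector has received plus the fraction of
  sectors beyond that minimum;
* rescalings of coverage — percent coverage (by the recording maximum) and
  PICA / PGCA (by the fitted individual / group coverage asymptote), which
  express the fraction of full habituation achieved;
* **turn classification and motion probabilities** — each decision between
  two consecutive steps is one of five outcomes (continue ++, reverse +-,
  stop +0, restart 0+, stay 00); group probabilities are reported in three
  variants differing in the conditioning denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .config import CoverageAsymptoteSpec
from .fit_models import get_form

__all__ = [
    "ActivitySeries",
    "CoverageState",
    "TransitionArrays",
    "MotionProbabilitySeries",
    "OUTCOMES",
    "activity",
    "cartesian_to_polar",
    "polar_to_cartesian",
    "edge_mask",
    "sector_index",
    "locate_sector_visits",
    "visit_matrix",
    "coverage",
    "coverage_series",
    "percent_coverage",
    "individual_coverage_asymptote",
    "pica",
    "pgca",
    "turning_angle",
    "turning_angles",
    "classify_transitions",
    "motion_probabilities",
    "individual_probability_series",
]

#: outcome order used throughout; codes are indices into this tuple
OUTCOMES = ("pp", "pm", "p0", "0p", "00")
MISSING = -1
_MOVING = (0, 1, 2)   # outcomes conditioned on a previous move
_RESTING = (3, 4)     # outcomes conditioned on a previous rest


@dataclass
class ActivitySeries:
    """Step lengths (cm) between consecutive samples; n-1 entries."""

    raw: np.ndarray
    thresholded: np.ndarray
    threshold: float


def activity(track, inactivity_threshold: float = 0.0) -> ActivitySeries:
    """Step length ΔD_i = |P_{i+1} - P_i|; steps below threshold become 0.

    Activity at time i is the step that *begins* at sample i.
    """
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    raw = np.hypot(dx, dy)
    thr = raw.copy()
    thr[thr < inactivity_threshold] = 0.0
    return ActivitySeries(raw=raw, thresholded=thr,
                          threshold=float(inactivity_threshold))


def cartesian_to_polar(x, y):
    """Arena-centered (x, y) -> (r, theta); theta in degrees, CCW from +x, [0, 360)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = np.hypot(x, y)
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    theta = np.where(r == 0, 0.0, theta)
    return r, theta


def polar_to_cartesian(r, theta_deg):
    th = np.radians(np.asarray(theta_deg, dtype=float))
    r = np.asarray(r, dtype=float)
    return r * np.cos(th), r * np.sin(th)


def edge_mask(track, edge_dist_cm: float) -> np.ndarray:
    """True where the sample lies in the edge band r >= R - edge_dist_cm."""
    r, _ = cartesian_to_polar(track.x, track.y)
    return r >= track.arena_radius_cm - edge_dist_cm


def sector_index(theta_deg, node_size: float) -> np.ndarray:
    """0-based sector index of each angular position."""
    M = int(round(360.0 / node_size))
    return (np.floor(np.asarray(theta_deg) / node_size).astype(int)) % M


@dataclass
class CoverageState:
    """Sector-visit bookkeeping and the coverage series for one track.

    ``events`` lists (sample_index, sector) visit credits in track order;
    ``final_counts`` is the end-of-recording per-sector visit vector.
    """

    M: int
    events: list
    final_counts: np.ndarray
    sample_times: np.ndarray
    C: np.ndarray                       # coverage at sample_times
    C_at_samples: np.ndarray            # coverage at every track sample
    percent: np.ndarray = field(default=None)
    A_ind: float | None = None
    pica: np.ndarray | None = None
    pgca: np.ndarray | None = None


def locate_sector_visits(track, node_size: float, edge_dist_cm: float):
    """Count sector *entry* events along a track.

    A sample credits a visit to its sector iff it lies in the edge band and
    either it is the first edge sample, or the previous edge sample sat in a
    different sector.  Lingering in one sector adds nothing.  When two
    consecutive in-band samples fall in non-adjacent sectors, every
    intermediate sector on the shorter angular arc is credited once (the
    subject necessarily passed through them); an exact half-circle jump is
    imputed counterclockwise.  Re-entering the same sector after a radial
    excursion out of the band counts as the same visit unless a different
    sector was entered in between.

    Returns ``(events, final_counts)`` with events as (sample_index, sector).
    """
    M = int(round(360.0 / node_size))
    r, theta = cartesian_to_polar(track.x, track.y)
    inband = r >= track.arena_radius_cm - edge_dist_cm
    sec = sector_index(theta, node_size)
    events: list[tuple[int, int]] = []
    counts = np.zeros(M, dtype=np.int64)
    last_sec = None        # sector of the most recent in-band sample
    prev_inband = False    # was sample i-1 in the band?
    for i in range(len(sec)):
        if not inband[i]:
            prev_inband = False
            continue
        s = int(sec[i])
        if last_sec is None:
            events.append((i, s))
            counts[s] += 1
        elif prev_inband:
            if s != last_sec:
                d_ccw = (s - last_sec) % M
                d_cw = (last_sec - s) % M
                if d_ccw <= d_cw:  # ties (180 deg) imputed counterclockwise
                    path = [(last_sec + k) % M for k in range(1, d_ccw + 1)]
                else:
                    path = [(last_sec - k) % M for k in range(1, d_cw + 1)]
                for p in path:
                    events.append((i, p))
                    counts[p] += 1
        else:
            if s != last_sec:
                events.append((i, s))
                counts[s] += 1
        last_sec = s
        prev_inband = True
    return events, counts


def visit_matrix(events, M: int, n_samples: int) -> np.ndarray:
    """Full v(sector, sample) cumulative visit-count matrix (tests / small M)."""
    v = np.zeros((M, n_samples), dtype=np.int64)
    for i, s in events:
        v[s, i:] += 1
    return v


def coverage(v, M: int | None = None):
    """Eq.-style coverage from a visit-count vector or (sector x time) matrix.

    ``C = v_min + (1/M) * #{sectors with v > v_min}``, columnwise for a matrix.
    """
    v = np.asarray(v)
    if v.ndim == 1:
        M = M if M is not None else v.size
        vmin = v.min()
        return float(vmin) + float(np.count_nonzero(v > vmin)) / M
    M = M if M is not None else v.shape[0]
    vmin = v.min(axis=0)
    return vmin + (v > vmin).sum(axis=0) / M


def coverage_series(events, M: int, track_times, eval_times) -> np.ndarray:
    """Coverage evaluated at ``eval_times`` by carrying visit counts forward."""
    eval_times = np.asarray(eval_times, dtype=float)
    counts = np.zeros(M, dtype=np.int64)
    C = np.empty(eval_times.size)
    ev_t = np.array([track_times[i] for i, _ in events], dtype=float)
    ev_s = np.array([s for _, s in events], dtype=int)
    ptr = 0
    for k, tc in enumerate(eval_times):
        while ptr < ev_t.size and ev_t[ptr] <= tc + 1e-12:
            counts[ev_s[ptr]] += 1
            ptr += 1
        vmin = counts.min()
        C[k] = vmin + np.count_nonzero(counts > vmin) / M
    return C


def percent_coverage(C) -> np.ndarray:
    """C(t) / max(C); final value 1 when any coverage was accumulated."""
    C = np.asarray(C, dtype=float)
    m = C.max() if C.size else 0.0
    if m <= 0:
        if C.size:
            warnings.warn("all-zero coverage series; percent coverage left at 0")
        return np.zeros_like(C)
    return C / m


def individual_coverage_asymptote(t, C, spec: CoverageAsymptoteSpec | None = None):
    """Fit the time-coverage curve and return the habituation asymptote.

    With the default asymptotic increase form a(e^{bt}-1), a<0, b<0, the
    asymptote is -a: the number of visits per sector needed to fully
    habituate.  Returns None (with a warning) on non-convergence.
    """
    spec = spec or CoverageAsymptoteSpec()
    form = get_form(spec.f_name)
    t = np.asarray(t, dtype=float)
    C = np.asarray(C, dtype=float)
    ok = np.isfinite(t) & np.isfinite(C)
    t, C = t[ok], C[ok]
    if t.size < 4:
        warnings.warn("too few coverage samples to fit an asymptote")
        return None
    lo, hi = (spec.parameter_bounds if spec.parameter_bounds is not None
              else form.sign_bounds())
    x0 = (np.asarray(spec.initial_parameters, float)
          if spec.initial_parameters is not None else form.guess(t, C))
    x0 = np.clip(x0, np.asarray(lo, float) + 1e-12, np.asarray(hi, float) - 1e-12)
    try:
        res = least_squares(lambda p: form(t, p) - C, x0, bounds=(lo, hi),
                            method="trf", max_nfev=spec.max_f_eval)
    except Exception:
        res = None
    if res is None or res.status <= 0 or not np.all(np.isfinite(res.x)):
        warnings.warn("coverage-asymptote fit did not converge")
        return None
    return float(spec.asymptote_sign * res.x[spec.asymptote_param])


def pica(C, A_ind: float | None) -> np.ndarray | None:
    """Coverage as a fraction of the individual's fitted asymptote."""
    if A_ind is None or not A_ind > 0:
        return None
    return np.asarray(C, dtype=float) / A_ind


def pgca(C, A_grp: float | None) -> np.ndarray | None:
    """Coverage as a fraction of the group-mean asymptote."""
    if A_grp is None or not A_grp > 0:
        return None
    return np.asarray(C, dtype=float) / A_grp


def turning_angle(P1, P2, P3, threshold: float = 0.0):
    """Turn magnitude at P2 in degrees, [0, 180], or None when undefined.

    Uses the law of cosines on the triangle (P1, P2, P3): with step lengths
    s1, s2 and closing distance d, the interior angle at P2 is
    phi = arccos((s1^2 + s2^2 - d^2) / (2 s1 s2)) and the turn is
    theta = 180 - phi (0 = straight ahead, 180 = full reversal).  Undefined
    when either step is below the inactivity threshold.
    """
    P1 = np.asarray(P1, float)
    P2 = np.asarray(P2, float)
    P3 = np.asarray(P3, float)
    s1 = float(np.hypot(*(P2 - P1)))
    s2 = float(np.hypot(*(P3 - P2)))
    if s1 < threshold or s2 < threshold or s1 == 0.0 or s2 == 0.0:
        return None
    d = float(np.hypot(*(P3 - P1)))
    cos_phi = np.clip((s1 * s1 + s2 * s2 - d * d) / (2.0 * s1 * s2), -1.0, 1.0)
    phi = np.degrees(np.arccos(cos_phi))
    return 180.0 - phi


def turning_angles(track, act: ActivitySeries) -> np.ndarray:
    """Vectorized turn magnitudes at samples 1..n-2; NaN where undefined."""
    x, y = track.x, track.y
    s1 = act.thresholded[:-1]
    s2 = act.thresholded[1:]
    r1 = act.raw[:-1]
    r2 = act.raw[1:]
    d = np.hypot(x[2:] - x[:-2], y[2:] - y[:-2])
    with np.errstate(divide="ignore", invalid="ignore"):
        cos_phi = np.clip((r1 ** 2 + r2 ** 2 - d ** 2) / (2.0 * r1 * r2),
                          -1.0, 1.0)
        theta = 180.0 - np.degrees(np.arccos(cos_phi))
    theta[(s1 == 0) | (s2 == 0)] = np.nan
    return theta


@dataclass
class TransitionArrays:
    """Per-decision turn outcomes for one track.

    ``codes[i]`` classifies the decision at sample i+1 (between step i and
    step i+1) as an index into :data:`OUTCOMES`, or -1 when the subject was
    outside the edge band.  ``theta`` is the turn magnitude (NaN when either
    adjacent step is zero).
    """

    times: np.ndarray
    codes: np.ndarray
    theta: np.ndarray
    in_edge: np.ndarray

    def indicator(self, outcome: str) -> np.ndarray:
        return (self.codes == OUTCOMES.index(outcome)).astype(np.int8)


def classify_transitions(track, act: ActivitySeries,
                         in_edge: np.ndarray | None = None,
                         edge_dist_cm: float | None = None) -> TransitionArrays:
    """Classify every decision into one of the five turn outcomes.

    For n samples there are n-1 steps and n-2 decisions; the decision at
    sample i compares step i-1 (previous) with step i (current), both after
    inactivity thresholding:

    * previous > 0 and current > 0: ``pp`` if |turn| <= 90 else ``pm``;
    * previous > 0, current = 0: ``p0``;
    * previous = 0: ``0p`` if current > 0 else ``00``.

    Decisions taken outside the edge band are recorded as missing.
    """
    n = len(track.x)
    if n < 3:
        raise ValueError("need at least 3 samples to classify decisions")
    if in_edge is None:
        if edge_dist_cm is None:
            in_edge = np.ones(n, dtype=bool)
        else:
            in_edge = edge_mask(track, edge_dist_cm)
    prev = act.thresholded[:-1]
    cur = act.thresholded[1:]
    theta = turning_angles(track, act)
    codes = np.full(n - 2, MISSING, dtype=np.int8)
    dec_edge = np.asarray(in_edge)[1:-1]
    moving = (prev > 0) & (cur > 0)
    codes[moving & (theta <= 90.0)] = 0                     # pp
    codes[moving & (theta > 90.0)] = 1                      # pm
    codes[(prev > 0) & (cur == 0)] = 2                      # p0
    codes[(prev == 0) & (cur > 0)] = 3                      # 0p
    codes[(prev == 0) & (cur == 0)] = 4                     # 00
    codes[~dec_edge] = MISSING
    return TransitionArrays(times=track.t[1:-1], codes=codes, theta=theta,
                            in_edge=dec_edge)


@dataclass
class MotionProbabilitySeries:
    """Group-level turn-outcome probabilities over decision times."""

    variant: str
    times: np.ndarray
    values: dict[str, np.ndarray]
    denominators: dict[str, np.ndarray]
    n_individuals: int


def motion_probabilities(transitions: list[TransitionArrays],
                         variant: str = "given_previous") -> MotionProbabilitySeries:
    """Population probabilities of the five outcomes at each decision time.

    * ``given_previous`` — numerator: individuals with the outcome;
      denominator: individuals with any outcome sharing its precondition
      (a previous move for pp/pm/p0, a previous rest for 0p/00), so
      P_pp+P_pm+P_p0 = 1 and P_0p+P_00 = 1 where defined.
    * ``given_any`` — denominator: individuals with any classified (in-edge)
      decision; all five sum to 1 where defined.
    * ``raw`` — denominator: group size.
    """
    if not transitions:
        raise ValueError("empty group")
    if variant not in ("given_previous", "given_any", "raw"):
        raise ValueError(f"unknown variant {variant!r}")
    T = min(t.codes.size for t in transitions)
    codes = np.stack([t.codes[:T] for t in transitions])
    times = transitions[0].times[:T]
    n_ind = codes.shape[0]
    counts = np.stack([(codes == k).sum(axis=0) for k in range(5)])
    values: dict[str, np.ndarray] = {}
    denoms: dict[str, np.ndarray] = {}
    moving_denom = counts[list(_MOVING)].sum(axis=0)
    resting_denom = counts[list(_RESTING)].sum(axis=0)
    any_denom = counts.sum(axis=0)
    for k, name in enumerate(OUTCOMES):
        if variant == "given_previous":
            denom = moving_denom if k in _MOVING else resting_denom
        elif variant == "given_any":
            denom = any_denom
        else:
            denom = np.full(T, n_ind)
        with np.errstate(divide="ignore", invalid="ignore"):
            val = np.where(denom > 0, counts[k] / np.maximum(denom, 1), np.nan)
        values[name] = val
        denoms[name] = denom.astype(float)
    return MotionProbabilitySeries(variant=variant, times=times, values=values,
                                   denominators=denoms, n_individuals=n_ind)


def individual_probability_series(ta: TransitionArrays, outcome: str,
                                  variant: str = "given_previous") -> np.ndarray:
    """One subject's conditional outcome series, for model fitting.

    ``given_previous``: 1 where the outcome occurred, 0 where an alternative
    sharing its precondition occurred, NaN elsewhere (e.g. the stay series is
    1 at 00, 0 at 0+, NaN at every moving or out-of-band decision).
    ``given_any``: 0 at any other classified decision.  ``raw``: 0 everywhere
    the outcome did not occur.
    """
    k = OUTCOMES.index(outcome)
    codes = ta.codes
    out = np.full(codes.shape, np.nan)
    if variant == "given_previous":
        pool = _MOVING if k in _MOVING else _RESTING
        defined = np.isin(codes, pool)
        out[defined] = 0.0
    elif variant == "given_any":
        out[codes != MISSING] = 0.0
    elif variant == "raw":
        out[:] = 0.0
    else:
        raise ValueError(f"unknown variant {variant!r}")
    out[codes == k] = 1.0
    return out
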