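"""Synthetic open-field tracks with known ground truth.

Two generators make every downstream stage testable without recorded data:

* :func:`simulate_explorer` — a stochastic edge-dwelling habituating walker.
  Nonzero step lengths decay exponentially in time (mean a0 e^{b0 t} + c0,
  the inverse of the exponential-decay habituation model), the probability
  of continuing in the same tangential direction decays with a configurable
  half-life, pauses are exact zero steps whose probability ramps up as the
  walker habituates, and the walker stays inside the arena disc with a
  configurable affinity for the edge band.
* :func:`scripted_track` — a deterministic boundary walk through an exact
  sector sequence (laps plus an explicit path), used to validate the
  visit-counting and coverage machinery against hand-countable ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .track_io import StandardTrack

__all__ = [
    "ExplorerParams",
    "ScriptedTrackSpec",
    "simulate_explorer",
    "scripted_track",
    "demo_lap_track",
    "make_cohort",
    "write_cohort_files",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class ExplorerParams:
    """Ground-truth parameters of the habituating explorer.

    ``a0 e^{b0 t} + c0`` is the mean *nonzero* step length (cm) at time t;
    pauses (exact zero steps) are governed separately by
    ``pause_prob_final``, whose probability rises from 0 with the same
    half-life that drives the decay of directional persistence.
    """

    a0: float = 1.5
    b0: float = -0.008
    c0: float = 0.06
    persistence_half_life: float = 150.0
    pause_prob_final: float = 0.3
    arena_radius_cm: float = 4.2
    edge_affinity: float = 0.9
    edge_band_cm: float = 1.0
    #: probability that a direction re-draw restores the individual's
    #: preferred circling direction (thigmotactic wall-following handedness);
    #: 0.5 makes reversals symmetric and angular motion purely diffusive
    handedness_bias: float = 0.75
    sample_freq: float = 1.0
    duration_s: float = 600.0
    jitter_cm: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.a0 < 0 or self.c0 < 0:
            raise ValueError("a0 and c0 must be >= 0")
        if self.b0 > 0:
            raise ValueError("b0 must be <= 0 (habituation decays)")
        for name in ("pause_prob_final", "edge_affinity"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.arena_radius_cm <= 0 or self.sample_freq <= 0 \
                or self.duration_s <= 0:
            raise ValueError("arena_radius_cm, sample_freq, duration_s must be > 0")


def simulate_explorer(params: ExplorerParams, group: str = "sim",
                      uid: str = "") -> StandardTrack:
    """Simulate one habituating edge-dwelling walker; reproducible per seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.sample_freq)) + 1
    dt = 1.0 / params.sample_freq
    R = params.arena_radius_cm
    band_lo = max(R - params.edge_band_cm, 0.05 * R)
    band_hi = 0.99 * R
    # two-state radial zone chain with stationary edge occupancy = edge_affinity
    p_enter = 0.5
    aff = min(max(params.edge_affinity, 1e-9), 1 - 1e-9)
    p_leave = min(1.0, p_enter * (1 - aff) / aff)

    phi = rng.uniform(0, 2 * np.pi)
    r = rng.uniform(band_lo, band_hi)
    handedness = float(rng.choice([-1.0, 1.0]))
    direction = handedness
    in_band = True
    xs = np.empty(n)
    ys = np.empty(n)
    xs[0], ys[0] = r * np.cos(phi), r * np.sin(phi)
    for k in range(1, n):
        t = (k - 1) * dt
        decay = math.exp(-t * _LN2 / params.persistence_half_life) \
            if params.persistence_half_life > 0 else 0.0
        p_pause = params.pause_prob_final * (1.0 - decay)
        if rng.random() < p_pause:
            xs[k], ys[k] = xs[k - 1], ys[k - 1]
            continue
        mean_len = params.a0 * math.exp(params.b0 * t) + params.c0
        step = rng.gamma(4.0, mean_len / 4.0) if mean_len > 0 else 0.0
        p_same = 0.5 + 0.5 * decay
        if rng.random() > p_same:
            direction = handedness if rng.random() < params.handedness_bias \
                else -handedness
        if in_band:
            if rng.random() < p_leave:
                in_band = False
                r_target = rng.uniform(0.3 * R, band_lo)
            else:
                r_target = min(band_hi, max(band_lo,
                                            r + rng.normal(0.0, 0.03)))
        else:
            if rng.random() < p_enter:
                in_band = True
                r_target = rng.uniform(band_lo, band_hi)
            else:
                r_target = rng.uniform(0.3 * R, band_lo)
        dr = r_target - r
        if abs(dr) >= step:
            r = r + math.copysign(step, dr)
        else:
            tangential = math.sqrt(max(step * step - dr * dr, 0.0))
            r = r_target
            phi += direction * tangential / max(r, 1e-6)
        xs[k], ys[k] = r * np.cos(phi), r * np.sin(phi)
    if params.jitter_cm > 0:
        xs = xs + rng.normal(0.0, params.jitter_cm, n)
        ys = ys + rng.normal(0.0, params.jitter_cm, n)
        rad = np.hypot(xs, ys)
        over = rad > R
        if over.any():
            scale = np.where(over, R / rad, 1.0)
            xs, ys = xs * scale, ys * scale
    t_axis = np.arange(n) * dt
    return StandardTrack(group=group, arena="sim", arena_radius_cm=R,
                         t=t_axis, x=xs, y=ys, dialect="synthetic",
                         uid=uid or f"sim{params.seed}")


@dataclass(frozen=True)
class ScriptedTrackSpec:
    """A boundary walk through an exact sector itinerary (1-based sectors)."""

    M: int = 24
    start_sector: int = 1
    lap_count: int = 1
    extra_path: tuple[int, ...] = ()
    sectors_per_step: int = 1
    sample_period: float = 1.0

    def validate(self) -> None:
        if self.M < 2:
            raise ValueError("M must be >= 2")
        if not 1 <= self.start_sector <= self.M:
            raise ValueError("start_sector out of range")
        if self.lap_count < 0:
            raise ValueError("lap_count must be >= 0")
        for s in self.extra_path:
            if not 1 <= s <= self.M:
                raise ValueError(f"extra_path sector {s} out of [1, {self.M}]")


def scripted_track(spec: ScriptedTrackSpec,
                   arena_radius_cm: float = 4.2) -> StandardTrack:
    """One sample per scripted sector, placed at the sector center near the wall.

    Laps run counterclockwise from ``start_sector``; ``extra_path`` then
    continues the walk and must stay contiguous in sector adjacency (each
    hop at most ``sectors_per_step`` sectors).
    """
    spec.validate()
    M = spec.M
    seq: list[int] = []
    for _ in range(spec.lap_count):
        seq.extend(((spec.start_sector - 1 + k) % M) + 1 for k in range(M))
    if spec.extra_path:
        prev = seq[-1] if seq else None
        for s in spec.extra_path:
            if prev is not None:
                hop = min((s - prev) % M, (prev - s) % M)
                if hop > spec.sectors_per_step:
                    raise ValueError(
                        f"extra_path not contiguous: sector {prev} -> {s} "
                        f"jumps {hop} sectors")
            seq.append(s)
            prev = s
    if not seq:
        raise ValueError("empty itinerary: lap_count=0 and no extra_path")
    node = 360.0 / M
    angles = np.radians((np.array(seq) - 0.5) * node)
    radius = 0.96 * arena_radius_cm
    t = np.arange(len(seq)) * spec.sample_period
    return StandardTrack(group="scripted", arena="scripted",
                         arena_radius_cm=arena_radius_cm, t=t,
                         x=radius * np.cos(angles), y=radius * np.sin(angles),
                         dialect="synthetic", uid="scripted")


def demo_lap_track(arena_radius_cm: float = 4.2,
                        duration_s: float = 200.0) -> StandardTrack:
    """The 24-sector worked example: first detected in sector 6, three full
    laps, then a walk from sector 6 down to sector 1 (sectors 1-6 end with 4
    visits, sectors 7-24 with 3)."""
    seq_len = 3 * 24 + 6
    spec = ScriptedTrackSpec(M=24, start_sector=6, lap_count=3,
                             extra_path=(6, 5, 4, 3, 2, 1),
                             sample_period=duration_s / (seq_len - 1))
    return scripted_track(spec, arena_radius_cm)


def make_cohort(n: int, params: ExplorerParams,
                between_individual_sd: float = 0.15, seed: int = 0,
                group: str = "sim"):
    """n explorers with per-individual parameters drawn around ``params``.

    a0, |b0|, c0 and the persistence half-life are scaled by independent
    multiplicative factors ``max(0.05, 1 + sd*z)``, z ~ N(0,1).  Each track
    gets its own generator with seed ``seed + index`` so cohorts are
    reproducible under parallel generation.  Returns ``(tracks, truth)``
    where ``truth`` is a DataFrame of the per-individual generating values.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    master = np.random.default_rng(seed)
    tracks = []
    rows = []
    for i in range(n):
        z = master.normal(size=4)
        f = np.maximum(0.05, 1.0 + between_individual_sd * z)
        p = replace(params,
                    a0=params.a0 * f[0],
                    b0=params.b0 * f[1],
                    c0=params.c0 * f[2],
                    persistence_half_life=params.persistence_half_life * f[3],
                    seed=seed + i)
        uid = f"{group}_{i:03d}"
        tracks.append(simulate_explorer(p, group=group, uid=uid))
        rows.append({"id": uid, "a0": p.a0, "b0": p.b0, "c0": p.c0,
                     "persistence_half_life": p.persistence_half_life,
                     "pause_prob_final": p.pause_prob_final})
    return tracks, pd.DataFrame(rows)


def write_cohort_files(tracks, outdir) -> list[Path]:
    """Dump tracks to the generic dialect so the file pipeline can be exercised."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for tr in tracks:
        p = outdir / f"{tr.uid or tr.group}.csv"
        pd.DataFrame({"time": tr.t, "x": tr.x, "y": tr.y}).to_csv(p, index=False)
        paths.append(p)
    return paths
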