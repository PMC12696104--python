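"""Analysis configuration: user parameters, defaults, and the fit-spec grid.

Three layers of settings drive a run:

* :class:`AnalysisConfig` — the experiment-specific parameters (groups and
  their tracker dialects, arena radius, frame rate, edge band, subsampling
  period, inactivity threshold, refit bound level).
* :class:`DefaultsConfig` — knobs a typical user leaves alone (sector size,
  coverage sampling granularity, analysis toggles, binning sizes).
* :class:`ModelSpec` / :class:`CoverageAsymptoteSpec` — which parametric form
  models each (x, y) relationship and how the coverage asymptote is extracted.

:func:`set_up_fits` expands the enabled variable grid into one
:class:`ModelSpec` per (x, y) pair with field-standard default forms.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .fit_models import FORMS, get_form

__all__ = [
    "AnalysisConfig",
    "DefaultsConfig",
    "CoverageAsymptoteSpec",
    "ModelSpec",
    "ConfigError",
    "set_up_fits",
    "validate_config",
    "load_config",
    "save_config",
    "X_VARIABLES",
    "PROB_OUTCOMES",
    "PROB_VARIANTS",
    "DEFAULT_Y_FORMS",
]

KNOWN_DIALECTS = ("generic", "ethovision-like", "anymaze-like", "buritrack-like")

X_VARIABLES = ("time", "coverage", "percent_coverage", "pica", "pgca")
PROB_OUTCOMES = ("prob_pp", "prob_pm", "prob_p0", "prob_0p", "prob_00")
PROB_VARIANTS = ("given_previous", "given_any", "raw")

# Default functional form per y-variable family.  The stopping probability
# prob_p0 is assigned exponential decay here but is freely overridable; the
# restarting probability prob_0p mirrors prob_00's complement and gets the
# asymptotic increase form.
DEFAULT_Y_FORMS = {
    "activity": "exponential_decay",
    "coverage": "asymptotic_increase",
    "prob_pp": "exponential_decay",
    "prob_pm": "asymptotic_increase",
    "prob_p0": "exponential_decay",
    "prob_0p": "asymptotic_increase",
    "prob_00": "asymptotic_increase",
}


class ConfigError(ValueError):
    """Raised when a configuration fails validation; carries all messages."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass
class AnalysisConfig:
    groups_and_types: dict[str, str] = field(default_factory=dict)
    #: global radius (cm) or per-arena mapping
    arena_radius_cm: float | dict[str, float] = 4.2
    sample_freq: float = 30.0
    edge_dist_cm: float = 1.0
    time_bin_size: float = 1.0
    inactivity_threshold: float = 0.05
    bound_level: float = 2.0
    smoothing_window: int | None = None  # None -> round(sample_freq / 6), odd, >= 3
    verbose: bool = True
    save_outputs: bool = True

    def radius_for(self, arena: str | None = None) -> float:
        if isinstance(self.arena_radius_cm, Mapping):
            if arena is None or arena not in self.arena_radius_cm:
                raise KeyError(f"no arena radius registered for arena {arena!r}")
            return float(self.arena_radius_cm[arena])
        return float(self.arena_radius_cm)


@dataclass
class DefaultsConfig:
    #: sector central angle, degrees; must divide 360 evenly.  The default
    #: 0.1 degree (3600 sectors) suits cm-scale subjects; sanity-check the
    #: resulting arc length against the subject's body length.
    node_size: float = 0.1
    coverage_sample_period: float = 1.0
    enable_pica: bool = False
    enable_pgca: bool = False
    enable_coverage_x: bool = False
    enable_percent_coverage_x: bool = True
    variants: tuple[str, ...] = ("given_previous",)
    enable_motion_probabilities: bool = True
    plot_categories: tuple[str, ...] = (
        "traces", "individuals", "solo_group", "group_components",
        "group_comparison")
    n_points: int = 50
    n_bins: int = 50

    def x_variables(self) -> tuple[str, ...]:
        xs = ["time"]
        if self.enable_coverage_x:
            xs.append("coverage")
        if self.enable_percent_coverage_x:
            xs.append("percent_coverage")
        if self.enable_pica:
            xs.append("pica")
        if self.enable_pgca:
            xs.append("pgca")
        return tuple(xs)

    def y_variables(self) -> tuple[str, ...]:
        ys = ["activity", "coverage"]
        if self.enable_motion_probabilities:
            for variant in self.variants:
                ys.extend(f"{o}_{variant}" for o in PROB_OUTCOMES)
        return tuple(ys)


@dataclass
class CoverageAsymptoteSpec:
    """How to extract the habituation asymptote from the time-coverage fit.

    With the asymptotic increase form a(e^{bx}-1) (a<0, b<0) the curve rises
    from 0 toward -a, so the asymptote is parameter 0 with sign -1.
    """

    f_name: str = "asymptotic_increase"
    asymptote_param: int = 0
    asymptote_sign: int = -1
    initial_parameters: tuple[float, ...] | None = None
    parameter_bounds: tuple | None = None
    max_f_eval: int = 5000

    def validate(self) -> list[str]:
        errs = []
        if self.f_name not in FORMS:
            errs.append(f"unknown coverage-asymptote form {self.f_name!r}")
        else:
            arity = get_form(self.f_name).arity
            if not 0 <= self.asymptote_param < arity:
                errs.append(
                    f"asymptote_param {self.asymptote_param} out of range for "
                    f"{self.f_name!r} (arity {arity})")
        if self.asymptote_sign not in (1, -1):
            errs.append(f"asymptote_sign must be +1 or -1, got {self.asymptote_sign}")
        return errs


@dataclass
class ModelSpec:
    """Which form models one (x, y) relationship, and how to fit/render it."""

    axes: tuple[str, str]
    model: str
    initial_parameters: tuple[float, ...] | None = None
    parameter_bounds: tuple | None = None
    display_parts: tuple[str, ...] | None = None
    max_f_eval: int = 5000

    def __post_init__(self):
        if self.display_parts is None and self.model in FORMS:
            self.display_parts = get_form(self.model).display_parts


def _y_family(y_var: str) -> str:
    for outcome in PROB_OUTCOMES:
        if y_var.startswith(outcome):
            return outcome
    return y_var


def set_up_fits(config: AnalysisConfig,
                defaults: DefaultsConfig) -> dict[tuple[str, str], ModelSpec]:
    """One ModelSpec per enabled (x, y) pair.

    Coverage appears as a y-variable only against time.  Returned specs use
    the default form for each y family; callers may replace individual
    entries before fitting.
    """
    specs: dict[tuple[str, str], ModelSpec] = {}
    for x_var in defaults.x_variables():
        if x_var not in X_VARIABLES:
            raise ConfigError([f"unknown x variable {x_var!r}"])
        for y_var in defaults.y_variables():
            if y_var == "coverage" and x_var != "time":
                continue
            if y_var == x_var:
                continue
            family = _y_family(y_var)
            if family not in DEFAULT_Y_FORMS:
                raise ConfigError([f"unknown y variable {y_var!r}"])
            specs[(x_var, y_var)] = ModelSpec(
                axes=(x_var, y_var), model=DEFAULT_Y_FORMS[family])
    return specs


def validate_config(config: AnalysisConfig,
                    defaults: DefaultsConfig | None = None) -> list[str]:
    """Check every invariant; returns the full list of violations (no raise)."""
    errs: list[str] = []
    if not config.groups_and_types:
        errs.append("groups_and_types must name at least one group")
    for g, dialect in config.groups_and_types.items():
        if dialect not in KNOWN_DIALECTS:
            errs.append(
                f"group {g!r} maps to unknown tracker dialect {dialect!r}; "
                f"known: {KNOWN_DIALECTS}")
    radii = (config.arena_radius_cm.values()
             if isinstance(config.arena_radius_cm, Mapping)
             else [config.arena_radius_cm])
    min_radius = None
    for r in radii:
        if not r > 0:
            errs.append(f"arena_radius_cm must be positive, got {r}")
        else:
            min_radius = r if min_radius is None else min(min_radius, r)
    if not config.sample_freq > 0:
        errs.append(f"sample_freq must be positive, got {config.sample_freq}")
    if not config.edge_dist_cm > 0:
        errs.append(f"edge_dist_cm must be positive, got {config.edge_dist_cm}")
    elif min_radius is not None and config.edge_dist_cm > min_radius:
        errs.append(
            f"edge_dist_cm ({config.edge_dist_cm}) exceeds the arena radius "
            f"({min_radius}); set it equal to the radius to disable the edge "
            "restriction")
    if config.sample_freq > 0 and config.time_bin_size * config.sample_freq < 1:
        errs.append(
            f"time_bin_size ({config.time_bin_size} s) is below the native "
            f"frame interval (1/{config.sample_freq} s)")
    if config.inactivity_threshold < 0:
        errs.append("inactivity_threshold must be >= 0")
    if not config.bound_level > 0:
        errs.append("bound_level must be positive")
    if config.smoothing_window is not None and config.smoothing_window < 1:
        errs.append("smoothing_window must be >= 1 when given")
    if defaults is not None:
        if defaults.node_size <= 0 or abs(round(360 / defaults.node_size)
                                          - 360 / defaults.node_size) > 1e-9:
            errs.append(
                f"node_size ({defaults.node_size}) must divide 360 evenly")
        if defaults.coverage_sample_period <= 0:
            errs.append("coverage_sample_period must be positive")
        if defaults.n_points < 2:
            errs.append("n_points must be >= 2")
        if defaults.n_bins < 2:
            errs.append("n_bins must be >= 2")
        for v in defaults.variants:
            if v not in PROB_VARIANTS:
                errs.append(f"unknown motion-probability variant {v!r}")
    return errs


# ---------------------------------------------------------------------------
# TOML round trip.  tomllib is read-only, so a minimal writer lives here.


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def save_config(path, config: AnalysisConfig, defaults: DefaultsConfig,
                group_colors: Mapping[str, str] | None = None) -> None:
    lines = ["[analysis]"]
    for name in ("arena_radius_cm", "sample_freq", "edge_dist_cm",
                 "time_bin_size", "inactivity_threshold", "bound_level",
                 "verbose", "save_outputs"):
        val = getattr(config, name)
        if isinstance(val, Mapping):
            continue
        lines.append(f"{name} = {_toml_value(val)}")
    if config.smoothing_window is not None:
        lines.append(f"smoothing_window = {_toml_value(config.smoothing_window)}")
    if isinstance(config.arena_radius_cm, Mapping):
        lines.append("\n[analysis.arena_radius_cm]")
        for k, v in config.arena_radius_cm.items():
            lines.append(f"{_toml_value(k)} = {_toml_value(v)}")
    lines.append("\n[analysis.groups_and_types]")
    for g, d in config.groups_and_types.items():
        lines.append(f"{_toml_value(g)} = {_toml_value(d)}")
    if group_colors:
        lines.append("\n[plot.group_colors]")
        for g, c in group_colors.items():
            lines.append(f"{_toml_value(g)} = {_toml_value(c)}")
    lines.append("\n[defaults]")
    for name in ("node_size", "coverage_sample_period", "enable_pica",
                 "enable_pgca", "enable_coverage_x",
                 "enable_percent_coverage_x", "variants",
                 "enable_motion_probabilities", "plot_categories",
                 "n_points", "n_bins"):
        lines.append(f"{name} = {_toml_value(getattr(defaults, name))}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_config(path) -> tuple[AnalysisConfig, DefaultsConfig, dict[str, str]]:
    """Read a TOML config; raises ConfigError on any violated invariant."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    a = dict(doc.get("analysis", {}))
    groups = a.pop("groups_and_types", {})
    config = AnalysisConfig(groups_and_types=dict(groups), **a)
    d = dict(doc.get("defaults", {}))
    for key in ("variants", "plot_categories"):
        if key in d:
            d[key] = tuple(d[key])
    defaults = DefaultsConfig(**d)
    colors = dict(doc.get("plot", {}).get("group_colors", {}))
    errs = validate_config(config, defaults)
    if errs:
        raise ConfigError(errs)
    return config, defaults, colors


def override(config: AnalysisConfig, **kwargs) -> AnalysisConfig:
    """Functional update used by the CLI's per-flag overrides."""
    return replace(config, **{k: v for k, v in kwargs.items() if v is not None})
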