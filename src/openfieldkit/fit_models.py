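"""Parametric habituation-curve fitting with an outlier-robust two-pass scheme.

Individual relationships (e.g. activity vs. time) are first fit naively with
bounded nonlinear least squares, constrained only by each model form's
parameter signs.  The spread of the naive parameters across the individuals of
a group then defines a box (mean +/- ``bound_level`` * SD per parameter), and
every individual is refit inside that box.  Outliers are thereby pulled toward
the group's parameter distribution instead of being discarded.  Group-level
curves are fit to the binned group means under the same box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ModelForm",
    "FORMS",
    "register_form",
    "get_form",
    "FitResult",
    "ParameterBounds",
    "fit_individual_naive",
    "find_fit_bounds",
    "refit_individual",
    "fit_group",
    "fit_cohort",
    "format_params",
    "format_group_params",
]

PARAM_NAMES = ("a", "b", "c")

#: default solver settings; the optimiser is scipy's trust-region reflective
MAX_F_EVAL = 5000
_XTOL = 1e-10
_FTOL = 1e-10
_GTOL = 1e-10


@dataclass(frozen=True)
class ModelForm:
    """A registered functional form y = f(x; params).

    ``param_signs`` holds +1 (parameter constrained positive), -1 (negative)
    or 0 (unconstrained); they become the wide bounds of the naive fit.
    ``display_parts`` are the text fragments interleaved with fitted parameter
    values when rendering the fitted equation (arity + 1 fragments).
    """

    name: str
    arity: int
    func: Callable[..., np.ndarray]
    param_signs: tuple[int, ...]
    display_parts: tuple[str, ...]
    guess: Callable[[np.ndarray, np.ndarray], np.ndarray]

    def __post_init__(self) -> None:
        if len(self.param_signs) != self.arity:
            raise ValueError(f"{self.name}: {self.arity} signs expected")
        if len(self.display_parts) != self.arity + 1:
            raise ValueError(f"{self.name}: display_parts must have arity+1 entries")

    def sign_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([0.0 if s > 0 else -np.inf for s in self.param_signs])
        hi = np.array([0.0 if s < 0 else np.inf for s in self.param_signs])
        return lo, hi

    def __call__(self, x: np.ndarray, params: Sequence[float]) -> np.ndarray:
        return self.func(np.asarray(x, dtype=float), *params)


def _span(x: np.ndarray) -> float:
    s = float(np.max(x) - np.min(x))
    return s if s > 0 else 1.0


def _guess_exp_decay(x, y):
    c = max(float(np.min(y)), 1e-6)
    a = max(float(np.mean(y[: max(1, y.size // 10)]) - c), 1e-6)
    return np.array([a, -3.0 / _span(x), c])


def _guess_asymptotic(x, y):
    a = min(-float(np.max(y)) * 1.05, -1e-6)
    return np.array([a, -3.0 / _span(x)])


def _guess_lin_dec(x, y):
    rise = float(np.max(y) - np.min(y))
    return np.array([-max(rise, 1e-6) / _span(x), max(float(np.max(y)), 1e-6)])


def _guess_lin_inc(x, y):
    rise = float(np.max(y) - np.min(y))
    return np.array([max(rise, 1e-6) / _span(x), max(float(np.min(y)), 1e-6)])


def _guess_sig_decay(x, y):
    return np.array([max(float(np.max(y)), 1e-6), -4.0 / _span(x), -_span(x) / 2.0])


def _guess_sig_inc(x, y):
    return np.array([max(float(np.max(y)), 1e-6), 4.0 / _span(x), -_span(x) / 2.0])


FORMS: dict[str, ModelForm] = {}


def register_form(form: ModelForm) -> ModelForm:
    """Add a form to the registry (user-defined forms included)."""
    FORMS[form.name] = form
    return form


def get_form(name: str) -> ModelForm:
    try:
        return FORMS[name]
    except KeyError:
        raise KeyError(
            f"unknown model form {name!r}; registered: {sorted(FORMS)}"
        ) from None


register_form(ModelForm(
    name="exponential_decay",
    arity=3,
    func=lambda x, a, b, c: a * np.exp(b * x) + c,
    param_signs=(1, -1, 1),
    display_parts=("y = ", " e^(", " x) + ", ""),
    guess=_guess_exp_decay,
))
register_form(ModelForm(
    name="asymptotic_increase",
    arity=2,
    func=lambda x, a, b: a * (np.exp(b * x) - 1.0),
    param_signs=(-1, -1),
    display_parts=("y = ", " (e^(", " x) - 1)"),
    guess=_guess_asymptotic,
))
register_form(ModelForm(
    name="linear_decrease",
    arity=2,
    func=lambda x, a, b: a * x + b,
    param_signs=(-1, 1),
    display_parts=("y = ", " x + ", ""),
    guess=_guess_lin_dec,
))
register_form(ModelForm(
    name="linear_increase",
    arity=2,
    func=lambda x, a, b: a * x + b,
    param_signs=(1, 1),
    display_parts=("y = ", " x + ", ""),
    guess=_guess_lin_inc,
))
register_form(ModelForm(
    name="sigmoidal_decay",
    arity=3,
    func=lambda x, a, b, c: a / (1.0 + np.exp(-b * (x + c))),
    param_signs=(1, -1, -1),
    display_parts=("y = ", " / (1 + e^(-", " (x + ", ")))"),
    guess=_guess_sig_decay,
))
register_form(ModelForm(
    name="sigmoidal_increase",
    arity=3,
    func=lambda x, a, b, c: a / (1.0 + np.exp(-b * (x + c))),
    param_signs=(1, 1, -1),
    display_parts=("y = ", " / (1 + e^(-", " (x + ", ")))"),
    guess=_guess_sig_inc,
))


@dataclass
class FitResult:
    """Best-fit parameters for one (id, x-variable, y-variable, form)."""

    uid: str
    group: str
    x_var: str
    y_var: str
    form: str
    naive: np.ndarray | None = None
    refit: np.ndarray | None = None
    naive_converged: bool = False
    refit_converged: bool = False
    rss: float = math.nan


@dataclass
class ParameterBounds:
    """Per-parameter refit box: naive mean -/+ bound_level * SD, per group."""

    low: np.ndarray
    high: np.ndarray
    n_individuals: int = 0


def _clean_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def _solve(form: ModelForm, x, y, x0, lo, hi, max_f_eval=MAX_F_EVAL):
    x0 = np.clip(np.asarray(x0, dtype=float), lo, hi)
    # trf needs a feasible start; nudge off any boundary with a finite width
    width = np.where(np.isfinite(hi - lo), hi - lo, 1.0)
    eps = 1e-12 + 1e-9 * np.abs(x0)
    x0 = np.minimum(np.maximum(x0, lo + np.minimum(eps, width / 4)),
                    hi - np.minimum(eps, width / 4))

    def resid(p):
        return form(x, p) - y

    try:
        res = least_squares(
            resid, x0, bounds=(lo, hi), method="trf",
            max_nfev=max_f_eval, xtol=_XTOL, ftol=_FTOL, gtol=_GTOL,
        )
    except Exception:
        return None, False, math.nan
    ok = res.status > 0 and np.all(np.isfinite(res.x))
    return res.x, bool(ok), float(2.0 * res.cost)


def fit_individual_naive(x, y, form: ModelForm | str,
                         initial: Sequence[float] | None = None,
                         bounds: tuple | None = None,
                         max_f_eval: int = MAX_F_EVAL):
    """Naive bounded fit: sign constraints only (or user-supplied wide bounds).

    Returns ``(params, converged, rss)``; ``params`` is None when there are
    fewer than arity+1 finite points or the solver fails.
    """
    if isinstance(form, str):
        form = get_form(form)
    x, y = _clean_xy(x, y)
    if x.size < form.arity + 1:
        return None, False, math.nan
    lo, hi = bounds if bounds is not None else form.sign_bounds()
    x0 = np.asarray(initial, float) if initial is not None else form.guess(x, y)
    return _solve(form, x, y, x0, np.asarray(lo, float), np.asarray(hi, float),
                  max_f_eval)


def find_fit_bounds(naive_params: np.ndarray, bound_level: float = 2.0,
                    form: ModelForm | None = None) -> ParameterBounds:
    """Refit box from the converged naive parameters of one group.

    ``naive_params`` is (n_individuals, arity).  With one individual the box
    collapses to that value; a zero SD is epsilon-widened so the solver has an
    interior.  The box is intersected with the form's sign bounds when a form
    is given, preserving parameter interpretability.
    """
    p = np.asarray(naive_params, dtype=float)
    if p.ndim == 1:
        p = p[None, :]
    if p.shape[0] == 0:
        raise ValueError("no converged naive fits to derive bounds from")
    mean = p.mean(axis=0)
    sd = p.std(axis=0, ddof=1) if p.shape[0] > 1 else np.zeros(p.shape[1])
    sd = np.where(np.isfinite(sd), sd, 0.0)
    low = mean - bound_level * sd - 1e-12
    high = mean + bound_level * sd + 1e-12
    if form is not None:
        slo, shi = form.sign_bounds()
        low = np.maximum(low, slo)
        high = np.minimum(high, shi)
        bad = low > high
        low[bad] = high[bad] - 1e-12
    return ParameterBounds(low=low, high=high, n_individuals=p.shape[0])


def refit_individual(x, y, form: ModelForm | str, bounds: ParameterBounds,
                     naive: Sequence[float] | None = None,
                     max_f_eval: int = MAX_F_EVAL):
    """Constrained refit inside the group box.

    When the naive optimum already lies inside the box it is also the
    constrained optimum, so it is returned directly.
    """
    if isinstance(form, str):
        form = get_form(form)
    x, y = _clean_xy(x, y)
    if x.size < form.arity + 1:
        return None, False, math.nan
    if naive is not None:
        naive = np.asarray(naive, dtype=float)
        if np.all(naive >= bounds.low) and np.all(naive <= bounds.high):
            rss = float(np.sum((form(x, naive) - y) ** 2))
            return naive, True, rss
    x0 = naive if naive is not None else form.guess(x, y)
    return _solve(form, x, y, x0, bounds.low, bounds.high, max_f_eval)


def fit_group(x, y, form: ModelForm | str, bounds: ParameterBounds,
              initial: Sequence[float] | None = None,
              max_f_eval: int = MAX_F_EVAL):
    """Fit the group-averaged (binned) data inside the group box."""
    if isinstance(form, str):
        form = get_form(form)
    x, y = _clean_xy(x, y)
    if x.size < form.arity + 1:
        return None, False, math.nan
    x0 = initial if initial is not None else form.guess(x, y)
    return _solve(form, x, y, x0, bounds.low, bounds.high, max_f_eval)


# ---------------------------------------------------------------------------
# cohort-level orchestration


@dataclass
class CohortFits:
    """All fits for one dataset: per-individual results, group boxes, group fits."""

    individual: list[FitResult] = field(default_factory=list)
    bounds: dict[tuple, ParameterBounds] = field(default_factory=dict)
    group: list[FitResult] = field(default_factory=list)


def fit_cohort(xy_data: dict, specs: dict, groups: dict[str, str],
               bound_level: float = 2.0,
               group_xy: dict | None = None) -> CohortFits:
    """Run the naive -> bounds -> refit scheme over a whole dataset.

    Parameters
    ----------
    xy_data
        ``{(x_var, y_var): {uid: (x_array, y_array)}}`` per-individual data.
    specs
        ``{(x_var, y_var): ModelSpec-like}`` — anything with ``.model``,
        ``.initial_parameters`` and ``.max_f_eval`` attributes.
    groups
        ``{uid: group_label}``.
    group_xy
        Optional ``{(x_var, y_var): {group: (x, y)}}`` binned group means to
        fit with the group boxes.
    """
    out = CohortFits()
    for key, per_ind in xy_data.items():
        if key not in specs:
            continue
        spec = specs[key]
        form = get_form(spec.model)
        naive_by_group: dict[str, list[tuple[str, np.ndarray]]] = {}
        results: dict[str, FitResult] = {}
        for uid, (x, y) in per_ind.items():
            params, ok, rss = fit_individual_naive(
                x, y, form, initial=spec.initial_parameters,
                max_f_eval=spec.max_f_eval)
            g = groups[uid]
            fr = FitResult(uid=uid, group=g, x_var=key[0], y_var=key[1],
                           form=form.name, naive=params, naive_converged=ok,
                           rss=rss)
            results[uid] = fr
            if ok:
                naive_by_group.setdefault(g, []).append((uid, params))
        for g, pairs in naive_by_group.items():
            mat = np.array([p for _, p in pairs])
            b = find_fit_bounds(mat, bound_level, form=form)
            out.bounds[key + (g,)] = b
        for uid, fr in results.items():
            b = out.bounds.get(key + (fr.group,))
            if b is None or not fr.naive_converged:
                continue
            x, y = per_ind[uid]
            params, ok, rss = refit_individual(x, y, form, b, naive=fr.naive,
                                               max_f_eval=spec.max_f_eval)
            fr.refit, fr.refit_converged, fr.rss = params, ok, rss
        out.individual.extend(results.values())
        if group_xy and key in group_xy:
            for g, (gx, gy) in group_xy[key].items():
                b = out.bounds.get(key + (g,))
                if b is None:
                    continue
                params, ok, rss = fit_group(gx, gy, form, b,
                                            initial=spec.initial_parameters,
                                            max_f_eval=spec.max_f_eval)
                out.group.append(FitResult(
                    uid=g, group=g, x_var=key[0], y_var=key[1],
                    form=form.name, refit=params, refit_converged=ok, rss=rss))
    return out


def _long_rows(fits: list[FitResult]) -> pd.DataFrame:
    rows = []
    for fr in fits:
        form = get_form(fr.form)
        for j in range(form.arity):
            rows.append({
                "id": fr.uid, "group": fr.group, "x_var": fr.x_var,
                "y_var": fr.y_var, "form": fr.form,
                "param_name": PARAM_NAMES[j],
                "naive": float(fr.naive[j]) if fr.naive is not None else math.nan,
                "refit": float(fr.refit[j]) if fr.refit is not None else math.nan,
                "converged": bool(fr.refit_converged),
            })
    cols = ["id", "group", "x_var", "y_var", "form", "param_name",
            "naive", "refit", "converged"]
    return pd.DataFrame(rows, columns=cols)


def format_params(fits: CohortFits, path=None) -> pd.DataFrame:
    """Long-format individual parameter table; the bridge to external stats."""
    df = _long_rows(fits.individual)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def format_group_params(fits: CohortFits, path=None) -> pd.DataFrame:
    df = _long_rows(fits.group)
    if path is not None:
        df.to_csv(path, index=False)
    return df
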