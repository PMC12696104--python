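"""Split-population validation of the statistical ladder's type-I error.

A single simulated population is divided into two random halves; since both
halves come from the same population, any parameter flagged significant by
the sub-test -> ANOVA chain is a false positive.  Repeating the random split
many times estimates the chain's realized type-I rate, which should sit near
the nominal alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisConfig, DefaultsConfig, set_up_fits
from .fit_models import (fit_individual_naive, find_fit_bounds, get_form,
                         refit_individual)
from .pipeline import analyze_tracks, build_xy_dataset
from .stats import run_anovas, run_manova, wilks_p, SingularDataError
from .synthetic import ExplorerParams, make_cohort

__all__ = ["FprResult", "split_population_fpr"]


@dataclass
class FprResult:
    fractions: np.ndarray
    n_parameters: int
    n_replicates: int

    @property
    def mean_fraction(self) -> float:
        return float(self.fractions.mean())


def _default_config() -> AnalysisConfig:
    return AnalysisConfig(groups_and_types={"A": "generic", "B": "generic"},
                          arena_radius_cm=4.2, sample_freq=1.0,
                          edge_dist_cm=1.0, time_bin_size=1.0,
                          inactivity_threshold=0.05)


def split_population_fpr(n_individuals: int = 110, n_replicates: int = 100,
                         seed: int = 0, params: ExplorerParams | None = None,
                         config: AnalysisConfig | None = None,
                         defaults: DefaultsConfig | None = None,
                         alpha: float = 0.05,
                         between_individual_sd: float = 0.15) -> FprResult:
    """Estimate the chain's false-positive fraction over random splits.

    One cohort is simulated and naive-fit once; each replicate re-splits the
    same individuals into two equal groups, derives per-group refit bounds,
    refits, and runs the MANOVA sub-test -> ANOVA chain on the default grid.
    The returned fractions count parameters significant in *both* tests,
    divided by the total number of grid parameters.
    """
    import pandas as pd

    config = config or _default_config()
    defaults = defaults or DefaultsConfig()
    params = params or ExplorerParams(seed=seed)
    tracks, _ = make_cohort(n_individuals, params,
                            between_individual_sd=between_individual_sd,
                            seed=seed)
    result = analyze_tracks(tracks, config, defaults)
    specs = set_up_fits(config, defaults)
    xy = build_xy_dataset(result, specs)
    uids = [m.uid for m in result.all_members()]

    # one naive fit per (individual, relationship), reused by every split
    naive: dict[tuple, dict[str, np.ndarray]] = {}
    forms = {}
    for key, spec in specs.items():
        form = get_form(spec.model)
        forms[key] = form
        fits = {}
        for uid, (x, y) in xy[key].items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p, ok, _ = fit_individual_naive(x, y, form,
                                                initial=spec.initial_parameters,
                                                max_f_eval=spec.max_f_eval)
            if ok:
                fits[uid] = p
        naive[key] = fits
    n_params_total = sum(forms[k].arity for k in specs)

    rng = np.random.default_rng(seed + 1)
    half = n_individuals // 2
    fractions = np.empty(n_replicates)
    for rep in range(n_replicates):
        perm = rng.permutation(uids)
        group_of = {uid: ("A" if i < half else "B")
                    for i, uid in enumerate(perm)}
        cols: dict[str, dict[str, float]] = {}
        relationships: dict[tuple, list[str]] = {}
        for key in specs:
            form = forms[key]
            fits = naive[key]
            refit_params: dict[str, np.ndarray] = {}
            for g in ("A", "B"):
                members = [u for u in fits if group_of[u] == g]
                if len(members) < 2:
                    continue
                mat = np.array([fits[u] for u in members])
                bounds = find_fit_bounds(mat, config.bound_level, form=form)
                for u in members:
                    x, y = xy[key][u]
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        p, ok, _ = refit_individual(x, y, form, bounds,
                                                    naive=fits[u])
                    if ok:
                        refit_params[u] = p
            pnames = [f"{key[0]}__{key[1]}__{j}" for j in range(form.arity)]
            relationships[key] = pnames
            for j, name in enumerate(pnames):
                cols[name] = {u: float(p[j]) for u, p in refit_params.items()}
        matrix = pd.DataFrame({name: pd.Series(v) for name, v in cols.items()})
        matrix.insert(0, "group", pd.Series({u: group_of[u] for u in uids}))
        matrix.insert(0, "id", matrix.index)
        matrix = matrix.reset_index(drop=True)

        n_sig = 0
        anova_table = run_anovas(matrix,
                                 [p for ps in relationships.values() for p in ps])
        for key, pnames in relationships.items():
            pnames = [p for p in pnames if p in matrix.columns]
            if not pnames:
                continue
            try:
                sub_p = wilks_p(run_manova(matrix, pnames))
            except (SingularDataError, ValueError):
                continue
            if not (np.isfinite(sub_p) and sub_p < alpha):
                continue
            for p in pnames:
                a_p = anova_table.loc[p, "PR(>F)"]
                if np.isfinite(a_p) and a_p < alpha:
                    n_sig += 1
        fractions[rep] = n_sig / n_params_total
    return FprResult(fractions=fractions, n_parameters=n_params_total,
                     n_replicates=n_replicates)
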