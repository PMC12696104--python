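"""Group comparison on fitted model parameters: MANOVA -> ANOVA -> pairwise t.

Every refit parameter of every individual is a dependent variable and the
experimental group is the independent variable.  The ladder runs:

1. a full one-way MANOVA over all parameters (when the data support it);
2. per-relationship MANOVA *sub-tests* over the 2-3 parameters of each
   (x, y) fit — the pragmatic alternative when n is small relative to the
   number of parameters;
3. one-way ANOVA per parameter;
4. pairwise two-sided t-tests per parameter, with Holm-Sidak adjusted
   p-values (column ``pvalue-hs``) and the mean difference as ``coef``.

Interpretation follows the significance chain: a parameter effect counts as
significant only when its relationship's sub-test AND its own ANOVA fall
below alpha.  Computation is never gated — all tables are always produced.
"""

from __future__ import annotations

import io
import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.multivariate.manova import MANOVA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatReport",
    "run_manova",
    "run_subtests",
    "run_anovas",
    "pairwise_ttests",
    "run_tests",
    "parameter_matrix",
]


class SingularDataError(RuntimeError):
    """Within-group covariance is singular; try the per-relationship sub-tests."""


def parameter_matrix(param_df: pd.DataFrame, value_col: str = "refit") -> pd.DataFrame:
    """Long fit table -> wide (individual x parameter) matrix with a group column.

    Parameter columns are named ``<x>__<y>__<name>``.  Only converged fits
    contribute; missing entries are NaN.
    """
    df = param_df[param_df["converged"]].copy()
    df["param"] = (df["x_var"].astype(str) + "__" + df["y_var"].astype(str)
                   + "__" + df["param_name"].astype(str))
    wide = df.pivot_table(index="id", columns="param", values=value_col,
                          aggfunc="first")
    groups = param_df.drop_duplicates("id").set_index("id")["group"]
    wide.insert(0, "group", groups.reindex(wide.index))
    return wide.reset_index()


def _complete_cases(matrix: pd.DataFrame, params: list[str]) -> pd.DataFrame:
    sub = matrix[["id", "group"] + params].dropna()
    return sub


def run_manova(matrix: pd.DataFrame, params: list[str]) -> pd.DataFrame:
    """One-way MANOVA on the given parameter columns.

    Returns the statistic table for the group effect (Wilks' lambda with its
    Rao F approximation, plus Pillai's trace), columns Value, Num DF, Den DF,
    F Value, Pr > F.  Raises :class:`SingularDataError` when the within-group
    covariance cannot support the test.
    """
    sub = _complete_cases(matrix, params)
    groups = sub["group"].unique()
    if len(groups) < 2:
        raise ValueError("MANOVA needs at least 2 groups with data")
    smallest = sub.groupby("group").size().min()
    if smallest <= len(params):
        raise SingularDataError(
            f"group size {smallest} too small for {len(params)} parameters; "
            "consider the per-relationship sub-tests")
    endog = sub[params].to_numpy(dtype=float)
    if np.any(np.nanstd(endog, axis=0) == 0):
        raise SingularDataError("a parameter is constant across individuals")
    if len(params) == 1:
        # with one dependent variable Wilks' test reduces to one-way ANOVA
        samples = [g[params[0]].to_numpy(dtype=float)
                   for _, g in sub.groupby("group")]
        F, pval = sps.f_oneway(*samples)
        n = len(sub)
        k = len(groups)
        lam = 1.0 / (1.0 + F * (k - 1) / (n - k))
        return pd.DataFrame(
            {"Value": [lam], "Num DF": [float(k - 1)],
             "Den DF": [float(n - k)], "F Value": [float(F)],
             "Pr > F": [float(pval)]},
            index=pd.Index(["Wilks' lambda"], name="statistic"))
    exog = pd.get_dummies(sub["group"], drop_first=True, dtype=float)
    exog.insert(0, "Intercept", 1.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mv = MANOVA(endog, exog.to_numpy())
            contrast = np.hstack([np.zeros((len(groups) - 1, 1)),
                                  np.eye(len(groups) - 1)])
            res = mv.mv_test(hypotheses=[("group", contrast)])
    except Exception as exc:
        raise SingularDataError(str(exc)) from exc
    table = res.results["group"]["stat"].copy()
    table.index.name = "statistic"
    return table


def wilks_p(table: pd.DataFrame) -> float:
    """Pr > F of the Wilks' lambda row of a MANOVA statistic table."""
    return float(table.loc["Wilks' lambda", "Pr > F"])


def run_subtests(matrix: pd.DataFrame,
                 relationships: dict[tuple[str, str], list[str]]):
    """MANOVA restricted to each relationship's parameters.

    Returns ``{(x, y): (table_or_None, p_value_or_NaN)}``; a relationship
    with too little data yields (None, NaN), mirroring reports that print NA
    when a test cannot be run.
    """
    out = {}
    for key, params in relationships.items():
        params = [p for p in params if p in matrix.columns]
        if not params:
            out[key] = (None, np.nan)
            continue
        try:
            table = run_manova(matrix, params)
            out[key] = (table, wilks_p(table))
        except (SingularDataError, ValueError):
            out[key] = (None, np.nan)
    return out


def run_anovas(matrix: pd.DataFrame, params: list[str]) -> pd.DataFrame:
    """One-way ANOVA per parameter; columns F and PR(>F) (NaN when untestable)."""
    rows = []
    for p in params:
        sub = matrix[["group", p]].dropna()
        samples = [g[p].to_numpy(dtype=float)
                   for _, g in sub.groupby("group") if len(g) > 0]
        if len(samples) < 2 or sum(len(s) for s in samples) <= len(samples):
            rows.append({"parameter": p, "F": np.nan, "PR(>F)": np.nan})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                F, pval = sps.f_oneway(*samples)
            except Exception:
                F, pval = np.nan, np.nan
        rows.append({"parameter": p, "F": float(F), "PR(>F)": float(pval)})
    return pd.DataFrame(rows).set_index("parameter")


def pairwise_ttests(matrix: pd.DataFrame, param: str,
                    welch: bool = False) -> pd.DataFrame:
    """All group pairs for one parameter.

    ``coef`` is mean(A) - mean(B); ``pvalue-hs`` is the Holm-Sidak adjusted
    two-sided p-value across the pairs of this parameter.
    """
    sub = matrix[["group", param]].dropna()
    groups = sorted(sub["group"].unique())
    rows = []
    raw_p = []
    for a, b in itertools.combinations(groups, 2):
        va = sub.loc[sub["group"] == a, param].to_numpy(dtype=float)
        vb = sub.loc[sub["group"] == b, param].to_numpy(dtype=float)
        if len(va) < 2 or len(vb) < 2:
            rows.append({"group_a": a, "group_b": b, "coef": np.nan,
                         "t": np.nan, "pvalue": np.nan})
            raw_p.append(np.nan)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, p = sps.ttest_ind(va, vb, equal_var=not welch)
        rows.append({"group_a": a, "group_b": b,
                     "coef": float(va.mean() - vb.mean()),
                     "t": float(t), "pvalue": float(p)})
        raw_p.append(float(p))
    df = pd.DataFrame(rows)
    adj = np.full(len(raw_p), np.nan)
    ok = np.isfinite(raw_p)
    if ok.any():
        adj[ok] = multipletests(np.asarray(raw_p)[ok], method="holm-sidak")[1]
    df["pvalue-hs"] = adj
    return df


@dataclass
class StatReport:
    """All tables from one run of the ladder, plus the significance chain."""

    full_manova: pd.DataFrame | None
    subtests: dict
    anovas: pd.DataFrame
    pairwise: dict[str, pd.DataFrame]
    significant: dict[str, bool] = field(default_factory=dict)
    alpha: float = 0.05
    notes: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        buf = io.StringIO()
        w = buf.write
        w("Group comparison report (alpha = %g)\n" % self.alpha)
        w("=" * 60 + "\n\n")
        for note in self.notes:
            w(f"note: {note}\n")
        if self.notes:
            w("\n")
        w("Full MANOVA (all parameters)\n" + "-" * 40 + "\n")
        if self.full_manova is None:
            w("not testable with the available data\n")
        else:
            w(self.full_manova.to_string() + "\n")
        w("\nMANOVA sub-tests (per relationship)\n" + "-" * 40 + "\n")
        for key, (table, p) in self.subtests.items():
            w(f"\n[{key[0]} vs {key[1]}]  Pr > F = "
              + ("NA" if not np.isfinite(p) else f"{p:.4g}") + "\n")
            if table is not None:
                w(table.to_string() + "\n")
        w("\nPer-parameter ANOVA\n" + "-" * 40 + "\n")
        w(self.anovas.to_string() + "\n")
        w("\nPairwise t-tests (Holm-Sidak adjusted)\n" + "-" * 40 + "\n")
        for p, df in self.pairwise.items():
            w(f"\n[{p}]\n" + df.to_string(index=False) + "\n")
        w("\nSignificance chain (sub-test AND ANOVA < alpha)\n" + "-" * 40 + "\n")
        if not self.significant:
            w("nothing testable\n")
        for p, flag in self.significant.items():
            w(f"{p}: {'SIGNIFICANT' if flag else 'ns'}\n")
        return buf.getvalue()


def run_tests(param_df: pd.DataFrame, alpha: float = 0.05,
              report_path=None, csv_dir=None, welch: bool = False) -> StatReport:
    """Run the full ladder on a long-format individual parameter table."""
    if param_df.empty or not param_df["converged"].any():
        report = StatReport(full_manova=None, subtests={},
                            anovas=pd.DataFrame(columns=["F", "PR(>F)"]),
                            pairwise={}, alpha=alpha,
                            notes=["no converged parameters: nothing testable"])
        if report_path is not None:
            with open(report_path, "w") as fh:
                fh.write(report.to_text())
        return report
    matrix = parameter_matrix(param_df)
    params = [c for c in matrix.columns if c not in ("id", "group")]
    relationships: dict[tuple[str, str], list[str]] = {}
    for p in params:
        x, y, _ = p.rsplit("__", 2)
        relationships.setdefault((x, y), []).append(p)
    notes = []
    try:
        full = run_manova(matrix, params)
    except (SingularDataError, ValueError) as exc:
        full = None
        notes.append(f"full MANOVA skipped: {exc}")
    subtests = run_subtests(matrix, relationships)
    anovas = run_anovas(matrix, params)
    pairwise = {p: pairwise_ttests(matrix, p, welch=welch) for p in params}
    significant = {}
    for (x, y), plist in relationships.items():
        _, sub_p = subtests[(x, y)]
        for p in plist:
            a_p = anovas.loc[p, "PR(>F)"] if p in anovas.index else np.nan
            significant[p] = bool(np.isfinite(sub_p) and sub_p < alpha
                                  and np.isfinite(a_p) and a_p < alpha)
    report = StatReport(full_manova=full, subtests=subtests, anovas=anovas,
                        pairwise=pairwise, significant=significant,
                        alpha=alpha, notes=notes)
    if report_path is not None:
        with open(report_path, "w") as fh:
            fh.write(report.to_text())
    if csv_dir is not None:
        from pathlib import Path
        d = Path(csv_dir)
        d.mkdir(parents=True, exist_ok=True)
        if full is not None:
            full.to_csv(d / "manova_full.csv")
        sub_rows = [{"x_var": k[0], "y_var": k[1], "pr_gt_f": p}
                    for k, (_, p) in subtests.items()]
        pd.DataFrame(sub_rows).to_csv(d / "manova_subtests.csv", index=False)
        anovas.to_csv(d / "anova.csv")
        if pairwise:
            pd.concat(pairwise, names=["parameter"]).reset_index(0).to_csv(
                d / "pairwise_t.csv", index=False)
    return report
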