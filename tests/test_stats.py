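import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from openfieldkit.stats import (SingularDataError, pairwise_ttests,
                                parameter_matrix, run_anovas, run_manova,
                                run_subtests, run_tests, wilks_p)


def gaussian_matrix(n_per_group=20, n_params=3, shift=None, seed=0,
                    groups=("A", "B")):
    rng = np.random.default_rng(seed)
    frames = []
    for gi, g in enumerate(groups):
        vals = rng.normal(size=(n_per_group, n_params))
        if shift is not None and gi == 1:
            vals[:, 0] += shift
        df = pd.DataFrame(vals, columns=[f"p{j}" for j in range(n_params)])
        df.insert(0, "group", g)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "id", [f"i{k}" for k in range(len(out))])
    return out


class TestManova:
    def test_determinism(self):
        m = gaussian_matrix()
        t1 = run_manova(m, ["p0", "p1", "p2"])
        t2 = run_manova(m, ["p0", "p1", "p2"])
        pd.testing.assert_frame_equal(t1, t2)

    def test_single_parameter_equals_anova_equals_squared_t(self):
        m = gaussian_matrix(n_params=1, seed=3)
        p_manova = wilks_p(run_manova(m, ["p0"]))
        anova = run_anovas(m, ["p0"])
        a = m.loc[m.group == "A", "p0"]
        b = m.loc[m.group == "B", "p0"]
        t, p_t = sps.ttest_ind(a, b)
        assert p_manova == pytest.approx(p_t, abs=1e-9)
        assert anova.loc["p0", "PR(>F)"] == pytest.approx(p_t, abs=1e-9)
        assert anova.loc["p0", "F"] == pytest.approx(t ** 2, abs=1e-9)

    def test_strong_shift_detected(self):
        rejections = 0
        for seed in range(40):
            m = gaussian_matrix(n_per_group=30, shift=3.0, seed=seed)
            if wilks_p(run_manova(m, ["p0", "p1", "p2"])) < 0.05:
                rejections += 1
        assert rejections >= 38  # power ~1 at a 3 SD mean shift

    def test_null_rejection_rate_near_alpha(self):
        pvals = [wilks_p(run_manova(gaussian_matrix(seed=s),
                                    ["p0", "p1", "p2"]))
                 for s in range(200)]
        rate = np.mean(np.array(pvals) < 0.05)
        # binomial 95% band around 0.05 at 200 replicates
        assert 0.01 <= rate <= 0.10

    def test_too_small_groups_raise_singular(self):
        m = gaussian_matrix(n_per_group=3)
        with pytest.raises(SingularDataError):
            run_manova(m, ["p0", "p1", "p2"])

    def test_constant_parameter_raises(self):
        m = gaussian_matrix()
        m["p0"] = 1.0
        with pytest.raises(SingularDataError):
            run_manova(m, ["p0", "p1"])


class TestSubtests:
    def test_one_table_per_relationship(self):
        m = gaussian_matrix(n_params=4)
        rel = {("time", "activity"): ["p0", "p1", "p2"],
               ("time", "coverage"): ["p3"]}
        out = run_subtests(m, rel)
        assert set(out) == set(rel)
        for table, p in out.values():
            assert table is not None and np.isfinite(p)

    def test_untestable_relationship_reports_na(self):
        m = gaussian_matrix(n_per_group=3, n_params=3)
        out = run_subtests(m, {("x", "y"): ["p0", "p1", "p2"]})
        table, p = out[("x", "y")]
        assert table is None and np.isnan(p)


class TestAnova:
    def test_textbook_two_group_f(self):
        m = pd.DataFrame({"id": list("abcdef"),
                          "group": ["A"] * 3 + ["B"] * 3,
                          "p": [1.0, 2, 3, 4, 5, 6]})
        out = run_anovas(m, ["p"])
        assert out.loc["p", "F"] == pytest.approx(13.5)

    def test_identical_groups_f_zero(self):
        m = pd.DataFrame({"id": list("abcdef"),
                          "group": ["A"] * 3 + ["B"] * 3,
                          "p": [1.0, 2, 3, 1, 2, 3]})
        out = run_anovas(m, ["p"])
        assert out.loc["p", "F"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["p", "PR(>F)"] == pytest.approx(1.0)


class TestPairwise:
    def test_identical_groups_zero_coef(self):
        m = pd.DataFrame({"id": list("abcd"), "group": ["A", "A", "B", "B"],
                          "p": [1.0, 2.0, 1.0, 2.0]})
        out = pairwise_ttests(m, "p")
        assert out["coef"][0] == pytest.approx(0.0)

    def test_separated_groups(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame({"id": [f"i{k}" for k in range(8)],
                          "group": ["A"] * 4 + ["B"] * 4,
                          "p": np.r_[rng.normal(0, 1e-3, 4),
                                     1 + rng.normal(0, 1e-3, 4)]})
        out = pairwise_ttests(m, "p")
        assert out["coef"][0] == pytest.approx(-1.0, abs=0.01)
        assert out["pvalue-hs"][0] < 1e-6

    def test_three_groups_three_pairs_adjustment_monotone(self):
        m = gaussian_matrix(groups=("A", "B", "C"), n_params=1, seed=5)
        out = pairwise_ttests(m, "p0")
        assert len(out) == 3
        assert (out["pvalue-hs"] >= out["pvalue"] - 1e-12).all()

    def test_tiny_group_gives_na_pair(self):
        m = pd.DataFrame({"id": list("abc"), "group": ["A", "A", "B"],
                          "p": [1.0, 2.0, 3.0]})
        out = pairwise_ttests(m, "p")
        assert np.isnan(out["pvalue"][0])


def _param_df(seed=0, shift=0.0):
    """Long-format fit table for two groups, two relationships."""
    rng = np.random.default_rng(seed)
    rows = []
    for g, n in (("A", 15), ("B", 15)):
        for i in range(n):
            uid = f"{g}{i}"
            for (x, y, form, arity) in (
                    ("time", "activity", "exponential_decay", 3),
                    ("time", "coverage", "asymptotic_increase", 2)):
                for j, pname in enumerate("abc"[:arity]):
                    val = rng.normal()
                    if g == "B" and y == "activity" and pname == "a":
                        val += shift
                    rows.append({"id": uid, "group": g, "x_var": x,
                                 "y_var": y, "form": form,
                                 "param_name": pname, "naive": val,
                                 "refit": val, "converged": True})
    return pd.DataFrame(rows)


class TestRunTests:
    def test_report_structure(self, tmp_path):
        report = run_tests(_param_df(), report_path=tmp_path / "r.txt",
                           csv_dir=tmp_path / "tables")
        text = (tmp_path / "r.txt").read_text()
        assert "Full MANOVA" in text and "sub-tests" in text
        assert "Pr > F" in text and "PR(>F)" in text and "pvalue-hs" in text
        assert (tmp_path / "tables" / "anova.csv").exists()
        assert len(report.significant) == 5

    def test_report_deterministic(self, tmp_path):
        a = run_tests(_param_df()).to_text()
        b = run_tests(_param_df()).to_text()
        assert a == b

    def test_empty_parameter_set(self, tmp_path):
        df = _param_df().iloc[0:0]
        report = run_tests(df, report_path=tmp_path / "r.txt")
        assert "nothing testable" in (tmp_path / "r.txt").read_text()
        assert report.significant == {}

    def test_shifted_parameter_flagged_through_chain(self):
        report = run_tests(_param_df(seed=1, shift=2.5))
        assert report.significant["time__activity__a"]
        assert not report.significant["time__coverage__a"]

    def test_chain_gates_interpretation_not_computation(self):
        report = run_tests(_param_df(seed=2))
        # ANOVA rows exist for every parameter even when sub-tests are null
        assert len(report.anovas) == 5
        assert len(report.pairwise) == 5


class TestChainTypeIError:
    def test_null_chain_rate_near_alpha(self):
        """Split-identical populations: the sub-test -> ANOVA chain flags
        about alpha of parameters (parameter-level Gaussian simulation)."""
        fractions = []
        for seed in range(200):
            df = _param_df(seed=seed)
            matrix = parameter_matrix(df)
            rel = {("time", "activity"): ["time__activity__a",
                                          "time__activity__b",
                                          "time__activity__c"],
                   ("time", "coverage"): ["time__coverage__a",
                                          "time__coverage__b"]}
            sub = run_subtests(matrix, rel)
            anova = run_anovas(matrix, [p for ps in rel.values() for p in ps])
            n_sig = 0
            for key, ps in rel.items():
                _, sp = sub[key]
                if not (np.isfinite(sp) and sp < 0.05):
                    continue
                for p in ps:
                    ap = anova.loc[p, "PR(>F)"]
                    if np.isfinite(ap) and ap < 0.05:
                        n_sig += 1
            fractions.append(n_sig / 5)
        mean = float(np.mean(fractions))
        # the chain is slightly conservative relative to alpha = 0.05
        assert 0.005 <= mean <= 0.09
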