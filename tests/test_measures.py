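import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from openfieldkit.config import CoverageAsymptoteSpec
from openfieldkit.measures import (OUTCOMES, activity, cartesian_to_polar,
                                   classify_transitions, coverage,
                                   coverage_series,
                                   individual_coverage_asymptote,
                                   individual_probability_series,
                                   locate_sector_visits, motion_probabilities,
                                   percent_coverage, pgca, pica,
                                   polar_to_cartesian, turning_angle,
                                   visit_matrix)


class TestActivity:
    def test_three_four_five_triangle(self, track_factory):
        tr = track_factory([0, 3], [0, 4])
        assert activity(tr).raw.tolist() == [5.0]

    def test_stationary_track_all_zero(self, track_factory):
        tr = track_factory([1] * 5, [2] * 5)
        assert activity(tr).raw.tolist() == [0.0] * 4

    def test_matches_per_pair_brute_force(self, track_factory):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, 100))
        tr = track_factory(x, y)
        expected = [np.sqrt((x[i + 1] - x[i]) ** 2 + (y[i + 1] - y[i]) ** 2)
                    for i in range(99)]
        np.testing.assert_allclose(activity(tr).raw, expected, rtol=1e-12)

    def test_threshold_monotonicity(self, track_factory):
        rng = np.random.default_rng(2)
        tr = track_factory(rng.normal(size=60) * 0.1,
                           rng.normal(size=60) * 0.1)
        nonzero = [np.count_nonzero(activity(tr, th).thresholded)
                   for th in (0.0, 0.05, 0.1, 0.2)]
        assert nonzero == sorted(nonzero, reverse=True)


class TestPolar:
    @pytest.mark.parametrize("xy,expected", [
        ((0.0, 2.0), (2.0, 90.0)),
        ((-1.0, 0.0), (1.0, 180.0)),
        ((0.0, 0.0), (0.0, 0.0)),
    ])
    def test_known_points(self, xy, expected):
        r, th = cartesian_to_polar(*xy)
        assert (float(r), float(th)) == pytest.approx(expected)

    @given(st.floats(-10, 10), st.floats(-10, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip(self, x, y):
        r, th = cartesian_to_polar(x, y)
        x2, y2 = polar_to_cartesian(r, th)
        assert abs(x - x2) < 1e-9 and abs(y - y2) < 1e-9


class TestSectorVisits:
    def test_lingering_counts_once(self, track_factory):
        tr = track_factory([4.0] * 10, [0.1] * 10)
        _, counts = locate_sector_visits(tr, 15.0, 1.0)
        assert counts.sum() == 1 and counts[0] == 1

    def test_skipped_sectors_on_shorter_arc_credited(self, track_factory):
        # jump from sector 1 to sector 4 (counterclockwise shorter):
        # sectors 2 and 3 imputed
        node = 15.0
        angles = [7.5, 52.5]  # centers of sectors 1 and 4
        x, y = polar_to_cartesian([4.0, 4.0], angles)
        tr = track_factory(x, y)
        _, counts = locate_sector_visits(tr, node, 1.0)
        assert counts[:4].tolist() == [1, 1, 1, 1]
        assert counts.sum() == 4

    def test_clockwise_shorter_arc(self, track_factory):
        x, y = polar_to_cartesian([4.0, 4.0], [7.5, 322.5])
        tr = track_factory(x, y)
        _, counts = locate_sector_visits(tr, 15.0, 1.0)
        # sector 1 -> sector 22 going clockwise through 24 and 23
        assert counts[0] == 1 and counts[23] == 1 and counts[22] == 1 \
            and counts[21] == 1
        assert counts.sum() == 4

    def test_radial_dip_same_sector_is_same_visit(self, track_factory):
        # leave the band radially, come back in the same sector: one visit
        x, y = polar_to_cartesian([4.0, 2.0, 4.0], [7.5, 7.5, 7.5])
        tr = track_factory(x, y)
        _, counts = locate_sector_visits(tr, 15.0, 1.0)
        assert counts.sum() == 1

    def test_out_of_band_samples_ignored(self, track_factory):
        tr = track_factory([0.1, 0.2, 0.1], [0.0, 0.1, 0.0])
        _, counts = locate_sector_visits(tr, 15.0, 1.0)
        assert counts.sum() == 0

    def test_visit_matrix_is_cumulative(self, track_factory):
        x, y = polar_to_cartesian([4.0] * 3, [7.5, 22.5, 7.5])
        tr = track_factory(x, y)
        events, counts = locate_sector_visits(tr, 15.0, 1.0)
        v = visit_matrix(events, 24, 3)
        assert v[:, -1].tolist() == counts.tolist()
        assert (np.diff(v, axis=1) >= 0).all()

    def test_brute_force_entry_count_oracle(self, track_factory):
        # random in-band walk, coarse sectors, no skipping: entry events
        # recomputed independently from the sector sequence
        rng = np.random.default_rng(7)
        th = np.cumsum(rng.uniform(-10, 10, size=80)) % 360.0
        x, y = polar_to_cartesian(np.full(80, 4.0), th)
        tr = track_factory(x, y)
        node = 30.0
        _, counts = locate_sector_visits(tr, node, 1.0)
        sec = (th // node).astype(int)
        expected = np.zeros(12, dtype=int)
        expected[sec[0]] += 1
        for a, b in zip(sec[:-1], sec[1:]):
            if a == b:
                continue
            d = (b - a) % 12 if (b - a) % 12 <= (a - b) % 12 else -((a - b) % 12)
            step = 1 if d > 0 else -1
            for k in range(1, abs(d) + 1):
                expected[(a + step * k) % 12] += 1
        assert counts.tolist() == expected.tolist()


class TestCoverage:
    @pytest.mark.parametrize("counts,expected", [
        ([5] * 21 + [4] * 3, 4.875),          # prints as 4.88
        ([3] * 13 + [2] * 11, 2 + 13 / 24),   # prints as 2.54
        ([3] * 24, 3.0),
        ([4] * 6 + [3] * 18, 3.25),
    ])
    def test_worked_examples(self, counts, expected):
        assert coverage(np.array(counts)) == pytest.approx(expected, abs=1e-12)

    def test_bracketing_and_monotonicity(self, track_factory):
        rng = np.random.default_rng(3)
        th = np.cumsum(rng.uniform(-25, 40, size=200)) % 360
        x, y = polar_to_cartesian(np.full(200, 4.0), th)
        tr = track_factory(x, y)
        events, _ = locate_sector_visits(tr, 15.0, 1.0)
        C = coverage_series(events, 24, tr.t, tr.t)
        v = visit_matrix(events, 24, 200)
        vmin = v.min(axis=0)
        assert (C >= vmin).all() and (C < vmin + 1).all()
        assert (np.diff(C) >= -1e-12).all()

    def test_rotation_invariance(self, track_factory):
        rng = np.random.default_rng(8)
        th = np.cumsum(rng.uniform(-20, 30, size=150)) % 360
        r = np.full(150, 4.0)
        node = 15.0
        base = None
        for rot in (0.0, node, 4 * node):
            x, y = polar_to_cartesian(r, (th + rot) % 360)
            events, _ = locate_sector_visits(track_factory(x, y), node, 1.0)
            C = coverage_series(events, 24, np.arange(150.0), np.arange(150.0))
            if base is None:
                base = C
            else:
                np.testing.assert_allclose(C, base, atol=1e-12)


class TestPercentAndRescalings:
    def test_simple_series(self):
        np.testing.assert_allclose(percent_coverage([1, 2, 4]),
                                   [0.25, 0.5, 1.0])

    def test_constant_nonzero_gives_ones(self):
        np.testing.assert_allclose(percent_coverage([3.0, 3.0]), 1.0)

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            out = percent_coverage([0.0, 0.0])
        assert out.tolist() == [0.0, 0.0]

    def test_monotone_in_monotone_out(self):
        rng = np.random.default_rng(5)
        C = np.cumsum(rng.uniform(0, 1, 50))
        assert (np.diff(percent_coverage(C)) >= 0).all()

    def test_pica_pgca_scaling(self):
        C = np.array([0.0, 3.5, 7.0])
        np.testing.assert_allclose(pica(C, 7.0), [0, 0.5, 1.0])
        np.testing.assert_allclose(pgca(C, 7.0), pica(C, 7.0))
        assert pica(C, None) is None


class TestCoverageAsymptote:
    def test_exact_model_recovery(self):
        t = np.arange(0.0, 600.0)
        C = -7.0 * (np.exp(-0.005 * t) - 1.0)
        A = individual_coverage_asymptote(t, C, CoverageAsymptoteSpec())
        assert A == pytest.approx(7.0, abs=1e-6)

    def test_fly_like_regime_approaches_seven_visits(self):
        # cohort built to mimic edge-dwelling subjects that approach about
        # seven visits to each boundary segment
        from openfieldkit.synthetic import ExplorerParams, make_cohort
        tracks, _ = make_cohort(8, ExplorerParams(a0=2.2, c0=0.1, seed=0),
                                between_individual_sd=0.1, seed=7)
        As = []
        for tr in tracks:
            events, _ = locate_sector_visits(tr, 0.1, 1.0)
            C = coverage_series(events, 3600, tr.t, tr.t)
            A = individual_coverage_asymptote(tr.t, C)
            if A is not None:
                As.append(A)
        assert len(As) >= 6
        assert np.mean(As) == pytest.approx(7.0, abs=1.5)

    def test_asymptote_at_least_max_coverage(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            a = rng.uniform(3, 9)
            b = rng.uniform(0.002, 0.01)
            t = np.arange(0.0, 600.0)
            C = a * (1 - np.exp(-b * t)) + rng.normal(0, 0.02, t.size)
            A = individual_coverage_asymptote(t, C)
            assert A is not None and A >= C.max() - 0.2

    def test_too_few_samples_warns_and_returns_none(self):
        with pytest.warns(UserWarning):
            assert individual_coverage_asymptote([0, 1, 2], [0, 1, 1]) is None


class TestTurningAngle:
    @pytest.mark.parametrize("pts,expected", [
        (((0, 0), (1, 0), (2, 0)), 0.0),      # straight ahead
        (((0, 0), (1, 0), (0, 0)), 180.0),    # full reversal
        (((0, 0), (1, 0), (1, 1)), 90.0),     # right angle: still positive
    ])
    def test_known_geometries(self, pts, expected):
        assert turning_angle(*pts) == pytest.approx(expected, abs=1e-9)

    def test_undefined_when_step_is_zero(self):
        assert turning_angle((0, 0), (0, 0), (1, 0)) is None

    def test_threshold_makes_small_steps_undefined(self):
        assert turning_angle((0, 0), (0.01, 0), (1, 0), threshold=0.05) is None


class TestClassifyTransitions:
    def test_straight_mover_is_all_pp(self, track_factory):
        tr = track_factory(np.arange(8.0), np.zeros(8), radius=100.0)
        ta = classify_transitions(tr, activity(tr))
        assert (ta.codes == 0).all()

    def test_move_pause_pause_move_sequence(self, track_factory):
        x = [0.0, 1.0, 1.0, 1.0, 2.0]
        tr = track_factory(x, [0.0] * 5, radius=100.0)
        ta = classify_transitions(tr, activity(tr))
        assert [OUTCOMES[c] for c in ta.codes] == ["p0", "00", "0p"]

    def test_exactly_one_outcome_per_in_band_decision(self, track_factory):
        rng = np.random.default_rng(11)
        steps = rng.choice([0.0, 0.5], size=99, p=[0.3, 0.7])
        ang = np.cumsum(rng.uniform(-2, 2, 99))
        x = np.concatenate([[0], np.cumsum(steps * np.cos(ang))])
        y = np.concatenate([[0], np.cumsum(steps * np.sin(ang))])
        tr = track_factory(x, y, radius=1000.0)
        ta = classify_transitions(tr, activity(tr))
        assert (ta.codes >= 0).all()

    def test_out_of_band_decisions_missing(self, track_factory):
        tr = track_factory(np.linspace(0, 1, 6), np.zeros(6), radius=4.2)
        ta = classify_transitions(tr, activity(tr), edge_dist_cm=1.0)
        assert (ta.codes == -1).all()


class TestMotionProbabilities:
    def _group(self, codes_list, track_factory):
        # craft TransitionArrays directly
        from openfieldkit.measures import TransitionArrays
        out = []
        for codes in codes_list:
            codes = np.asarray(codes, dtype=np.int8)
            out.append(TransitionArrays(
                times=np.arange(len(codes), dtype=float), codes=codes,
                theta=np.zeros(len(codes)), in_edge=codes >= 0))
        return out

    def test_worked_four_individual_example(self, track_factory):
        # outcomes {++, ++, +-, 0+} at one time point
        tas = self._group([[0], [0], [1], [3]], track_factory)
        gp = motion_probabilities(tas, "given_previous")
        assert gp.values["pp"][0] == pytest.approx(2 / 3)
        assert gp.values["0p"][0] == pytest.approx(1.0)
        ga = motion_probabilities(tas, "given_any")
        assert ga.values["pp"][0] == pytest.approx(0.5)

    def test_raw_denominator_is_group_size(self, track_factory):
        tas = self._group([[0], [-1], [-1], [-1]], track_factory)
        raw = motion_probabilities(tas, "raw")
        assert raw.values["pp"][0] == pytest.approx(0.25)
        assert (raw.denominators["pp"] == 4).all()

    def test_always_forward_group(self, track_factory):
        tas = self._group([[0, 0, 0]] * 3, track_factory)
        gp = motion_probabilities(tas, "given_previous")
        assert (gp.values["pp"] == 1.0).all()
        assert (gp.values["pm"] == 0.0).all()
        assert np.isnan(gp.values["00"]).all()  # no resting denominators

    def test_conservation_identities_exact(self, small_cohort, sim_config,
                                           defaults):
        from openfieldkit.pipeline import analyze_tracks
        tracks, _ = small_cohort
        res = analyze_tracks(tracks, sim_config, defaults)
        tas = [m.trans for m in res.groups["A"].members]
        gp = motion_probabilities(tas, "given_previous")
        move = gp.denominators["pp"] > 0
        s = (gp.values["pp"] + gp.values["pm"] + gp.values["p0"])[move]
        np.testing.assert_allclose(s, 1.0, atol=1e-12)
        rest = gp.denominators["00"] > 0
        s2 = (gp.values["0p"] + gp.values["00"])[rest]
        np.testing.assert_allclose(s2, 1.0, atol=1e-12)
        ga = motion_probabilities(tas, "given_any")
        anyd = ga.denominators["pp"] > 0
        s3 = sum(ga.values[o] for o in ga.values)[anyd]
        np.testing.assert_allclose(s3, 1.0, atol=1e-12)
        raw = motion_probabilities(tas, "raw")
        s4 = sum(raw.values[o] for o in raw.values)
        assert (s4 <= 1.0 + 1e-12).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            motion_probabilities([], "given_previous")

    def test_individual_series_matches_group_mean(self, small_cohort,
                                                  sim_config, defaults):
        # averaging the per-individual conditional series over non-missing
        # individuals reproduces the group probability exactly
        from openfieldkit.pipeline import analyze_tracks
        tracks, _ = small_cohort
        res = analyze_tracks(tracks, sim_config, defaults)
        tas = [m.trans for m in res.groups["A"].members]
        gp = motion_probabilities(tas, "given_previous")
        mat = np.vstack([individual_probability_series(t, "pp",
                                                       "given_previous")
                         for t in tas])
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(mat, axis=0)
        defined = gp.denominators["pp"] > 0
        np.testing.assert_allclose(mean[defined], gp.values["pp"][defined],
                                   atol=1e-12)
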