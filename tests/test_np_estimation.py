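"""Estimator checks against independent oracles.

The two-state and competing-risks reductions are compared with lifelines'
Kaplan-Meier and Aalen-Johansen fitters and with hand-computed closed forms;
the general case is compared with a brute-force product of (I + dA) factors
assembled directly from counted events.
"""

import numpy as np
import pandas as pd
import pytest
from lifelines import AalenJohansenFitter, KaplanMeierFitter

import waitlist_msm as wm
from waitlist_msm.np_estimation import greenwood_variance
from waitlist_msm.state_space import N_STATES

from conftest import make_record, table_from_paths

DEATH = 15
DD = 13


def two_state_table(structure, durations, observed):
    """All subjects in state 1 (0% active); death is the only realized exit."""
    records = []
    for k, (t, e) in enumerate(zip(durations, observed)):
        records.append(
            make_record(
                f"s{k}",
                terminal_day=t if e else None,
                terminal_state=DEATH if e else None,
                censor_day=None if e else t,
            )
        )
    return wm.prepare_transition_table(records, structure)


class TestCounting:
    def test_at_risk_and_event_counts(self, structure):
        records = [
            make_record("a", censor_day=100),
            make_record("b", censor_day=100),
            make_record("c", terminal_day=50, terminal_state=DEATH),
        ]
        table = wm.prepare_transition_table(records, structure)
        profile = wm.count_risk_and_events(table, structure)
        assert profile.event_times.tolist() == [50.0]
        assert profile.at_risk[0, 0] == 3
        tid = structure.transition_id(1, DEATH)
        assert profile.events[0, tid - 1] == 1
        assert profile.events.sum() == 1

    def test_empty_table_gives_empty_profile(self, structure):
        table = wm.prepare_transition_table([make_record("a", censor_day=10)], structure)
        profile = wm.count_risk_and_events(table, structure)
        assert len(profile.event_times) == 0
        assert profile.events.size == 0

    def test_simultaneous_events_share_one_time(self, structure):
        records = [
            make_record("a", terminal_day=50, terminal_state=DEATH),
            make_record("b", terminal_day=50, terminal_state=DEATH),
            make_record("c", censor_day=100),
        ]
        profile = wm.count_risk_and_events(
            wm.prepare_transition_table(records, structure), structure
        )
        assert len(profile.event_times) == 1
        tid = structure.transition_id(1, DEATH)
        assert profile.events[0, tid - 1] == 2
        assert profile.at_risk[0, 0] == 3


class TestNelsonAalen:
    def test_single_jump_is_one_over_at_risk(self, structure):
        table = two_state_table(structure, [10, 20, 20, 20], [1, 0, 0, 0])
        haz = wm.nelson_aalen(wm.count_risk_and_events(table, structure))
        tid = structure.transition_id(1, DEATH)
        assert haz.cumulative(tid, np.array([30.0]))[0] == pytest.approx(0.25)

    def test_two_jumps_sum(self, structure):
        table = two_state_table(structure, [10, 20, 30, 30, 30], [1, 1, 0, 0, 0])
        haz = wm.nelson_aalen(wm.count_risk_and_events(table, structure))
        tid = structure.transition_id(1, DEATH)
        assert haz.cumulative(tid, np.array([30.0]))[0] == pytest.approx(1 / 5 + 1 / 4)

    def test_no_events_identically_zero(self, structure):
        table = two_state_table(structure, [10, 20], [0, 0])
        haz = wm.nelson_aalen(wm.count_risk_and_events(table, structure))
        assert haz.delta.size == 0 or haz.delta.sum() == 0

    def test_forbidden_transition_hazard_is_structurally_absent(self, val_fit):
        frame = val_fit.hazards.to_frame()
        pairs = {val_fit.structure.pair(int(t)) for t in frame["transition_id"]}
        inactive = {st.index for st in val_fit.space.transient if st.index % 2 == 0}
        assert not any(f in inactive and t == DD for f, t in pairs)


class TestAalenJohansenOracles:
    def hand_built_table(self, structure):
        # A: 1 -> 3 at day 10, censored 30; B: dies day 20; C: censored 30;
        # D: starts in state 3, censored 25.
        records = [
            make_record("A", updates=[wm.Update(day=10, cpra=40)], censor_day=30),
            make_record("B", terminal_day=20, terminal_state=DEATH),
            make_record("C", censor_day=30),
            make_record("D", initial_cpra=40, censor_day=25),
        ]
        return wm.prepare_transition_table(records, structure)

    def test_matches_brute_force_product(self, structure):
        table = self.hand_built_table(structure)
        fit = wm.fit_multistate(table, structure)
        traj = wm.aalen_johansen(fit.hazards, 0.0, times=np.array([30.0]))
        # independent brute force: factors assembled from the raw counts
        dA10 = np.zeros((N_STATES, N_STATES))
        dA10[0, 2] = 1 / 3  # one of three subjects in state 1 moves to state 3
        dA10[0, 0] = -1 / 3
        dA20 = np.zeros((N_STATES, N_STATES))
        dA20[0, 14] = 1 / 2  # one of the remaining two dies
        dA20[0, 0] = -1 / 2
        expected = (np.eye(N_STATES) + dA10) @ (np.eye(N_STATES) + dA20)
        np.testing.assert_allclose(traj.at(30.0), expected, atol=1e-12)

    def test_no_events_in_window_gives_identity(self, structure):
        table = self.hand_built_table(structure)
        fit = wm.fit_multistate(table, structure)
        traj = wm.aalen_johansen(fit.hazards, 21.0, times=np.array([29.0]))
        np.testing.assert_allclose(traj.at(29.0), np.eye(N_STATES), atol=0)

    def test_survival_matches_kaplan_meier(self, structure):
        durations = [3, 5, 5, 8, 10, 12, 12, 15, 20, 21]
        observed = [1, 1, 0, 1, 0, 1, 1, 0, 1, 0]
        table = two_state_table(structure, durations, observed)
        fit = wm.fit_multistate(table, structure)
        traj = wm.aalen_johansen(fit.hazards, 0.0)
        km = KaplanMeierFitter().fit(durations, observed)
        for t in [3, 5, 8, 12, 20, 21]:
            assert traj.at(t)[0, 0] == pytest.approx(
                km.predict(t), abs=1e-12
            )

    def test_survival_variance_matches_closed_form_greenwood(self, structure):
        # 5 subjects, deaths at two times: d=2 of Y=5 at day 10 and, after a
        # censoring at day 15, d=1 of Y=2 at day 20
        # -> S = (3/5)(1/2), var = S^2 (2/(5*3) + 1/(2*1))
        table = two_state_table(structure, [10, 10, 15, 20, 25], [1, 1, 0, 1, 0])
        fit = wm.fit_multistate(table, structure)
        traj = wm.aalen_johansen(fit.hazards, 0.0, times=np.array([25.0]))
        S = (3 / 5) * (1 / 2)
        var = S**2 * (2 / (5 * 3) + 1 / (2 * 1))
        assert traj.at(25.0)[0, 0] == pytest.approx(S, abs=1e-12)
        assert traj.variance_at(25.0)[0, 0] == pytest.approx(var, abs=1e-12)
        se = greenwood_variance(fit.hazards, traj)
        assert se[-1, 0, 0] == pytest.approx(np.sqrt(var), abs=1e-12)

    def test_absorbing_columns_match_cumulative_incidence(self, structure):
        """Competing-risks reduction: one transient state, two event types."""
        rng = np.random.default_rng(5)
        n = 60
        death_t = rng.exponential(300, n).round() + 1
        dd_t = rng.exponential(400, n).round() + 1
        censor_t = rng.exponential(500, n).round() + 1
        # jitter to avoid ties: lifelines' AJ fitter dislikes tied times
        t = np.minimum(np.minimum(death_t, dd_t), censor_t) + rng.uniform(0, 0.5, n)
        event = np.where(
            censor_t <= np.minimum(death_t, dd_t),
            0,
            np.where(death_t < dd_t, 1, 2),
        )
        records = []
        for k in range(n):
            terminal = {1: DEATH, 2: DD}.get(event[k])
            records.append(
                make_record(
                    f"s{k}",
                    terminal_day=t[k] if terminal else None,
                    terminal_state=terminal,
                    censor_day=None if terminal else t[k],
                )
            )
        fit = wm.fit_multistate(
            wm.prepare_transition_table(records, structure), structure
        )
        traj = wm.aalen_johansen(fit.hazards, 0.0)
        ajf = AalenJohansenFitter(calculate_variance=False).fit(
            pd.Series(t), pd.Series(event), event_of_interest=1
        )
        cif = ajf.cumulative_density_
        for q in [100, 300, 600]:
            expected = float(cif[cif.index <= q].iloc[-1, 0]) if (cif.index <= q).any() else 0.0
            assert traj.at(q)[0, DEATH - 1] == pytest.approx(expected, abs=1e-10)


class TestMatrixProperties:
    def test_rows_sum_to_one_everywhere(self, val_fit):
        traj = val_fit.transition_probabilities(0.0, with_variance=False)
        sums = traj.probabilities.sum(axis=2)
        np.testing.assert_allclose(sums, 1.0, atol=1e-10)

    def test_chapman_kolmogorov(self, val_fit):
        s, t, u = 30.0, 180.0, 400.0
        P_su = val_fit.transition_probabilities(s, times=[u], with_variance=False).at(u)
        P_st = val_fit.transition_probabilities(s, times=[t], with_variance=False).at(t)
        P_tu = val_fit.transition_probabilities(t, times=[u], with_variance=False).at(u)
        np.testing.assert_allclose(P_su, P_st @ P_tu, atol=1e-10)

    def test_absorbing_probabilities_monotone(self, val_fit):
        grid = np.arange(0.0, 731.0, 30.0)
        traj = val_fit.transition_probabilities(0.0, times=grid, with_variance=False)
        for k in range(12, 16):
            col = traj.probabilities[:, :12, k]
            assert (np.diff(col, axis=0) >= -1e-12).all()

    def test_absorbing_rows_stay_unit_vectors(self, val_fit):
        traj = val_fit.transition_probabilities(0.0, with_variance=False)
        np.testing.assert_allclose(
            traj.probabilities[:, 12:, :],
            np.broadcast_to(np.eye(16)[12:], (len(traj.times), 4, 16)),
            atol=0,
        )

    def test_origin_beyond_last_event_warns_identity(self, val_fit):
        with pytest.warns(UserWarning):
            traj = val_fit.transition_probabilities(1e6, times=[1e6 + 5.0])
        np.testing.assert_allclose(traj.at(1e6 + 5.0), np.eye(16), atol=0)


class TestConfidenceIntervals:
    def test_zero_variance_bands_collapse(self, structure):
        table = two_state_table(structure, [10, 20], [0, 0])
        fit = wm.fit_multistate(table, structure)
        traj = wm.aalen_johansen(fit.hazards, 0.0, times=np.array([15.0]))
        lo, up = wm.confidence_interval(traj, 0.95)
        np.testing.assert_array_equal(lo, traj.probabilities)
        np.testing.assert_array_equal(up, traj.probabilities)

    def test_bands_truncate_to_unit_interval(self, val_fit):
        traj = val_fit.transition_probabilities(0.0, times=[365.0])
        lo, up = wm.confidence_interval(traj, 0.999999999)
        assert lo.min() >= 0 and up.max() <= 1

    def test_band_width_monotone_in_level(self, val_fit, grid_365):
        traj = val_fit.transition_probabilities(0.0, times=grid_365)
        widths = []
        for level in (0.5, 0.8, 0.95):
            lo, up = wm.confidence_interval(traj, level)
            widths.append((up - lo).sum())
        assert widths[0] < widths[1] < widths[2]

    def test_log_bands_positive_for_positive_estimates(self, val_fit, grid_365):
        traj = val_fit.transition_probabilities(0.0, times=grid_365)
        lo, up = wm.confidence_interval(traj, 0.95, method="log")
        p = traj.probabilities
        assert (lo[p > 0] > 0).all()
        assert (lo <= p).all() and (up >= p).all()

    def test_variance_non_negative(self, val_fit, grid_365):
        traj = val_fit.transition_probabilities(0.0, times=grid_365)
        assert (traj.variance >= -1e-15).all()


class TestParameterRecovery:
    def test_estimates_approach_oracle_with_n(self, structure):
        """Sup-norm error vs the matrix-exponential truth shrinks with n."""
        errs = {}
        for n in (150, 1200):
            sc = wm.validation_scenario(n_subjects=n, seed=77)
            fit = wm.fit_multistate(
                table_from_paths(wm.simulate_paths(sc), structure), structure
            )
            P = fit.transition_probabilities(
                0.0, times=[365.0], with_variance=False
            ).at(365.0)
            truth = wm.true_transition_probability(sc.intensities, 0, 365)
            errs[n] = np.abs(P - truth).max()
        assert errs[1200] < errs[150]
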