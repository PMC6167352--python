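"""Parameter sampling, green-episode screening, Holocene extension, subsets."""

import math

import numpy as np
import pytest

import greensahara as gs
from greensahara import (
    ModelParams,
    ParamRanges,
    SimulationConfig,
    Trajectory,
    correlation_subset,
    detect_green_events,
    extend_holocene,
    sample_params,
    screen_ensemble,
    sensitivity_from_records,
)

from conftest import constant_forcing


class TestSampleParams:
    def test_draws_respect_ranges_and_mean(self):
        ranges = ParamRanges(d=(0.5, 1.5))
        draws = sample_params(1_000, ranges, seed=1)
        d = np.array([p.d for p in draws])
        assert np.all((d > 0.5) & (d < 1.5))
        sd = math.sqrt(1.0 / 12.0)
        assert abs(d.mean() - 1.0) < 4 * sd / math.sqrt(1_000)

    def test_same_seed_identical_draws(self):
        a = sample_params(50, seed=9)
        b = sample_params(50, seed=9)
        assert a == b

    def test_degenerate_near_point_range(self):
        ranges = ParamRanges(sigma=(0.5, 0.5 + 1e-9))
        draws = sample_params(20, ranges, seed=0)
        assert all(0.5 <= p.sigma <= 0.5 + 1e-9 for p in draws)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            ParamRanges(a=(1.0, -1.0))

    def test_yaml_round_trip(self, tmp_path):
        ranges = ParamRanges(b=(-30.0, -5.0))
        path = tmp_path / "ranges.yaml"
        ranges.to_yaml(path)
        assert ParamRanges.from_yaml(path) == ranges


class TestDetectGreenEvents:
    @staticmethod
    def _traj(v, oldest=None, dt=1.0):
        v = np.asarray(v, dtype=float)
        n = v.size
        oldest = (n - 1) * dt if oldest is None else oldest
        t = oldest - dt * np.arange(n)
        return Trajectory(t, v, np.zeros(n))

    def test_always_desert_no_events(self):
        traj = self._traj(np.full(10_000, -0.8))
        assert detect_green_events(traj) == []

    def test_always_green_single_spanning_event(self):
        traj = self._traj(np.full(10_000, 0.8))
        (event,) = detect_green_events(traj)
        assert event.start == traj.time[0] and event.end == traj.time[-1]

    def test_three_engineered_episodes_recovered(self):
        # noiseless run forced green in three separated 10-kyr windows
        n = 60_001
        t = 60_000.0 - np.arange(n)
        P = np.zeros(n)
        for old, young in [(55_000, 45_000), (35_000, 25_000), (15_000, 5_000)]:
            P[(t <= old) & (t >= young)] = -0.05
        f = gs.ForcingSeries(t, P, np.zeros(n))
        p = ModelParams(a=-0.5, b=-20.0, c=0.0, d=1.0, tau_v=10.0, tau_N=5.0, sigma=0.0)
        traj = gs.simulate(p, f, SimulationConfig(seed=0))
        events = detect_green_events(traj)
        assert len(events) == 3
        for event, (old, young) in zip(events, [(55_000, 45_000), (35_000, 25_000), (15_000, 5_000)]):
            assert abs(event.start - old) <= 600   # within smooth_window/2 + tau_v lag
            assert abs(event.end - young) <= 600

    def test_short_blips_dropped_and_gaps_merged(self):
        v = np.full(30_000, -0.5)
        v[5_000:5_500] = 0.8               # 500 yr blip: below min_duration
        v[10_000:13_000] = 0.8             # two 3-kyr episodes ...
        v[14_000:17_000] = 0.8             # ... separated by a 1-kyr gap: merged
        traj = self._traj(v)
        events = detect_green_events(traj, smooth_window=100, min_duration=2_000, merge_gap=2_000)
        assert len(events) == 1
        assert events[0].duration > 6_000

    def test_window_longer_than_trajectory_rejected(self):
        with pytest.raises(ValueError):
            detect_green_events(self._traj(np.zeros(100)), smooth_window=1_000)


class TestScreening:
    def test_never_positive_rainfall_is_implausible(self):
        p = ModelParams(a=-1.5, b=0.0, c=0.0, d=1.0, tau_v=10.0, tau_N=5.0, sigma=0.1)
        recs = screen_ensemble([p], constant_forcing(n=30_000), required_events=6)
        assert recs[0].plausible is False and recs[0].green_events == []

    def test_truth_member_with_six_events_is_plausible(self, truth_study):
        screening = truth_study.forcing.slice(230_000.0, 20_000.0)
        recs = screen_ensemble(
            [truth_study.params], screening, member_seeds=[truth_study.seed]
        )
        assert recs[0].plausible
        assert len(recs[0].green_events) == 6

    def test_retained_fraction_strictly_between_zero_and_one(self, screened_ensemble):
        frac = np.mean([r.plausible for r in screened_ensemble])
        assert 0.0 < frac < 1.0

    def test_order_invariance(self, default_forcing):
        params = sample_params(6, seed=3)
        screening = default_forcing.slice(230_000.0, 20_000.0)
        fwd = screen_ensemble(params, screening, base_seed=3)
        rev = screen_ensemble(
            params[::-1], screening, member_seeds=[3 + i for i in range(6)][::-1]
        )
        for a, b in zip(fwd, rev[::-1]):
            assert len(a.green_events) == len(b.green_events)
            assert a.plausible == b.plausible


class TestHoloceneExtension:
    def test_truth_member_seven_total_events_and_collapse(self, truth_study):
        f = truth_study.forcing
        recs = screen_ensemble(
            [truth_study.params], f.slice(230_000.0, 20_000.0),
            member_seeds=[truth_study.seed],
        )
        recs = extend_holocene(recs, f.slice(20_000.0, 0.0))
        rec = recs[0]
        assert rec.plausible
        assert rec.holocene_green_event is not None
        assert len(rec.green_events) + 1 == 7
        assert rec.collapse_t_star == truth_study.collapse_t_star
        assert not rec.never_leaves_green

    def test_member_green_to_present_never_leaves(self):
        # r stays positive through the whole window: no collapse t*
        p = ModelParams(a=0.5, b=0.0, c=0.0, d=1.0, tau_v=10.0, tau_N=5.0, sigma=0.1)
        f = constant_forcing(n=20_001)
        recs = screen_ensemble([p], f, required_events=1)
        assert recs[0].plausible
        recs = extend_holocene(recs, constant_forcing(n=5_001, oldest=5_000.0))
        assert recs[0].never_leaves_green is True
        assert recs[0].collapse_t_star is None

    def test_engineered_midholocene_collapse_dated(self, truth_study):
        # single sign change of r at ~5.5 ka: t* lands in that century
        n = 15_001
        t = 15_000.0 - np.arange(n)
        P = np.where(t >= 5_500.0, -0.05, 0.05)
        f = gs.ForcingSeries(t, P, np.zeros(n))
        p = ModelParams(a=0.0, b=-10.0, c=0.0, d=1.0, tau_v=10.0, tau_N=5.0, sigma=0.3)
        recs = screen_ensemble([p], f.slice(15_000.0, 6_000.0), required_events=1)
        recs = extend_holocene(recs, f.slice(6_000.0, 0.0))
        assert recs[0].collapse_t_star is not None
        assert abs(recs[0].collapse_t_star - 5_500.0) <= 100.0

    def test_exclusion_of_never_collapsing_members_leaves_ss_unchanged(
        self, screened_ensemble
    ):
        ss_all = sensitivity_from_records(screened_ensemble)
        kept = [r for r in screened_ensemble if not r.never_leaves_green]
        ss_kept = sensitivity_from_records(kept)
        assert np.array_equal(ss_all.count, ss_kept.count)
        assert np.array_equal(ss_all.smoothed, ss_kept.smoothed)


class TestReplicates:
    def test_replicates_structural_and_reproducible(self, default_forcing):
        series, peaks = gs.replicate_experiment(
            default_forcing, n_members=40, n_replicates=3, base_seed=5
        )
        assert len(series) == 3 and len(peaks) == 3
        shapes = {s.bin_start.shape for s in series}
        assert len(shapes) == 1
        _, peaks2 = gs.replicate_experiment(
            default_forcing, n_members=40, n_replicates=3, base_seed=5
        )
        assert peaks == peaks2


class TestCorrelationSubset:
    @staticmethod
    def _fake_trajs(rng, n, t):
        return {
            i: Trajectory(t, np.cumsum(rng.standard_normal(t.size)) * 0.01, np.zeros(t.size))
            for i in range(n)
        }

    def test_observed_equal_to_member_ranks_first(self):
        rng = np.random.default_rng(0)
        t = 10_000.0 - 100.0 * np.arange(101)
        trajs = self._fake_trajs(rng, 10, t)
        obs = (t, trajs[7].v.copy())
        ids = correlation_subset(trajs, obs, k=3)
        assert ids[0] == 7

    def test_selection_always_fills_k(self):
        rng = np.random.default_rng(1)
        t = 10_000.0 - 100.0 * np.arange(101)
        trajs = self._fake_trajs(rng, 20, t)
        obs = (t, rng.standard_normal(t.size))
        assert len(correlation_subset(trajs, obs, k=10)) == 10

    def test_constant_member_gets_zero_r2(self):
        t = 10_000.0 - 100.0 * np.arange(101)
        trajs = {
            0: Trajectory(t, np.zeros(t.size), np.zeros(t.size)),
            1: Trajectory(t, np.sin(t / 500.0), np.zeros(t.size)),
        }
        obs = (t, np.sin(t / 500.0))
        assert correlation_subset(trajs, obs, k=2) == [1, 0]

    def test_truth_recovery_under_noise(self, truth_study, screened_ensemble):
        # proxy = truth v + 50% noise: the planted truth member ranks top 1%
        trajs = {r.member_id: r.trajectory for r in screened_ensemble}
        truth_v = trajs[0].v
        rng = np.random.default_rng(123)
        noise = rng.standard_normal(truth_v.size) * 0.5 * np.std(truth_v)
        obs = (trajs[0].time, truth_v + noise)
        n = len(trajs)
        ids = correlation_subset(trajs, obs, k=n)
        rank = ids.index(0)
        assert rank < max(1, math.ceil(0.01 * n))
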