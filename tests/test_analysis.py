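import numpy as np
import pytest

from swarmscan import analysis, session as S, synth
from swarmscan.analysis import PresenceSchedule, Spectra


def make_session(means, interval=2.0):
    """means: list of (mx, my) or None for gaps."""
    records = []
    for k, m in enumerate(means):
        if m is None:
            records.append(S.make_record(k * interval, []))
        else:
            records.append(S.make_record(k * interval, [m]))
    return S.Session(S.SessionMeta(interval=interval), records)


class TestComputeSpectra:
    def test_projection_with_gap(self):
        sp = analysis.compute_spectra(make_session([(1, 2), (3, 4), None]))
        assert sp.lateral[:2].tolist() == [1, 3]
        assert np.isnan(sp.lateral[2]) and np.isnan(sp.vertical[2])
        assert sp.vertical[:2].tolist() == [2, 4]

    def test_empty_session_errors(self):
        with pytest.raises(ValueError):
            analysis.compute_spectra(S.Session(S.SessionMeta(), []))

    def test_constant_swarm_flat_spectra(self):
        cfg = synth.SwarmConfig(
            arena_w=100, arena_h=80, n=4, n_frames=20, sigma=0.0,
            min_separation=0.0, seed=1,
        )
        sess = synth.ground_truth_session(synth.simulate_motion(cfg), cfg)
        sp = analysis.compute_spectra(sess)
        assert np.ptp(sp.lateral) == 0.0
        assert np.ptp(sp.vertical) == 0.0

    def test_drift_toward_left_wall_monotone(self):
        cfg = synth.SwarmConfig(
            arena_w=200, arena_h=100, n=6, n_frames=30, sigma=0.0, kappa=2.0,
            p_rest_to_fly=1.0, p_fly_to_rest=0.0, stimulus_point=(2.0, 50.0),
            presence=((0.0, 1e9),), min_separation=0.0, seed=2,
        )
        sp = analysis.compute_spectra(
            synth.ground_truth_session(synth.simulate_motion(cfg), cfg)
        )
        assert (np.diff(sp.lateral) <= 1e-9).all()

    def test_round_trip_identical(self, tmp_path):
        sess = make_session([(1.25, 2.5), None, (3.0, 4.0)])
        direct = analysis.compute_spectra(sess)
        S.write_session(sess, tmp_path / "s.txt")
        via_file = analysis.compute_spectra(S.read_session(tmp_path / "s.txt"))
        assert np.allclose(direct.t, via_file.t)
        assert np.allclose(direct.lateral, via_file.lateral, equal_nan=True)
        assert np.allclose(direct.vertical, via_file.vertical, equal_nan=True)


class TestDetectGaps:
    def test_no_gaps(self):
        sp = analysis.compute_spectra(make_session([(1, 1)] * 5))
        assert analysis.detect_gaps(sp, 0.0) == []

    def test_ten_record_gap(self):
        means = [(1, 1)] * 3 + [None] * 10 + [(1, 1)] * 3
        sp = analysis.compute_spectra(make_session(means, interval=2.0))
        gaps = analysis.detect_gaps(sp, min_duration=15.0)
        assert gaps == [(6.0, 26.0)]  # 10 records x 2 s = 20 s

    def test_alternating_below_threshold(self):
        means = [(1, 1), None] * 6
        sp = analysis.compute_spectra(make_session(means, interval=2.0))
        assert analysis.detect_gaps(sp, min_duration=5.0) == []

    def test_run_length_oracle(self, rng):
        # maximal missing runs found by explicit run-length encoding
        for _ in range(30):
            pattern = rng.random(40) < 0.4
            means = [None if m else (1.0, 1.0) for m in pattern]
            sp = analysis.compute_spectra(make_session(means, interval=2.0))
            min_dur = float(rng.choice([0.0, 4.0, 8.0]))
            got = analysis.detect_gaps(sp, min_dur)
            runs = []
            k = 0
            while k < len(pattern):
                if pattern[k]:
                    start = k
                    while k < len(pattern) and pattern[k]:
                        k += 1
                    runs.append((start * 2.0, k * 2.0))
                else:
                    k += 1
            want = [r for r in runs if r[1] - r[0] >= min_dur]
            assert got == want
            # disjoint and ordered
            for (a1, b1), (a2, b2) in zip(got[:-1], got[1:]):
                assert b1 <= a2

    def test_negative_duration_rejected(self):
        sp = analysis.compute_spectra(make_session([(1, 1)]))
        with pytest.raises(ValueError):
            analysis.detect_gaps(sp, -1)


class TestActivityIndex:
    def test_constant_series_zero(self):
        sp = analysis.compute_spectra(make_session([(5, 5)] * 10))
        assert analysis.activity_index(sp, (0, 20), "lateral") == 0.0

    def test_square_wave(self):
        means = [(0, 0), (10, 10), (0, 0), (10, 10)]
        sp = analysis.compute_spectra(make_session(means))
        assert analysis.activity_index(sp, (0, 8), "vertical") == pytest.approx(10.0)

    def test_missing_only_window_undefined(self):
        sp = analysis.compute_spectra(make_session([None, None, (1, 1)]))
        assert np.isnan(analysis.activity_index(sp, (0, 4), "lateral"))

    def test_skips_pairs_with_missing_member(self):
        means = [(0, 0), None, (10, 10), (20, 20)]
        sp = analysis.compute_spectra(make_session(means))
        # only the (10,10)->(20,20) pair is usable
        assert analysis.activity_index(sp, (0, 8), "lateral") == pytest.approx(10.0)

    def test_shift_invariance_and_scaling(self, rng):
        vals = rng.normal(0, 5, 20)
        sp1 = analysis.compute_spectra(make_session([(v, v) for v in vals]))
        sp2 = analysis.compute_spectra(make_session([(v + 100, v + 100) for v in vals]))
        sp3 = analysis.compute_spectra(make_session([(3 * v, 3 * v) for v in vals]))
        w = (0, 40)
        a1 = analysis.activity_index(sp1, w, "lateral")
        assert analysis.activity_index(sp2, w, "lateral") == pytest.approx(a1)
        assert analysis.activity_index(sp3, w, "lateral") == pytest.approx(3 * a1)

    def test_bad_axis(self):
        sp = analysis.compute_spectra(make_session([(1, 1)]))
        with pytest.raises(ValueError):
            analysis.activity_index(sp, (0, 2), "diagonal")


class TestPresenceSchedule:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            PresenceSchedule([("P1", 0, 10), ("P2", 5, 15)])

    def test_periodic_builder(self):
        sched = PresenceSchedule.periodic(4, 60.0, 300.0, 300.0)
        assert [s[0] for s in sched.intervals] == ["P1", "P2", "P3", "P4"]
        assert sched.intervals[2] == ("P3", 1260.0, 1560.0)

    def test_csv_round_trip(self, tmp_path):
        sched = PresenceSchedule.periodic(2, 10.0, 20.0, 30.0)
        p = tmp_path / "sched.csv"
        sched.to_csv(p)
        assert PresenceSchedule.from_csv(p).intervals == sched.intervals


class TestPresenceResponse:
    def test_empty_schedule(self):
        sp = analysis.compute_spectra(make_session([(1, 1)] * 10))
        assert analysis.presence_response(sp, PresenceSchedule([])) == []

    def _presence_config(self, seed, **kw):
        base = dict(
            arena_w=650, arena_h=400, n=60, n_frames=400, sigma=3.0,
            presence_sigma_scale_y=2.0, min_separation=0.0, seed=seed,
            presence=tuple(
                (lo, hi) for _, lo, hi in
                PresenceSchedule.periodic(2, 100.0, 150.0, 150.0).intervals
            ),
        )
        base.update(kw)
        return synth.SwarmConfig(**base)

    def test_vertical_excitation_detected(self):
        sched = PresenceSchedule.periodic(2, 100.0, 150.0, 150.0)
        positive = 0
        total = 0
        for seed in range(20):
            cfg = self._presence_config(seed)
            sp = analysis.compute_spectra(
                synth.ground_truth_session(synth.simulate_motion(cfg), cfg)
            )
            for rep in analysis.presence_response(sp, sched):
                total += 1
                if rep.vertical_diff > 0:
                    positive += 1
        assert positive / total >= 0.8

    def test_attraction_shifts_lateral_mean_negative(self):
        # stimulus at the left wall, presence in the final stretch: the
        # pre-flank holds the undisturbed swarm, so the inside mean drops
        sched = PresenceSchedule([("P1", 400.0, 600.0)])
        cfg = self._presence_config(
            0, kappa=3.0, sigma=0.0, presence_sigma_scale_y=1.0,
            stimulus_point=(2.0, 200.0), p_rest_to_fly=1.0, p_fly_to_rest=0.0,
            n_frames=300, presence=((400.0, 600.0),),
        )
        sp = analysis.compute_spectra(
            synth.ground_truth_session(synth.simulate_motion(cfg), cfg)
        )
        (rep,) = analysis.presence_response(sp, sched)
        assert rep.lateral_shift < 0

    def test_report_csv(self, tmp_path):
        sched = PresenceSchedule.periodic(1, 4.0, 8.0, 8.0)
        sp = analysis.compute_spectra(make_session([(k, k) for k in range(20)]))
        reports = analysis.presence_response(sp, sched)
        analysis.write_report_csv(reports, tmp_path / "r.csv")
        lines = (tmp_path / "r.csv").read_text().splitlines()
        assert lines[0].startswith("label,t_start,t_end,lateral_inside")
        assert len(lines) == 2
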