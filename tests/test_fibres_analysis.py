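import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repliconscope import fibres as fib
from repliconscope.datatypes import FibreSegment, FibreTrack


def make_track(segments, fid=0):
    return FibreTrack(fid, [FibreSegment(*s) for s in segments])


class TestUnitConversions:
    @pytest.mark.parametrize(
        "um, kbp", [(24.75, 49.5), (0.0, 0.0), (125.0, 250.0), (94.35, 188.7)]
    )
    def test_track_length(self, um, kbp):
        assert fib.track_length_kbp(um) == pytest.approx(kbp)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fib.track_length_kbp(-1.0)

    @pytest.mark.parametrize("kbp, speed", [(49.5, 1.65), (73.8, 2.46), (0.0, 0.0)])
    def test_fork_speed(self, kbp, speed):
        assert fib.fork_speed(kbp) == pytest.approx(speed)

    def test_bad_pulse(self):
        with pytest.raises(ValueError):
            fib.fork_speed(49.5, 0.0)


class TestForkSpeedsFromTrack:
    def test_simple_bidirectional_pattern(self):
        # gap | p2 | p1 | p2 | gap : two forks of 24.75 um each
        track = make_track([
            ("gap", 0.0, 10.0),
            ("pulse2", 10.0, 34.75),
            ("pulse1", 34.75, 59.75),
            ("pulse2", 59.75, 84.5),
            ("gap", 84.5, 100.0),
        ])
        speeds = fib.fork_speeds_from_track(track)
        assert speeds == pytest.approx([1.65, 1.65])

    def test_termination_region_excluded(self):
        # p1 | p2 | p1 : converging forks, not a single-fork track
        track = make_track([
            ("gap", 0.0, 5.0),
            ("pulse1", 5.0, 20.0),
            ("pulse2", 20.0, 60.0),
            ("pulse1", 60.0, 75.0),
            ("gap", 75.0, 90.0),
        ])
        assert fib.fork_speeds_from_track(track) == []

    def test_censored_skipped_with_warning(self):
        track = make_track([
            ("pulse2", 0.0, 20.0, True),
            ("pulse1", 20.0, 40.0),
            ("pulse2", 40.0, 64.75),
            ("gap", 64.75, 80.0),
        ])
        with pytest.warns(UserWarning):
            speeds = fib.fork_speeds_from_track(track)
        assert speeds == pytest.approx([fib.fork_speed(24.75 * 2)])


class TestInterOriginDistances:
    def two_origin_track(self, centre_gap_um=94.35):
        a = 10.0
        segs = [("gap", 0.0, a)]
        # origin 1: p2 p1 p2 with p1 centred at a + 15
        segs += [("pulse2", a, a + 10), ("pulse1", a + 10, a + 20),
                 ("pulse2", a + 20, a + 30)]
        b = a + 15 + centre_gap_um  # p1 centre of origin 2
        segs += [("gap", a + 30, b - 20)]
        segs += [("pulse2", b - 20, b - 10), ("pulse1", b - 10, b + 10),
                 ("pulse2", b + 10, b + 20)]
        segs += [("gap", b + 20, b + 40)]
        return make_track(segs)

    def test_reference_distance(self):
        """Two origins 94.35 um apart give a single IOD of 188.7 kbp."""
        track = self.two_origin_track(94.35)
        iods = fib.inter_origin_distances(track)
        assert iods == pytest.approx([188.7])

    def test_single_origin_empty(self):
        track = make_track([
            ("gap", 0.0, 10.0),
            ("pulse2", 10.0, 20.0),
            ("pulse1", 20.0, 30.0),
            ("pulse2", 30.0, 40.0),
            ("gap", 40.0, 50.0),
        ])
        assert fib.inter_origin_distances(track) == []

    def test_unflanked_block_not_an_origin(self):
        # pulse1 at the fibre start has no left pulse2 flank
        track = make_track([
            ("pulse1", 0.0, 10.0),
            ("pulse2", 10.0, 20.0),
            ("gap", 20.0, 40.0),
            ("pulse2", 40.0, 50.0),
            ("pulse1", 50.0, 60.0),
            ("pulse2", 60.0, 70.0),
            ("gap", 70.0, 80.0),
        ])
        assert fib.inter_origin_distances(track) == []

    def test_gap_origin_flag(self):
        # unlabeled region between diverging pulse2 tracks
        track = make_track([
            ("pulse2", 5.0, 15.0),
            ("pulse1", 15.0, 25.0),
            ("pulse2", 25.0, 35.0),
            ("gap", 35.0, 45.0),
            ("pulse2", 45.0, 55.0),
            ("pulse1", 55.0, 65.0),
            ("pulse2", 65.0, 75.0),
            ("gap", 75.0, 85.0),
        ])
        default = fib.inter_origin_distances(track)
        with_gaps = fib.inter_origin_distances(track, include_gap_origins=True)
        assert len(default) == 1
        assert len(with_gaps) == 2


class TestSummarize:
    def test_table_iod_row(self):
        """sd 121.4 at n=50 gives s.e.m. 17.2 and 95% CI 33.6."""
        rng = np.random.default_rng(0)
        # build a sample with exactly this sd by construction
        x = rng.normal(size=50)
        x = (x - x.mean()) / x.std(ddof=1) * 121.4 + 188.7
        s = fib.summarize(x)
        assert s.sd == pytest.approx(121.4)
        assert round(s.sem, 1) == 17.2
        assert round(s.ci95, 1) == 33.6

    def test_table_rfs_row(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=122)
        x = (x - x.mean()) / x.std(ddof=1) * 1.28 + 1.65
        s = fib.summarize(x)
        assert round(s.sem, 2) == 0.12
        assert round(s.ci95, 2) == 0.23

    def test_constant_vector(self):
        s = fib.summarize([3.0, 3.0, 3.0])
        assert s.sd == 0 and s.sem == 0 and s.ci95 == 0

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            fib.summarize([1.0])

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-1e4, 1e4), min_size=2, max_size=100))
    def test_sem_contract(self, values):
        s = fib.summarize(values)
        assert s.sem * np.sqrt(s.n) == pytest.approx(s.sd, abs=1e-9)
        assert s.ci95 == pytest.approx(fib.Z_95 * s.sem)


class TestSlidingAverage:
    def test_constant_sequence(self):
        res = fib.sliding_average([5.0] * 10)
        np.testing.assert_allclose(res.running_means, 5.0)
        assert res.converged

    def test_alternating_closed_form(self):
        res = fib.sliding_average([1.0, -1.0, 1.0, -1.0, 1.0])
        np.testing.assert_allclose(res.running_means, [1, 0, 1 / 3, 0, 1 / 5])

    def test_iid_converges_at_table_n(self):
        """At n=122 the 5% flag fires well above chance even for the
        very dispersed speed distribution (CV 0.78), and essentially
        always at a moderate CV."""
        high_cv = moderate_cv = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            high_cv += fib.sliding_average(
                g.normal(1.65, 1.28, size=122), tolerance=0.05
            ).converged
            moderate_cv += fib.sliding_average(
                g.normal(1.65, 0.4, size=122), tolerance=0.05
            ).converged
        assert high_cv >= 10
        assert moderate_cv >= 19

    def test_window_mode(self):
        res = fib.sliding_average([1, 2, 3, 4, 5], window=2)
        np.testing.assert_allclose(res.running_means, [1.5, 2.5, 3.5, 4.5])

    def test_window_too_large(self):
        with pytest.raises(ValueError):
            fib.sliding_average([1, 2, 3], window=4)
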