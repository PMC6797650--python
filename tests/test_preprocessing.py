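"""Cleaning strategies: filtering, gap interpolation, triadic closure, sweeps."""

import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfidcontacts.events import (
    ConfigError,
    ContactEvent,
    DyadRaster,
    EventLog,
    ValidationError,
    events_from_raster,
    rasterize,
)
from rfidcontacts.preprocessing import (
    ProcessingConfig,
    Step,
    apply_pipeline,
    close_triads,
    filter_min_duration,
    interpolate_gaps,
    sweep,
)
from conftest import make_random_log
from _oracles import brute_close_triads, brute_interpolate


def dyad_log(*intervals, roster=(1, 2), window=(0, 200)):
    return EventLog(
        [ContactEvent(1, 2, s, e) for s, e in intervals], roster=roster, window=window
    )


# hypothesis strategy: random small rasters realised as logs
@st.composite
def small_logs(draw):
    n = draw(st.integers(3, 5))
    s = draw(st.integers(20, 80))
    seed = draw(st.integers(0, 2**20))
    rng = np.random.default_rng(seed)
    return make_random_log(rng, n, s, density=draw(st.floats(0.1, 0.6)))


class TestMinDuration:
    def test_shorter_than_cutoff_deleted(self):
        log = dyad_log((0, 19))
        assert len(filter_min_duration(log, 20)) == 0

    def test_exactly_cutoff_retained(self):
        log = dyad_log((0, 20))
        assert len(filter_min_duration(log, 20)) == 1

    def test_zero_cutoff_is_identity(self, rng):
        log = make_random_log(rng, 4, 60)
        assert filter_min_duration(log, 0) == log

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValidationError):
            filter_min_duration(dyad_log((0, 5)), -1)

    @given(small_logs(), st.integers(0, 30))
    @settings(max_examples=30, deadline=None)
    def test_output_subset_and_monotone(self, log, cutoff):
        filtered = filter_min_duration(log, cutoff)
        assert set(filtered.events) <= set(log.events)
        # positives non-increasing in the cutoff
        harder = filter_min_duration(log, cutoff + 5)
        assert harder.total_contact_seconds() <= filtered.total_contact_seconds()


class TestInterpolateGaps:
    def test_gap_within_cutoff_merges(self):
        log = dyad_log((0, 10), (25, 40))
        merged = interpolate_gaps(log, 20)
        assert [(e.start, e.end) for e in merged.events] == [(0, 40)]

    def test_boundary_gap_merges_transitively(self):
        log = dyad_log((0, 10), (85, 95), (170, 180))
        merged = interpolate_gaps(log, 75)
        assert [(e.start, e.end) for e in merged.events] == [(0, 180)]

    def test_gap_above_cutoff_kept_apart(self):
        log = dyad_log((0, 10), (32, 40))
        assert len(interpolate_gaps(log, 20)) == 2

    def test_negative_gap_rejected(self):
        with pytest.raises(ValidationError):
            interpolate_gaps(dyad_log((0, 5)), -1)

    @given(small_logs(), st.integers(0, 20))
    @settings(max_examples=40, deadline=None)
    def test_matches_per_second_fill_oracle(self, log, gap):
        merged = interpolate_gaps(log, gap)
        expected = brute_interpolate(rasterize(log).data, gap)
        np.testing.assert_array_equal(rasterize(merged).data, expected)

    @given(small_logs(), st.integers(0, 20))
    @settings(max_examples=30, deadline=None)
    def test_idempotent_and_monotone(self, log, gap):
        once = interpolate_gaps(log, gap)
        assert interpolate_gaps(once, gap) == once
        wider = rasterize(interpolate_gaps(log, gap + 7)).data
        assert (rasterize(once).data <= wider).all()
        assert (rasterize(log).data <= rasterize(once).data).all()


class TestCloseTriads:
    def test_pair_intersection_imputed(self):
        log = EventLog(
            [ContactEvent("A", "B", 0, 100), ContactEvent("A", "C", 50, 150)],
            roster=["A", "B", "C"],
            window=(0, 200),
        )
        closed = close_triads(log, 1)
        bc = [e for e in closed.events if e.dyad == ("B", "C")]
        assert [(e.start, e.end) for e in bc] == [(50, 100)]

    def test_clique_log_is_fixpoint(self):
        events = [ContactEvent(a, b, 0, 50) for a, b in [(1, 2), (1, 3), (2, 3)]]
        log = EventLog(events, roster=[1, 2, 3], window=(0, 100))
        for iters in (1, 3):
            assert close_triads(log, iters) == log

    def test_path_reaches_clique_in_two_iterations(self):
        path = [("A", "B"), ("B", "C"), ("C", "D")]
        log = EventLog(
            [ContactEvent(a, b, 0, 60) for a, b in path], roster=list("ABCD"), window=(0, 60)
        )
        one = close_triads(log, 1)
        dyads_one = {e.dyad for e in one.events}
        assert dyads_one == {("A", "B"), ("B", "C"), ("C", "D"), ("A", "C"), ("B", "D")}
        two = close_triads(log, 2)
        assert {e.dyad for e in two.events} == {
            ("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")
        }
        assert close_triads(log, 3) == two

    def test_zero_iterations_identity(self, rng):
        log = make_random_log(rng, 4, 40)
        assert close_triads(log, 0) == log

    @given(small_logs(), st.integers(1, 3))
    @settings(max_examples=25, deadline=None)
    def test_matches_per_second_brute_force(self, log, iters):
        closed = close_triads(log, iters)
        ids = log.sorted_roster()
        pos = {p: k for k, p in enumerate(ids)}
        raster = rasterize(log)
        pairs = [(pos[a], pos[b]) for a, b in raster.dyads]
        expected = brute_close_triads(raster.data, pairs, len(ids), iters)
        np.testing.assert_array_equal(rasterize(closed).data, expected)

    @given(small_logs())
    @settings(max_examples=20, deadline=None)
    def test_active_seconds_non_decreasing_and_fixpoint(self, log):
        prev = rasterize(log).data
        n = len(log.roster)
        bound = int(np.ceil(np.log2(max(n, 2)))) + 1
        for i in range(1, bound + 1):
            cur = rasterize(close_triads(log, i)).data
            assert (prev <= cur).all()
            prev = cur
        assert np.array_equal(rasterize(close_triads(log, bound + 1)).data, prev)


class TestPipeline:
    def test_interpolate_then_filter(self):
        log = dyad_log((0, 40), (60, 100))
        config = ProcessingConfig([Step("interpolate", 75), Step("min_duration", 55)])
        out = apply_pipeline(log, config)
        assert [(e.start, e.end) for e in out.events] == [(0, 100)]

    def test_order_matters(self):
        log = dyad_log((0, 40), (60, 100))
        config = ProcessingConfig([Step("min_duration", 55), Step("interpolate", 75)])
        assert len(apply_pipeline(log, config)) == 0

    def test_empty_config_is_identity(self, rng):
        log = make_random_log(rng, 4, 50)
        assert apply_pipeline(log, ProcessingConfig([])) == log

    def test_unknown_step_rejected(self):
        with pytest.raises(ConfigError):
            Step("smooth", 10)
        with pytest.raises(ConfigError):
            ProcessingConfig.from_dicts([{"kind": "smooth", "value": 3}])

    def test_config_from_yaml(self, tmp_path):
        path = tmp_path / "steps.yaml"
        path.write_text(
            textwrap.dedent(
                """
                steps:
                  - kind: interpolate
                    max_gap_s: 75
                  - kind: min_duration
                    cutoff_s: 55
                """
            )
        )
        config = ProcessingConfig.from_file(path)
        assert config.to_dicts() == [
            {"kind": "interpolate", "value": 75},
            {"kind": "min_duration", "value": 55},
        ]


class TestSweep:
    def test_perfect_observation_optimum_at_zero(self, rng):
        log = make_random_log(rng, 4, 60)
        result = sweep("min_duration", [0, 5, 10], log, log)
        assert result.optimum_value == 0
        assert result.optimum_score == 1.0

    def test_one_row_per_grid_point(self, rng):
        observed = make_random_log(rng, 4, 60)
        truth = make_random_log(rng, 4, 60)
        result = sweep("interpolate", [0, 10, 20], observed, truth)
        assert len(result.metrics) == 3
        assert list(result.to_frame()["value"]) == [0, 10, 20]

    def test_mismatched_windows_rejected(self, rng):
        observed = make_random_log(rng, 4, 60)
        truth = make_random_log(rng, 4, 50)
        with pytest.raises(ValidationError):
            sweep("interpolate", [0], observed, truth)

    def test_ties_break_to_smallest_value(self, rng):
        log = make_random_log(rng, 3, 40)
        result = sweep("triadic_closure", [0, 0, 1], log, log)
        assert result.optimum_value == 0
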