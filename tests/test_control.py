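import math

import numpy as np
import pytest

from wormbot.control import (
    ControlDecision,
    ControlMessage,
    ForagingEnv,
    LocomotionCommand,
    MessageError,
    OLQ_FOR_REGION,
    RMD_REGION,
    build_foraging_network,
    concentration,
    decide_foraging,
    decode_frequency_to_length,
    decode_locomotion,
    decode_message,
    encode_message,
    encode_regions,
    make_inprocess_pair,
    make_socketpair_transports,
    run_foraging_episode,
    stimulus_from_concentration,
)
from wormbot.membrane import ResponseClass
from wormbot.robot import RegionAssignment


def resp(active, kind=None):
    if not active:
        return ResponseClass("silent", [])
    return ResponseClass(kind or "single_spike",
                         [50.0] if kind != "oscillation" else [50.0, 70.0, 90.0],
                         frequency=50.0 if kind == "oscillation" else None)


class TestConcentration:
    def test_peak_value_at_target(self):
        assert concentration(0.0) == 10_000_000.0

    def test_far_field_is_effectively_zero(self):
        assert concentration(10.0) < 1e-70

    def test_one_meter_value(self):
        assert concentration(1.0) == pytest.approx(
            1.0e7 * math.exp(-2.0), rel=1e-12)  # ~1,353,352.83

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            concentration(-0.1)


class TestStimulusEncoder:
    def test_unchanged_concentration_gives_baseline(self):
        assert stimulus_from_concentration(500.0, 500.0) == 51.0

    def test_rise_and_fall_offset_the_baseline(self):
        assert stimulus_from_concentration(510.0, 500.0) == 61.0
        assert stimulus_from_concentration(490.0, 500.0) == 41.0

    def test_clamped_to_dynamic_range(self):
        assert stimulus_from_concentration(1e7, 0.0) == 200.0
        assert stimulus_from_concentration(0.0, 1e7) == 0.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            stimulus_from_concentration(float("nan"), 0.0)


class TestForagingDecision:
    def test_active_keeps_previous_heading(self):
        rng = np.random.default_rng(0)
        d = decide_foraging(resp(True), [0.0, 1.0], rng)
        assert d.kind == "keep_direction"
        assert np.allclose(d.heading, [0.0, 1.0])

    def test_oscillation_counts_as_activated(self):
        d = decide_foraging(resp(True, "oscillation"), [1.0, 0.0],
                            np.random.default_rng(0))
        assert d.kind == "keep_direction"

    def test_silent_draws_reproducible_random_heading(self):
        a = decide_foraging(resp(False), [1.0, 0.0], np.random.default_rng(42))
        b = decide_foraging(resp(False), [1.0, 0.0], np.random.default_rng(42))
        assert a.kind == "new_random_direction"
        assert np.allclose(a.heading, b.heading)
        assert np.linalg.norm(a.heading) == pytest.approx(1.0)

    def test_heading_always_normalized(self):
        d = ControlDecision("keep_direction", [3.0, 4.0])
        assert np.allclose(d.heading, [0.6, 0.8])


class TestRegionCoding:
    def full_assignment(self):
        return RegionAssignment(
            {i: r for i, r in enumerate("ABCD" * 3)})

    def test_all_regions_encode_four_olq_protocols(self):
        prots = encode_regions(self.full_assignment())
        assert sorted(p.target for p in prots) == sorted(OLQ_FOR_REGION.values())
        assert all(p.amplitude == 100.0 for p in prots)

    @pytest.mark.parametrize("region,olq", [("D", "OLQVL"), ("C", "OLQVR"),
                                            ("A", "OLQDR"), ("B", "OLQDL")])
    def test_single_region_maps_to_its_olq(self, region, olq):
        prots = encode_regions(RegionAssignment({0: region}))
        assert [p.target for p in prots] == [olq]

    def test_rmdvr_extends_d_only(self):
        responses = {m: resp(m == "RMDVR") for m in RMD_REGION}
        cmd = decode_locomotion(responses)
        assert cmd.actions == {"A": "hold", "B": "hold", "C": "hold",
                               "D": "extend"}

    def test_all_active_gives_full_four_region_pattern(self):
        responses = {m: resp(True) for m in RMD_REGION}
        cmd = decode_locomotion(responses)
        assert cmd.actions == {"A": "shrink", "B": "extend", "C": "shrink",
                               "D": "extend"}

    def test_all_silent_holds(self):
        responses = {m: resp(False) for m in RMD_REGION}
        assert set(decode_locomotion(responses).actions.values()) == {"hold"}

    def test_missing_rmd_rejected(self):
        with pytest.raises(ValueError, match="RMDVL"):
            decode_locomotion({m: resp(True) for m in
                               ("RMDDR", "RMDDL", "RMDVR")})

    def test_command_invariant_rejects_inverted_pattern(self):
        with pytest.raises(ValueError):
            LocomotionCommand({"A": "extend"})
        with pytest.raises(ValueError):
            LocomotionCommand({"B": "shrink"})


class TestFrequencyDecoder:
    def test_affine_endpoints_and_midpoint(self):
        freq, leg = (20.0, 60.0), (0.24, 0.50)
        lo, ok = decode_frequency_to_length(
            resp_osc(20.0), freq, leg)
        hi, _ = decode_frequency_to_length(resp_osc(60.0), freq, leg)
        mid, _ = decode_frequency_to_length(resp_osc(40.0), freq, leg)
        assert ok
        assert lo == pytest.approx(0.24)
        assert hi == pytest.approx(0.50)
        assert mid == pytest.approx(0.37)

    def test_out_of_range_frequency_clamped(self):
        L, ok = decode_frequency_to_length(resp_osc(500.0), (20.0, 60.0),
                                           (0.24, 0.50))
        assert ok and L == pytest.approx(0.50)

    def test_non_oscillatory_input_flags_and_returns_minimum(self):
        L, ok = decode_frequency_to_length(resp(False), (20.0, 60.0),
                                           (0.24, 0.50))
        assert not ok and L == 0.24
        L, ok = decode_frequency_to_length(resp(True), (20.0, 60.0),
                                           (0.24, 0.50))
        assert not ok and L == 0.24


def resp_osc(freq):
    return ResponseClass("oscillation", [10.0, 20.0, 30.0], frequency=freq)


class TestMessages:
    def msg(self):
        return ControlMessage(3, "robot->bnn", {"concentration": 1.5})

    def test_round_trip_is_lossless(self):
        line = encode_message(self.msg())
        assert line.endswith("\n") and "\n" not in line[:-1]
        back = decode_message(line)
        assert back == self.msg()

    def test_truncated_line_reports_position(self):
        line = encode_message(self.msg())
        with pytest.raises(MessageError, match="position"):
            decode_message(line[: len(line) // 2])

    def test_unknown_schema_version_rejected(self):
        import json

        data = json.loads(encode_message(self.msg()))
        data["schema_version"] = 99
        with pytest.raises(MessageError, match="version"):
            decode_message(json.dumps(data))

    def test_unknown_role_rejected(self):
        with pytest.raises(MessageError):
            ControlMessage(0, "alien", {})

    def test_transport_pairs_deliver_in_order(self):
        a, b = make_inprocess_pair()
        a.send(self.msg())
        a.send(ControlMessage(4, "bnn->robot", {"kind": "keep_direction"}))
        assert b.recv().step == 3
        assert b.recv().step == 4
        with pytest.raises(MessageError):
            b.recv()


class TestForagingEpisode:
    def test_start_at_target_converges_in_zero_steps(self):
        env = ForagingEnv()
        result = run_foraging_episode(env, seed=0, start=(0.0, 0.0),
                                      max_steps=10)
        assert result.converged and result.steps == 0

    def test_monotone_approach_keeps_heading_throughout(self):
        env = ForagingEnv()
        result = run_foraging_episode(
            env, seed=0, start=(2.0, 0.0), max_steps=40,
            initial_heading=(-1.0, 0.0))
        assert result.converged
        assert all(d == "keep_direction" for d in result.decisions)
        assert np.allclose(result.trajectory[:, 3:5], [-1.0, 0.0])
        dists = np.hypot(result.trajectory[:, 1], result.trajectory[:, 2])
        assert np.all(np.diff(dists) < 0.0)

    def test_decisions_track_the_concentration_sign_end_to_end(self):
        # stimulus > 51 (moved closer) must decode to keep; < 51 to random
        env = ForagingEnv()
        result = run_foraging_episode(env, seed=3, start=(1.5, 1.0),
                                      max_steps=200)
        assert result.converged
        xy = result.trajectory[:, 1:3]
        d = np.hypot(xy[:, 0], xy[:, 1])
        for i, kind in enumerate(result.decisions):
            if i < 2:
                continue
            moved_closer = d[i - 1] < d[i - 2] - 1e-9
            moved_away = d[i - 1] > d[i - 2] + 1e-9
            if moved_closer:
                assert kind == "keep_direction", i
            elif moved_away:
                assert kind == "new_random_direction", i

    def test_socket_and_inprocess_transports_agree(self):
        env = ForagingEnv()
        net = build_foraging_network()
        a = run_foraging_episode(env, network=net, seed=5, start=(1.0, 1.0),
                                 max_steps=60)
        socks = make_socketpair_transports()
        b = run_foraging_episode(env, network=net, seed=5, start=(1.0, 1.0),
                                 max_steps=60, transports=socks)
        for t in socks:
            t.close()
        assert np.array_equal(a.trajectory, b.trajectory)
        assert a.decisions == b.decisions
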