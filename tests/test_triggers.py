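import dataclasses

import numpy as np
import pytest

from icualarms import (
    ChannelId,
    ConfigurationError,
    ScenarioRule,
    TriggerSpec,
    builtin_scenarios,
    eval_absolute_trigger,
    eval_relative_trigger,
    eval_scenario,
    plausibility_filter,
    sensors_present,
)
from conftest import flat_record, uniform_trace

PULSE_GT_110_20S = TriggerSpec(
    channel=ChannelId.Pulse, kind="absolute_sustained", direction="above",
    threshold=110.0, duration_s=20.0,
)


class TestAbsoluteTrigger:
    def test_persistence_delays_activation(self):
        tr = uniform_trace(ChannelId.Pulse, np.full(61, 120.0))
        ivs = eval_absolute_trigger(tr, PULSE_GT_110_20S)
        assert [(iv.t_on, iv.t_off) for iv in ivs] == [(20.0, 60.0)]

    def test_never_violating(self):
        tr = uniform_trace(ChannelId.ARTsys, np.full(601, 90.0))
        spec = TriggerSpec(
            channel=ChannelId.ARTsys, kind="absolute_sustained",
            direction="below", threshold=78.0, duration_s=300.0,
        )
        assert eval_absolute_trigger(tr, spec) == []

    def test_square_wave_never_persists(self):
        v = np.tile(np.r_[np.full(10, 130.0), np.full(10, 90.0)], 6)
        tr = uniform_trace(ChannelId.Pulse, v)
        assert eval_absolute_trigger(tr, PULSE_GT_110_20S) == []

    def test_threshold_is_strict(self):
        tr = uniform_trace(ChannelId.Pulse, np.full(61, 110.0))
        assert eval_absolute_trigger(tr, PULSE_GT_110_20S) == []
        tr2 = uniform_trace(ChannelId.Pulse, np.full(61, 110.01))
        assert len(eval_absolute_trigger(tr2, PULSE_GT_110_20S)) == 1

    def test_missing_breaks_continuity(self):
        v = np.full(61, 120.0)
        v[30] = np.nan
        tr = uniform_trace(ChannelId.Pulse, v)
        ivs = eval_absolute_trigger(tr, PULSE_GT_110_20S)
        assert [(iv.t_on, iv.t_off) for iv in ivs] == [(20.0, 29.0), (51.0, 60.0)]

    def test_channel_mismatch(self):
        tr = uniform_trace(ChannelId.CVPmean, np.full(30, 8.0))
        with pytest.raises(ConfigurationError):
            eval_absolute_trigger(tr, PULSE_GT_110_20S)


class TestRelativeTrigger:
    def test_ramp_exceeding_percent_rise(self):
        # HR 80 -> 120 over 30 s then held: a 50 % rise, beyond +40 %/59 s
        v = np.r_[np.full(70, 80.0), np.linspace(80, 120, 30), np.full(100, 120.0)]
        tr = uniform_trace(ChannelId.HR, v)
        spec = TriggerSpec(
            channel=ChannelId.HR, kind="relative_change", direction="rise",
            threshold=40.0, threshold_unit="percent", window_s=59.0,
        )
        assert len(eval_relative_trigger(tr, spec)) >= 1

    def test_constant_trace_never_changes(self):
        tr = uniform_trace(ChannelId.HR, np.full(200, 80.0))
        spec = TriggerSpec(
            channel=ChannelId.HR, kind="relative_change", direction="rise",
            threshold=10.0, threshold_unit="percent", window_s=30.0,
        )
        assert eval_relative_trigger(tr, spec) == []

    @pytest.mark.parametrize("step_to,expect", [(109.0, 0), (111.0, 1)])
    def test_absolute_delta_boundary(self, step_to, expect):
        # "+30 bpm within 20 s": a step to 109 misses, to 111 satisfies
        v = np.r_[np.full(60, 80.0), np.full(60, step_to)]
        tr = uniform_trace(ChannelId.HR, v)
        spec = TriggerSpec(
            channel=ChannelId.HR, kind="relative_change", direction="rise",
            threshold=30.0, threshold_unit="native", window_s=20.0,
        )
        assert len(eval_relative_trigger(tr, spec)) == expect

    def test_window_longer_than_trace_warns_empty(self):
        tr = uniform_trace(ChannelId.HR, np.full(30, 80.0))
        spec = TriggerSpec(
            channel=ChannelId.HR, kind="relative_change", direction="rise",
            threshold=40.0, threshold_unit="percent", window_s=120.0,
        )
        with pytest.warns(UserWarning):
            assert eval_relative_trigger(tr, spec) == []

    def test_scope_extends_activity(self):
        # a completed fall stays active for scope_s afterwards
        v = np.r_[np.full(40, 2.0), np.full(200, 1.0)]
        tr = uniform_trace(ChannelId.Perf, v)
        base = TriggerSpec(
            channel=ChannelId.Perf, kind="relative_change", direction="fall",
            threshold=20.0, threshold_unit="percent", window_s=20.0,
        )
        scoped = dataclasses.replace(base, scope_s=120.0)
        t_off_base = eval_relative_trigger(tr, base)[-1].t_off
        t_off_scoped = eval_relative_trigger(tr, scoped)[-1].t_off
        assert t_off_scoped == t_off_base + 120.0


class TestPlausibilityFilter:
    def test_cvp_spike_removed(self):
        v = np.full(30, 8.0)
        v[10] = 200.0
        tr = uniform_trace(ChannelId.CVPmean, v)
        out, n = plausibility_filter(tr, (-5.0, 40.0))
        assert n == 1 and np.isnan(out.values[10])

    def test_identity_when_all_plausible(self):
        tr = uniform_trace(ChannelId.CVPmean, np.full(30, 8.0))
        out, n = plausibility_filter(tr, (-5.0, 40.0))
        assert n == 0
        np.testing.assert_array_equal(out.values, tr.values)

    def test_negative_arterial_pressure_removed(self):
        v = np.full(30, 120.0)
        v[3] = -10.0
        tr = uniform_trace(ChannelId.ARTsys, v)
        out, n = plausibility_filter(tr, (0.0, 300.0))
        assert n == 1 and np.isnan(out.values[3])

    def test_bad_limits(self):
        tr = uniform_trace(ChannelId.CVPmean, np.full(5, 8.0))
        with pytest.raises(ValueError):
            plausibility_filter(tr, (40.0, -5.0))


class TestSensorsPresent:
    def test_missing_arterial_line(self):
        rec = flat_record(skip=(ChannelId.ARTsys,))
        svt = builtin_scenarios()[0]
        ok, missing = sensors_present(rec, svt)
        assert not ok and missing == [ChannelId.ARTsys]

    def test_all_channels_present(self):
        rec = flat_record()
        for rule in builtin_scenarios():
            ok, missing = sensors_present(rec, rule)
            assert ok and missing == []

    def test_pulse_substitutes_for_missing_ecg(self):
        rec = flat_record(skip=(ChannelId.HR,))
        svt = builtin_scenarios()[0]
        ok, missing = sensors_present(rec, svt)
        assert ok

    def test_mostly_missing_channel_counts_as_absent(self):
        rec = flat_record(duration_s=1000.0)
        rec.traces[ChannelId.ARTsys].values[: 600] = np.nan
        svt = builtin_scenarios()[0]
        ok, missing = sensors_present(rec, svt)
        assert not ok and ChannelId.ARTsys in missing

    def test_either_or_pressure_slot_for_hypovolemia(self):
        hypo = builtin_scenarios()[4]
        ok, _ = sensors_present(flat_record(skip=(ChannelId.ARTmean,)), hypo)
        assert ok  # cuff pressure satisfies the pressure slot
        ok, missing = sensors_present(
            flat_record(skip=(ChannelId.ARTmean, ChannelId.NIBPm)), hypo
        )
        assert not ok and set(missing) == {ChannelId.ARTmean, ChannelId.NIBPm}


def _svt_episode_record(duration_s=2000.0):
    """HR/Pulse 80->121 in 30 s, ARTsys 120->95, held: beats every SVT limit."""
    rec = flat_record(duration_s=duration_s)
    n = int(duration_s) + 1
    t0 = 300
    for ch, target in [(ChannelId.HR, 121.0), (ChannelId.Pulse, 121.0),
                       (ChannelId.ARTsys, 95.0)]:
        v = rec.traces[ch].values
        base = v[0]
        v[t0 : t0 + 30] = np.linspace(base, target, 30)
        v[t0 + 30 : t0 + 200] = target
        v[t0 + 200 : t0 + 260] = np.linspace(target, base, 60)
    return rec


class TestEvalScenario:
    def test_svt_episode_fires_exactly_once(self):
        rec = _svt_episode_record()
        alarms = eval_scenario(rec, builtin_scenarios()[0])
        assert len(alarms) == 1
        a = alarms[0]
        assert 300 <= a.t_fire <= 600
        assert len(a.contributing) == 3
        assert all(iv.t_on <= a.t_fire for iv in a.contributing)

    def test_refractory_rearm_gives_two_alarms(self):
        # a 10-minute sustained condition with a 300 s refractory: the rule
        # fires, silences, and re-fires once while the condition persists
        rec = flat_record(duration_s=2000.0)
        v = rec.traces[ChannelId.Pulse].values
        v[100:640] = 130.0
        rule = ScenarioRule(
            name="fast pulse", description="", triggers=(PULSE_GT_110_20S,),
            refractory_s=300.0,
        )
        alarms = eval_scenario(rec, rule)
        assert [a.t_fire for a in alarms] == [120.0, 420.0]

    def test_no_two_alarms_within_refractory(self, rng):
        rec = flat_record(duration_s=4000.0)
        v = rec.traces[ChannelId.Pulse].values
        v[:] = 80 + 40 * (rng.random(v.size) < 0.5)  # choppy: many crossings
        rule = ScenarioRule(
            name="fast pulse", description="",
            triggers=(dataclasses.replace(PULSE_GT_110_20S, duration_s=5.0),),
            refractory_s=200.0,
        )
        alarms = eval_scenario(rec, rule)
        fires = [a.t_fire for a in alarms]
        assert all(b - a >= 200.0 for a, b in zip(fires, fires[1:]))

    def test_monotonicity_in_threshold_and_duration(self):
        rec = _svt_episode_record()
        base = ScenarioRule(name="p", description="", triggers=(PULSE_GT_110_20S,))
        n_base = len(eval_scenario(rec, base))
        for spec in (
            dataclasses.replace(PULSE_GT_110_20S, threshold=130.0),
            dataclasses.replace(PULSE_GT_110_20S, duration_s=500.0),
        ):
            harder = ScenarioRule(name="p", description="", triggers=(spec,))
            assert len(eval_scenario(rec, harder)) <= n_base

    def test_ineligible_record_yields_no_alarms(self):
        rec = flat_record(skip=(ChannelId.CVPmean,))
        hypo = builtin_scenarios()[4]
        ok, _ = sensors_present(rec, hypo)
        assert not ok
        assert eval_scenario(rec, hypo) == []

    def test_zero_trigger_rule_rejected(self):
        with pytest.raises(ValueError, match="maximum of four|triggers"):
            ScenarioRule(name="empty", description="", triggers=())

    def test_compatibility_mode_rejects_parameter_reuse(self):
        reuse = ScenarioRule(
            name="cvp twice", description="",
            triggers=(
                TriggerSpec(channel=ChannelId.CVPmean, kind="absolute_sustained",
                            direction="above", threshold=16.0, duration_s=60.0),
                TriggerSpec(channel=ChannelId.CVPmean, kind="absolute_sustained",
                            direction="below", threshold=40.0, duration_s=60.0),
            ),
        )
        rec = flat_record()
        with pytest.raises(ConfigurationError, match="more than once"):
            eval_scenario(rec, reuse, compatibility_mode=True)
        eval_scenario(rec, reuse)  # allowed outside compatibility mode

    def test_plausibility_filter_suppresses_spike_driven_alarm(self):
        # elevated-CVP condition evidenced only by an implausible 200 mmHg
        # reading: alarms without the screen, silent with it
        rec = flat_record(duration_s=1200.0)
        rec.traces[ChannelId.CVPmean].values[200:500] = 200.0
        rule = ScenarioRule(
            name="high cvp", description="",
            triggers=(
                TriggerSpec(channel=ChannelId.CVPmean, kind="absolute_sustained",
                            direction="above", threshold=16.0, duration_s=180.0),
            ),
        )
        assert len(eval_scenario(rec, rule)) >= 1
        filtered = eval_scenario(
            rec, rule, plausibility={ChannelId.CVPmean: (-5.0, 40.0)}
        )
        assert filtered == []
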