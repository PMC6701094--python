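"""Wind schedule, attenuation model, and the failure-threshold trial simulator."""

import numpy as np
import pytest
from scipy import stats

from windlodge.indices import (
    aggregate_reduction_index,
    cumulative_lodging_index,
    failure_wind_speed,
)
from windlodge.simulator import (
    AttenuationProfile,
    CultivarSimSpec,
    MixtureComponent,
    attenuate,
    build_wind_schedule,
    default_plant_distances,
    fig3_like_library,
    simulate_trial,
)
from windlodge.trial_data import Layer, ValidationError, build_distribution


class TestWindSchedule:
    def test_default_protocol(self):
        sched = build_wind_schedule()
        assert sched.speeds == (5, 10, 12, 14, 16, 18, 20, 22, 24, 26, 28, 30)
        holds = {lv.speed: lv.hold_duration for lv in sched.levels}
        assert holds[5] == 30 and holds[10] == 19 and holds[12] == 19

    def test_short_schedule(self):
        assert build_wind_schedule(max_speed=10).speeds == (5, 10)

    def test_non_divisible_range_clamps_final_level(self, caplog):
        with caplog.at_level("WARNING"):
            sched = build_wind_schedule(max_speed=29)
        assert sched.speeds[-1] == 29 and sched.speeds[-2] == 28
        assert "clamped" in caplog.text

    def test_max_below_changeover_rejected(self):
        with pytest.raises(ValidationError):
            build_wind_schedule(max_speed=8)


class TestAttenuation:
    def test_far_middle_layer_endpoint(self):
        out = attenuate(30, 7, Layer.MIDDLE, AttenuationProfile.default())
        assert out == pytest.approx(30 * (1 - 0.65))

    def test_identity_profile_passes_speed_through(self):
        assert attenuate(17.3, 5, Layer.TOP, AttenuationProfile.identity()) == 17.3

    def test_linear_midpoint_interpolation(self):
        out = attenuate(30, 4.5, Layer.BOTTOM, AttenuationProfile.default())
        assert out == pytest.approx(30 * (1 - (0.22 + 0.59) / 2))

    def test_below_near_anchor_uses_near_ri(self):
        profile = AttenuationProfile.default()
        assert profile.ri(1.0, Layer.BOTTOM) == 0.22

    def test_beyond_validated_range_rejected(self):
        with pytest.raises(ValidationError):
            attenuate(30, 7.5, Layer.MIDDLE, AttenuationProfile.default())

    def test_default_anchor_values(self):
        profile = AttenuationProfile.default()
        expected = {Layer.BOTTOM: (0.22, 0.59), Layer.MIDDLE: (0.02, 0.65), Layer.TOP: (0.02, 0.66)}
        for layer, (near, far) in expected.items():
            assert profile.ri(2.0, layer) == near
            assert profile.ri(7.0, layer) == far

    def test_decreasing_ri_with_distance_rejected(self):
        with pytest.raises(ValidationError):
            AttenuationProfile(
                anchors={
                    Layer.BOTTOM: (0.5, 0.2),
                    Layer.MIDDLE: (0.0, 0.5),
                    Layer.TOP: (0.0, 0.5),
                }
            )


def unimodal_spec(mean, sd=2.0, n=84, **kw):
    return CultivarSimSpec("sim", (MixtureComponent(1.0, mean, sd),), n_plants=n, **kw)


class TestSimulateTrial:
    schedule = build_wind_schedule()
    identity = AttenuationProfile.identity()

    def test_same_seed_is_bit_identical(self):
        spec = unimodal_spec(20)
        a = simulate_trial(spec, self.schedule, self.identity, seed=7)
        b = simulate_trial(spec, self.schedule, self.identity, seed=7)
        assert a == b
        c = simulate_trial(spec, self.schedule, self.identity, seed=8)
        assert a != c

    def test_plants_are_conserved(self, rng):
        for seed in rng.integers(0, 2**31, 10):
            spec = unimodal_spec(float(rng.uniform(10, 35)), n=50)
            trial = simulate_trial(spec, self.schedule, self.identity, seed=int(seed))
            assert sum(o.lodged_count for o in trial.observations) == 50

    def test_narrow_threshold_lodges_at_first_covering_level(self):
        spec = unimodal_spec(19.5, sd=1e-9, noise_sd=0.0)
        trial = simulate_trial(spec, self.schedule, self.identity, seed=1)
        counts = {o.level_speed: o.lodged_count for o in trial.observations if not o.is_censored}
        assert counts == {20.0: spec.n_plants}

    def test_unreachable_threshold_censors_everything(self):
        spec = unimodal_spec(100)
        trial = simulate_trial(spec, self.schedule, self.identity, seed=1)
        censored = [o for o in trial.observations if o.is_censored]
        assert censored[0].lodged_count == spec.n_plants

    def test_level_fractions_match_normal_cdf_oracle(self):
        """Lodged fraction per level ~ CDF increments at level boundaries."""
        mu, sd, n = 20.0, 2.0, 1000
        spec = unimodal_spec(mu, sd=sd, n=n)
        trial = simulate_trial(spec, self.schedule, self.identity, seed=123)
        counts = {o.level_speed: o.lodged_count for o in trial.observations if not o.is_censored}
        prev = -np.inf
        for level in self.schedule.speeds:
            p = stats.norm.cdf(level, mu, sd) - stats.norm.cdf(prev, mu, sd)
            observed = counts.get(level, 0)
            tolerance = 3 * np.sqrt(n * p * (1 - p)) + 1
            assert abs(observed - n * p) <= tolerance, f"level {level}"
            prev = level

    def test_attenuation_shifts_lodging_to_higher_generated_speeds(self):
        spec = unimodal_spec(15, n=200)
        plain = simulate_trial(spec, self.schedule, self.identity, seed=5)
        damped = simulate_trial(spec, self.schedule, AttenuationProfile.default(), seed=5)
        mean_level = lambda t: np.average(
            [o.level_speed for o in t.observations if not o.is_censored],
            weights=[o.lodged_count for o in t.observations if not o.is_censored],
        )
        # with the default profile the local speed is far below the generated
        # speed, so lodging happens later (or not at all)
        damped_lodged = sum(
            o.lodged_count for o in damped.observations if not o.is_censored
        )
        assert damped_lodged < 200
        if damped_lodged:
            assert mean_level(damped) > mean_level(plain)

    def test_anemometer_log_covers_every_hold_second(self):
        spec = unimodal_spec(20, n=5, noise_sd=0.0)
        trial = simulate_trial(spec, self.schedule, self.identity, seed=2)
        outlet = [r for r in trial.anemometer if r.layer is Layer.OUTLET]
        assert len(outlet) == int(self.schedule.total_duration)
        # noise-free: outlet samples equal the generated level exactly
        for start, end, level in self.schedule.hold_windows():
            window = [r.speed for r in outlet if start <= r.time < end]
            assert window == [level.speed] * int(level.hold_duration)

    def test_ri_recovered_from_noise_free_logs(self):
        """aggregate_reduction_index inverts the attenuation model exactly."""
        profile = AttenuationProfile.default()
        spec = unimodal_spec(20, n=5, noise_sd=0.0)
        trial = simulate_trial(spec, self.schedule, profile, seed=3)
        for layer in (Layer.BOTTOM, Layer.MIDDLE, Layer.TOP):
            results = aggregate_reduction_index(
                trial.anemometer, trial.anemometer, layer, self.schedule
            )
            expected = profile.ri(profile.d_far, layer)
            for r in results:
                assert r.ri == pytest.approx(expected, abs=1e-12)

    def test_knockdown_contagion_increases_lodging(self):
        base = unimodal_spec(28, n=200)
        contagious = unimodal_spec(28, n=200, knockdown_prob=0.5)
        lodged = lambda t: sum(
            o.lodged_count for o in t.observations if not o.is_censored
        )
        a = simulate_trial(base, self.schedule, self.identity, seed=11)
        b = simulate_trial(contagious, self.schedule, self.identity, seed=11)
        assert lodged(b) >= lodged(a)

    def test_default_plant_distances_fill_two_rows(self):
        d = default_plant_distances(84)
        assert len(d) == 84 and max(d) == pytest.approx(7.0) and min(d) > 0


class TestParameterRecovery:
    def test_fws_tracks_threshold_mean(self):
        """FWS of a simulated unimodal cultivar sits within one schedule step of mu."""
        schedule = build_wind_schedule()
        identity = AttenuationProfile.identity()
        for mu in (16.0, 20.0, 24.0):
            spec = unimodal_spec(mu, n=1000)
            hits = 0
            n_rep = 20
            for seed in range(n_rep):
                trial = simulate_trial(spec, schedule, identity, seed=1000 + seed)
                dist = build_distribution(trial.observations, s_max=schedule.max_speed)
                fws = failure_wind_speed(dist)
                if not fws.censored and abs(fws.value - mu) <= 2.0:
                    hits += 1
            assert hits >= int(0.95 * n_rep), f"mu={mu}: {hits}/{n_rep}"

    def test_raising_threshold_mean_raises_cli(self):
        schedule = build_wind_schedule()
        identity = AttenuationProfile.identity()
        clis = {}
        for mu in (18.0, 24.0):
            values = []
            for seed in range(50):
                trial = simulate_trial(
                    unimodal_spec(mu, n=84), schedule, identity, seed=300 + seed
                )
                dist = build_distribution(trial.observations, s_max=30)
                values.append(cumulative_lodging_index(dist))
            clis[mu] = np.mean(values)
        assert clis[24.0] > clis[18.0]


class TestPresetLibrary:
    def test_presets_have_expected_names_and_valid_mixtures(self):
        lib = fig3_like_library()
        assert len(lib) == 6
        for spec in lib.values():
            assert abs(sum(c.weight for c in spec.components) - 1.0) < 1e-9

    def test_mostly_censored_preset_rarely_lodges(self):
        lib = fig3_like_library()
        spec = CultivarSimSpec(
            "jd", lib["mostly_censored"].components, n_plants=500
        )
        trial = simulate_trial(
            spec, build_wind_schedule(), AttenuationProfile.identity(), seed=42
        )
        dist = build_distribution(trial.observations, s_max=30)
        assert dist.censored_mass > 0.9

    def test_bimodal_preset_has_two_modes(self):
        lib = fig3_like_library()
        spec = CultivarSimSpec(
            "xd", lib["bimodal_12_24"].components, n_plants=1000
        )
        trial = simulate_trial(
            spec, build_wind_schedule(), AttenuationProfile.identity(), seed=42
        )
        dist = build_distribution(trial.observations, s_max=30)
        masses = dict(dist.bins)
        series = [masses.get(s, 0.0) for s in build_wind_schedule().speeds]
        maxima = sum(
            1
            for i in range(len(series))
            if series[i] > 0
            and (i == 0 or series[i] >= series[i - 1])
            and (i == len(series) - 1 or series[i] > series[i + 1])
        )
        assert maxima >= 2
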