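"""PSTH construction, rate–speed coupling, sensory responses and the
four-class PCA classification."""

import numpy as np
import pytest

from incerta import DegenerateInputError
from incerta import events as E
from incerta import synth
from incerta import units as U


@pytest.fixture(scope="module")
def classified_population(speed_profile_module=None):
    """16 units (4/class) on 300 s of movement, with detected speed peaks."""
    t, speed, _ = synth.gen_speed_profile(300.0, fs=50.0, seed=11)
    profs = synth.default_class_profiles()
    trains, truth = [], []
    k = 0
    for lab, p in profs.items():
        for r in range(4):
            trains.append(synth.gen_spike_train(p, t, speed, seed=400 + k,
                                                unit_id=f"{lab}-{r}"))
            truth.append(lab)
            k += 1
    ev = E.detect_peaks(speed, fps=50.0, kind="speed")
    return trains, truth, ev


class TestBuildPsth:
    def test_homogeneous_train_flat_psth(self):
        rng = np.random.default_rng(0)
        st = np.sort(rng.uniform(0, 600, 6000))     # ~10 spikes/s
        tr = U.SpikeTrain("u0", st)
        ev = np.arange(10.0, 590.0, 5.0)
        mat = U.build_psth([tr], ev, window=(-3, 3), bin_width=0.5)
        assert mat.rates.shape == (1, 12)
        assert np.allclose(mat.rates, 10.0, atol=1.5)

    def test_single_spike_count_arithmetic(self):
        ev = np.array([10.0, 20.0, 30.0, 40.0])
        tr = U.SpikeTrain("u0", np.array([20.0]))
        mat = U.build_psth([tr], ev, window=(-1, 1), bin_width=0.1)
        zero_bin = int(round(1.0 / 0.1))            # bin starting at 0
        assert mat.rates[0, zero_bin] == pytest.approx(1 / (4 * 0.1))
        assert mat.rates.sum() == pytest.approx(1 / (4 * 0.1))

    def test_empty_event_set_rejected(self):
        with pytest.raises(DegenerateInputError):
            U.build_psth([U.SpikeTrain("u", np.arange(10.0))], np.array([]))

    def test_window_must_cover_zero(self):
        with pytest.raises(DegenerateInputError):
            U.build_psth([U.SpikeTrain("u", np.arange(10.0))],
                         np.array([5.0]), window=(1.0, 3.0))

    def test_merged_psth_is_event_weighted_mean(self, classified_population):
        """PSTH over a merged event set equals the event-count-weighted
        mean of the per-subset PSTHs (exact identity)."""
        trains, _, ev = classified_population
        evA = ev.times[::2]
        evB = ev.times[1::2]
        m_all = U.build_psth(trains, ev.times, window=(-2, 2), bin_width=0.2)
        m_a = U.build_psth(trains, evA, window=(-2, 2), bin_width=0.2)
        m_b = U.build_psth(trains, evB, window=(-2, 2), bin_width=0.2)
        nA, nB = len(evA), len(evB)
        merged = (nA * m_a.rates + nB * m_b.rates) / (nA + nB)
        assert np.allclose(m_all.rates, merged, atol=1e-12)


class TestClassify:
    def test_recovers_generator_classes(self, classified_population):
        trains, truth, ev = classified_population
        mat = U.build_psth(trains, ev)
        res = U.classify_units(mat)
        acc = np.mean([r.label == tl for r, tl in zip(res, truth)])
        assert acc >= 0.85

    def test_each_unit_gets_exactly_one_label(self, classified_population):
        trains, _, ev = classified_population
        res = U.classify_units(U.build_psth(trains, ev))
        assert all(r.label in U.CLASS_LABELS for r in res)
        assert len(res) == len(trains)

    def test_invariant_to_unit_order(self, classified_population):
        trains, _, ev = classified_population
        mat = U.build_psth(trains, ev)
        res = {r.unit_id: r.label for r in U.classify_units(mat)}
        mat_rev = U.build_psth(trains[::-1], ev)
        res_rev = {r.unit_id: r.label for r in U.classify_units(mat_rev)}
        assert res == res_rev

    def test_invariant_to_common_rate_rescaling(self, classified_population):
        trains, _, ev = classified_population
        mat = U.build_psth(trains, ev)
        res = [r.label for r in U.classify_units(mat)]
        mat.rates = mat.rates * 3.7
        res_scaled = [r.label for r in U.classify_units(mat)]
        assert res == res_scaled

    def test_flat_population_refused(self):
        rates = np.full((10, 60), 5.0)
        mat = U.PSTHMatrix(rates=rates, bin_width=0.1, window=(-3.0, 3.0),
                           unit_ids=[f"u{i}" for i in range(10)],
                           n_events=np.full(10, 20))
        with pytest.raises(DegenerateInputError, match="flat"):
            U.classify_units(mat)

    def test_too_few_units_refused(self):
        rates = np.random.default_rng(0).poisson(5, (5, 60)).astype(float)
        mat = U.PSTHMatrix(rates=rates, bin_width=0.1, window=(-3.0, 3.0),
                           unit_ids=[f"u{i}" for i in range(5)],
                           n_events=np.full(5, 20))
        with pytest.raises(DegenerateInputError, match="8 units"):
            U.classify_units(mat)

    def test_lone_activated_unit_lands_on_movement_side(self):
        """One strongly movement-activated unit among weak ones must be
        assigned to the movement-activated (Class1) side."""
        t, speed, _ = synth.gen_speed_profile(300.0, fs=50.0, seed=3)
        profs = synth.default_class_profiles()
        trains = [synth.gen_spike_train(profs["Class2b"], t, speed,
                                        seed=i, unit_id=f"w{i}")
                  for i in range(9)]
        trains.append(synth.gen_spike_train(profs["Class1a"], t, speed,
                                            seed=99, unit_id="strong"))
        ev = E.detect_peaks(speed, fps=50.0, kind="speed")
        res = {r.unit_id: r.label for r in
               U.classify_units(U.build_psth(trains, ev))}
        assert res["strong"].startswith("Class1")


class TestRateSpeedCorrelation:
    def test_positive_coupling_positive_r(self, speed_profile,
                                          class_profiles):
        t, speed, _ = speed_profile
        tr = synth.gen_spike_train(class_profiles["Class1a"], t, speed, seed=5)
        r, slope = U.rate_speed_correlation(tr, t, speed)
        assert r > 0.3 and slope > 0

    def test_zero_coupling_ci_contains_zero(self, speed_profile):
        from incerta.resampling import windowed_pairs
        t, speed, _ = speed_profile
        prof = synth.ClassProfile("Class2b", 10.0, 0.0)
        tr = synth.gen_spike_train(prof, t, speed, seed=6)
        r, slope = U.rate_speed_correlation(tr, t, speed)
        assert abs(r) < 0.2
        # bootstrap CI of the windowed-slope via resampling windows
        edges = np.arange(t[0], t[-1], 0.2)
        counts, _ = np.histogram(tr.spike_times, bins=edges)
        xs, ys = windowed_pairs(t, speed, speed, 0.2)  # window means of speed
        rate = counts / 0.2
        n = min(len(rate), len(xs))
        rng = np.random.default_rng(0)
        boots = []
        for _ in range(500):
            i = rng.integers(0, n, n)
            sx, sy = xs[i], rate[:n][i]
            boots.append(np.polyfit(sx, sy, 1)[0])
        lo, hi = np.percentile(boots, [2.5, 97.5])
        assert lo < 0 < hi

    def test_constant_speed_rejected(self):
        tr = U.SpikeTrain("u", np.sort(np.random.default_rng(0)
                                       .uniform(0, 100, 500)))
        t = np.arange(0, 100, 0.02)
        with pytest.raises(DegenerateInputError, match="constant speed"):
            U.rate_speed_correlation(tr, t, np.full_like(t, 2.0))

    def test_too_short_support_rejected(self):
        tr = U.SpikeTrain("u", np.array([0.1, 0.5, 0.9]))
        t = np.arange(0, 1.0, 0.02)
        with pytest.raises(DegenerateInputError, match="10 windows"):
            U.rate_speed_correlation(tr, t, np.sin(t) ** 2)


class TestSensoryResponse:
    def test_stimulus_locked_bump_is_responsive(self):
        t = np.arange(0, 300, 0.02)
        stim = np.arange(10.0, 290.0, 5.0)
        prof = synth.ClassProfile("Class2b", 5.0, 0.0)
        tr = synth.gen_spike_train(prof, t, np.zeros_like(t), seed=0,
                                   stim_times=stim, stim_gain=40.0,
                                   stim_dur=0.5)
        res = U.sensory_response(tr, stim, response_window=(0.0, 1.5),
                                 baseline_window=(-1.5, 0.0), seed=0)
        assert res.responsive and res.evoked > 0

    def test_uncoupled_units_rarely_flagged(self):
        """Type-I contract: ≥ 90% of no-response units are non-responsive
        at the 95% bootstrap level."""
        t = np.arange(0, 320, 0.02)
        stim = np.arange(10.0, 310.0, 5.0)    # 60 stimuli per unit
        prof = synth.ClassProfile("Class2b", 8.0, 0.0)
        flags = [U.sensory_response(
            synth.gen_spike_train(prof, t, np.zeros_like(t), seed=k),
            stim, seed=k).responsive for k in range(40)]
        assert np.mean(flags) <= 0.1

    def test_zero_spikes_non_responsive(self):
        tr = U.SpikeTrain("silent", np.array([]))
        res = U.sensory_response(tr, np.arange(10.0, 60.0, 4.0), seed=0)
        assert res.evoked == 0.0 and not res.responsive

    def test_overlapping_windows_rejected(self):
        tr = U.SpikeTrain("u", np.arange(0.0, 50.0, 0.1))
        with pytest.raises(DegenerateInputError, match="overlap"):
            U.sensory_response(tr, np.arange(5.0, 45.0, 4.0),
                               response_window=(0.0, 1.5),
                               baseline_window=(-1.0, 0.5))
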