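"""Evoked-field quantification: preprocessing, N100m/SF measurement,
pooled statistics and the cross-validated model-to-field map."""

import numpy as np
import pytest
from scipy import stats

from tempasym.aef import (
    SourceWaveform,
    compare_conditions,
    correlate,
    cross_validate,
    fit_linear_map,
    hemisphere_contrast,
    measure_n100m,
    measure_sf,
    pooled_sample,
    preprocess_epoch,
    read_source_waveform,
    write_source_waveform,
)

EPOCH_T = -500.0 + np.arange(1901)


def make_epoch(samples, subject="S01", hemisphere="left", etype="ramped", hl=4.0):
    return SourceWaveform(subject, hemisphere, etype, hl, samples)


def gaussian_epoch(depth=-30.0, latency=100.0, sigma=15.0, sf=0.0):
    x = depth * np.exp(-0.5 * ((EPOCH_T - latency) / sigma) ** 2)
    if sf:
        x = x + sf * ((EPOCH_T > 300) & (EPOCH_T < 1000))
    return x


class TestPreprocess:
    def test_clean_epoch_unchanged(self):
        w = make_epoch(gaussian_epoch())
        out = preprocess_epoch(w)
        np.testing.assert_allclose(out.samples, w.samples, atol=1e-9)

    def test_constant_offset_removed_exactly(self):
        w = make_epoch(gaussian_epoch() + 17.0)
        out = preprocess_epoch(w)
        np.testing.assert_allclose(out.samples, gaussian_epoch(), atol=1e-9)

    def test_linear_drift_removed(self):
        slope = 0.02
        w = make_epoch(gaussian_epoch() + slope * (EPOCH_T + 500.0))
        out = preprocess_epoch(w)
        tail = out.samples[EPOCH_T >= 1300.0]
        residual_slope = np.polyfit(EPOCH_T[EPOCH_T >= 1300.0], tail, 1)[0]
        assert abs(residual_slope) < 0.05 * slope
        # baseline window mean restored to zero
        base = out.samples[(EPOCH_T >= -100) & (EPOCH_T <= 0)]
        assert abs(base.mean()) < 1e-9

    def test_short_epoch_rejected(self):
        with pytest.raises(ValueError):
            SourceWaveform("S01", "left", "ramped", 4.0, np.zeros(500))


class TestMeasureN100m:
    def test_recovers_injected_deflection(self):
        m = measure_n100m(make_epoch(gaussian_epoch(depth=-30.0, latency=100.0)))
        assert m.amplitude == pytest.approx(-30.0, abs=1e-6)
        assert m.latency_ms == pytest.approx(100.0, abs=1.0)
        assert not m.flagged

    def test_flat_epoch_flagged(self):
        m = measure_n100m(make_epoch(np.zeros(1901)))
        assert m.amplitude == 0.0
        assert m.flagged

    def test_tie_broken_to_earliest_latency(self):
        x = np.zeros(1901)
        x[EPOCH_T == 80.0] = -5.0
        x[EPOCH_T == 160.0] = -5.0
        m = measure_n100m(make_epoch(x))
        assert m.latency_ms == pytest.approx(80.0)


class TestMeasureSf:
    def test_constant_plateau_depth(self):
        x = np.zeros(1901)
        x[(EPOCH_T >= 700) & (EPOCH_T <= 1100)] = -20.0
        assert measure_sf(make_epoch(x)).depth == pytest.approx(-20.0)

    def test_zero_epoch_depth_zero(self):
        assert measure_sf(make_epoch(np.zeros(1901))).depth == 0.0

    def test_window_covers_201_samples(self):
        w = make_epoch(np.arange(1901, dtype=float) * 0 + 1.0)
        assert measure_sf(w).depth == pytest.approx(1.0)


class TestPooledSample:
    def waveforms(self, n_subjects):
        return [
            make_epoch(gaussian_epoch(depth=-20.0 - i), subject=f"S{i:02d}")
            for i in range(n_subjects)
        ]

    def test_n100m_pool_is_31_samples_per_subject(self):
        assert pooled_sample(self.waveforms(1), "n100m").size == 31
        assert pooled_sample(self.waveforms(27), "n100m").size == 837

    def test_sf_pool_is_201_samples_per_subject(self):
        assert pooled_sample(self.waveforms(27), "sf").size == 5427

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            pooled_sample(self.waveforms(1), "bogus")

    def test_inconsistent_rates_rejected(self):
        ws = self.waveforms(1)
        ws.append(
            SourceWaveform("S99", "left", "ramped", 4.0, np.zeros(3802), 2000.0)
        )
        with pytest.raises(ValueError):
            pooled_sample(ws, "n100m")


class TestStats:
    def test_identical_samples_not_significant(self):
        x = np.arange(50.0)
        _, p = compare_conditions(x, x)
        assert p == pytest.approx(1.0)

    def test_large_shift_highly_significant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, 100)
        b = rng.normal(5.0, 1.0, 100)
        _, p = compare_conditions(a, b)
        assert p < 1e-3

    def test_statistic_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        a = rng.random(40)
        b = rng.random(40) + 0.3
        s1, _ = compare_conditions(a, b)
        s2, _ = compare_conditions(np.exp(a), np.exp(b))
        assert s1 == pytest.approx(s2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions(np.array([]), np.arange(5.0))

    @pytest.mark.parametrize("slope, expected", [(2.0, 1.0), (-1.0, -1.0)])
    def test_perfect_linear_correlation(self, slope, expected):
        x = np.arange(10.0)
        r, _ = correlate(x, slope * x + 1.0)
        assert r == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate(np.ones(5), np.arange(5.0))


class TestLinearMap:
    def setup_series(self):
        t = np.arange(0.0, 1001.0)
        deriv = np.sin(t / 40.0)
        return deriv, t

    def test_exact_recovery_of_slope_and_intercept(self):
        deriv, t = self.setup_series()
        field = np.zeros(1901)
        mask = (EPOCH_T >= 0) & (EPOCH_T <= 1000)
        field[mask] = 3.0 * deriv - 7.0
        lm = fit_linear_map(deriv, t, make_epoch(field), center_ms=100.0)
        assert lm.slope == pytest.approx(3.0)
        assert lm.intercept == pytest.approx(-7.0)

    def test_noisy_recovery_within_fifteen_percent(self):
        deriv, t = self.setup_series()
        rng = np.random.default_rng(8)
        field = np.zeros(1901)
        mask = (EPOCH_T >= 0) & (EPOCH_T <= 1000)
        signal = 3.0 * deriv - 7.0
        field[mask] = signal + rng.normal(0.0, 0.1 * signal.std(), signal.size)
        lm = fit_linear_map(deriv, t, make_epoch(field), center_ms=100.0)
        assert lm.slope == pytest.approx(3.0, rel=0.15)
        assert lm.intercept == pytest.approx(-7.0, rel=0.15)

    def test_constant_derivative_rejected(self):
        _, t = self.setup_series()
        with pytest.raises(ValueError):
            fit_linear_map(np.ones(t.size), t, make_epoch(np.zeros(1901)), 100.0)


class TestCrossValidate:
    def make_subjects(self, n, identical=False):
        t = np.arange(0.0, 1001.0)
        deriv = np.sin(t / 40.0)
        rng = np.random.default_rng(4)
        subjects = {}
        for i in range(n):
            gain = 1.0 if identical else 1.0 + 0.2 * rng.standard_normal()
            field = gaussian_epoch(depth=-25.0 * gain)
            mask = (EPOCH_T >= 0) & (EPOCH_T <= 1000)
            field[mask] += gain * deriv
            subjects[f"S{i:02d}"] = make_epoch(field, subject=f"S{i:02d}")
        return subjects, deriv, t

    @pytest.mark.parametrize("n, folds", [(2, 2), (27, 702)])
    def test_fold_count_is_n_times_n_minus_one(self, n, folds):
        subjects, deriv, t = self.make_subjects(n)
        cv = cross_validate(subjects, deriv, t)
        assert cv.n_folds == folds

    def test_identical_subjects_give_identical_fold_errors(self):
        subjects, deriv, t = self.make_subjects(4, identical=True)
        cv = cross_validate(subjects, deriv, t)
        np.testing.assert_allclose(cv.fold_rmse, cv.fold_rmse[0], atol=1e-9)

    def test_single_subject_rejected(self):
        subjects, deriv, t = self.make_subjects(1)
        with pytest.raises(ValueError):
            cross_validate(subjects, deriv, t)


class TestHemisphereContrast:
    def make_set(self, boost=0.0):
        ws = []
        for subj in ("S01", "S02", "S03"):
            for hemi in ("left", "right"):
                for etype in ("ramped", "damped"):
                    for hl in (0.5, 1.0, 4.0, 16.0, 32.0):
                        depth = -20.0 - (2.0 if etype == "ramped" else 0.0)
                        if hemi == "right" and etype == "ramped" and hl == 4.0:
                            depth -= boost
                        ws.append(
                            make_epoch(
                                gaussian_epoch(depth=depth),
                                subject=subj,
                                hemisphere=hemi,
                                etype=etype,
                                hl=hl,
                            )
                        )
        return ws

    def test_identical_hemispheres_give_zero_differences(self):
        ai_by_hemi, diffs = hemisphere_contrast(self.make_set(boost=0.0))
        for (etype, hl), (delta, _p) in diffs.items():
            if etype == "ramped" and hl == 4.0:
                continue
            assert delta == pytest.approx(0.0, abs=1e-9)
        left = [r.ai for r in ai_by_hemi["left"]]
        right = [r.ai for r in ai_by_hemi["right"]]
        np.testing.assert_allclose(left, right)

    def test_right_boost_appears_only_at_4ms(self):
        ai_by_hemi, diffs = hemisphere_contrast(self.make_set(boost=6.0))
        ai_gap = {
            r.half_life_ms: right.ai - r.ai
            for r, right in zip(ai_by_hemi["left"], ai_by_hemi["right"])
        }
        assert max(ai_gap, key=lambda h: abs(ai_gap[h])) == 4.0
        delta, p = diffs[("ramped", 4.0)]
        assert delta > 0  # left minus right: right is deeper (more negative)
        assert p < 0.01

    def test_ai_antisymmetric_under_envelope_swap(self):
        ws = self.make_set()
        swapped = [
            SourceWaveform(
                w.subject,
                w.hemisphere,
                "ramped" if w.envelope_type == "damped" else "damped",
                w.half_life_ms,
                w.samples,
            )
            for w in ws
        ]
        ai_a, _ = hemisphere_contrast(ws)
        ai_b, _ = hemisphere_contrast(swapped)
        for hemi in ("left", "right"):
            for ra, rb in zip(ai_a[hemi], ai_b[hemi]):
                assert ra.ai == pytest.approx(-rb.ai)


def test_source_waveform_round_trip(tmp_path):
    w = make_epoch(gaussian_epoch(), subject="S07", hemisphere="right")
    path = write_source_waveform(w, tmp_path / "epoch.tsv")
    back = read_source_waveform(path)
    assert back.subject == "S07"
    assert back.hemisphere == "right"
    assert back.half_life_ms == 4.0
    np.testing.assert_allclose(back.samples, w.samples, rtol=1e-6)
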