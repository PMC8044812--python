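"""Signal-to-relaxivity conversion, voxel QC and bolus-window location."""

import numpy as np
import pytest

from dscleak import (
    AcquisitionWindow,
    DSCSeries,
    NumericalError,
    ReferenceCurve,
    RunConfig,
    ValidationError,
    build_reference_curve,
    discard_leading_volumes,
    estimate_baseline,
    locate_bolus_window,
    make_reference_curve,
    qc_sufficient_drop,
    select_nonenhancing_voxels,
    signal_to_relaxivity,
    simulate_case,
)


def _series(n_t: int) -> DSCSeries:
    sig = np.full((4, 4, 2, n_t), 100.0)
    return DSCSeries(signal=sig, tr_seconds=1.1, te_seconds=0.03)


def _window(n_t: int = 100) -> AcquisitionWindow:
    return AcquisitionWindow(baseline_end=20, t0=20, t1=40, n_timepoints=n_t)


class TestDiscardLeadingVolumes:
    @pytest.mark.parametrize("n_in,n_drop,n_out", [(120, 2, 118), (50, 2, 48), (60, 0, 60)])
    def test_counts(self, n_in, n_drop, n_out):
        out = discard_leading_volumes(_series(n_in), n_drop)
        assert out.n_timepoints == n_out
        assert out.discarded_leading_volumes == n_drop

    def test_too_few_remaining(self):
        with pytest.raises(ValidationError):
            discard_leading_volumes(_series(21), 2)


class TestEstimateBaseline:
    def test_constant_baseline(self):
        trace = np.r_[np.full(20, 7.0), np.zeros(80)]
        s0, sd = estimate_baseline(trace, _window())
        assert s0 == 7.0 and sd == 0.0

    def test_hand_mean(self):
        trace = np.r_[np.array([100, 102, 98, 100, 100.0]), np.zeros(95)]
        win = AcquisitionWindow(baseline_end=5, t0=20, t1=40, n_timepoints=100)
        s0, _ = estimate_baseline(trace, win)
        assert s0 == pytest.approx(100.0)

    def test_short_baseline_rejected(self):
        win = AcquisitionWindow(baseline_end=4, t0=20, t1=40, n_timepoints=100)
        with pytest.raises(ValidationError):
            estimate_baseline(np.zeros(100), win)


class TestSignalToRelaxivity:
    def test_baseline_signal_maps_to_zero(self):
        vals, clamped = signal_to_relaxivity(np.full(30, 50.0), 50.0, 0.03)
        assert np.allclose(vals, 0.0) and not clamped.any()

    def test_one_over_te_closed_form(self):
        s0, te = 200.0, 0.030
        vals, _ = signal_to_relaxivity(np.array([s0 * np.exp(-1)]), s0, te)
        assert vals[0] == pytest.approx(1 / te)  # 33.333... 1/s

    def test_overshoot_preserved_negative(self):
        s0, te = 100.0, 0.03
        vals, _ = signal_to_relaxivity(np.array([2 * s0]), s0, te)
        assert vals[0] == pytest.approx(-np.log(2) / te)

    def test_rescaling_invariance(self, rng):
        trace = rng.uniform(50, 150, 40)
        a, _ = signal_to_relaxivity(trace, 100.0, 0.03)
        b, _ = signal_to_relaxivity(7.0 * trace, 700.0, 0.03)
        assert np.allclose(a, b)

    def test_nonpositive_samples_clamped_and_flagged(self):
        vals, clamped = signal_to_relaxivity(np.array([100.0, 0.0, -5.0]), 100.0, 0.03)
        assert clamped.tolist() == [False, True, True]
        assert np.isfinite(vals).all()

    def test_nonpositive_s0_rejected(self):
        with pytest.raises(ValidationError):
            signal_to_relaxivity(np.ones(5), 0.0, 0.03)

    def test_inverse_of_forward_transform(self, clean_reference):
        """Round trip through the synthetic exponential transform is the
        identity on noiseless traces."""
        te, s0 = 0.03, 600.0
        signal = s0 * np.exp(-te * clean_reference.values)
        vals, _ = signal_to_relaxivity(signal, s0, te)
        assert np.max(np.abs(vals - clean_reference.values)) < 1e-9


class TestSufficientDrop:
    def test_drop_threshold_inequalities(self):
        trace = np.r_[np.full(20, 100.0), np.full(80, 89.0)]
        win = _window()
        assert qc_sufficient_drop(trace, 100.0, 2.0, win)
        trace2 = np.r_[np.full(20, 100.0), np.full(80, 91.0)]
        assert not qc_sufficient_drop(trace2, 100.0, 2.0, win)

    def test_noiseless_any_drop_counts(self):
        trace = np.r_[np.full(20, 100.0), np.full(80, 99.99)]
        assert qc_sufficient_drop(trace, 100.0, 0.0, _window())
        assert not qc_sufficient_drop(np.full(100, 100.0), 100.0, 0.0, _window())


class TestNonenhancingSelection:
    def test_phantom_regions(self, noiseless_spec, config):
        case = simulate_case(noiseless_spec)
        window = locate_bolus_window(case.reference, config)
        mask = select_nonenhancing_voxels(
            case.series.signal, case.vois.brain, window, config
        )
        # noiseless no-leakage brain: everything returns to baseline
        assert mask.sum() == case.vois.brain.sum()

    def test_elevated_tail_voxel_rejected(self, noiseless_spec, config):
        """A strong T2*-dominant leaky voxel keeps an elevated relaxivity
        tail, so its signal tail stays depressed below baseline."""
        from dscleak import simulate_voxel_signal

        case = simulate_case(noiseless_spec)
        ref = case.reference
        window = locate_bolus_window(ref, config)
        leaky = simulate_voxel_signal(
            ref.values, ref.time_step, k1=1.0, k2=-0.05, kep=0.0,
            s0=600.0, noise_sd=0.0, te_seconds=noiseless_spec.te_seconds,
        )
        signal = case.series.signal.copy()
        signal[2, 2, 0] = leaky
        mask = select_nonenhancing_voxels(signal, case.vois.brain, window, config)
        assert not mask[2, 2, 0]

    def test_constant_voxel_rejected_by_drop_rule(self, noiseless_spec, config):
        case = simulate_case(noiseless_spec)
        window = locate_bolus_window(case.reference, config)
        signal = case.series.signal.copy()
        signal[2, 2, 0] = 600.0
        mask = select_nonenhancing_voxels(signal, case.vois.brain, window, config)
        assert not mask[2, 2, 0]

    def test_low_noise_nawm_mostly_selected(self, config):
        """Tail criterion holds with probability -> 1 as noise vanishes when
        there is no steady-state plateau."""
        from dscleak import GammaParams, PhantomSpec

        spec = PhantomSpec(
            noise_sd=1e-3,
            gamma_params=GammaParams(recirculation_fraction=0.0, steady_state_level=0.0),
            seed=3,
        )
        case = simulate_case(spec)
        window = locate_bolus_window(case.reference, config)
        mask = select_nonenhancing_voxels(case.series.signal, case.vois.brain, window, config)
        nawm = case.vois.nawm
        assert mask[nawm].mean() > 0.9

    def test_empty_selection_raises(self, config):
        sig = np.full((12, 12, 2, 100), 100.0)  # no bolus anywhere
        brain = np.zeros((12, 12, 2), bool)
        brain[1:-1, 1:-1] = True
        with pytest.raises(NumericalError):
            select_nonenhancing_voxels(sig, brain, _window(), config)


class TestBuildReferenceCurve:
    def test_single_voxel_mask(self, rng):
        stack = rng.normal(size=(3, 3, 1, 40))
        mask = np.zeros((3, 3, 1), bool)
        mask[1, 1, 0] = True
        ref = build_reference_curve(stack, mask, 1.1)
        assert np.array_equal(ref.values, stack[1, 1, 0])
        assert ref.n_voxels_averaged == 1

    def test_opposite_curves_cancel(self, rng):
        c = rng.normal(size=40)
        stack = np.stack([c, -c])[:, None, None, :].reshape(2, 1, 1, 40)
        mask = np.ones((2, 1, 1), bool)
        ref = build_reference_curve(stack, mask, 1.0)
        assert np.allclose(ref.values, 0.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            build_reference_curve(np.zeros((2, 2, 1, 30)), np.zeros((2, 2, 1), bool), 1.0)

    def test_weighted_mean_property(self, rng):
        """Averaging over a union of disjoint voxel sets equals the
        voxel-count-weighted mean of the subset averages."""
        stack = rng.normal(size=(6, 1, 1, 25))
        m1 = np.zeros((6, 1, 1), bool)
        m2 = np.zeros((6, 1, 1), bool)
        m1[:2] = True
        m2[2:] = True
        r1 = build_reference_curve(stack, m1, 1.0)
        r2 = build_reference_curve(stack, m2, 1.0)
        r12 = build_reference_curve(stack, m1 | m2, 1.0)
        weighted = (2 * r1.values + 4 * r2.values) / 6
        assert np.allclose(r12.values, weighted)

    def test_noiseless_phantom_reference_recovered(self, noiseless_spec, config):
        """Forward/inverse consistency: the reference rebuilt from noiseless
        unit-K1 voxels equals the generating curve to 1e-6 1/s."""
        case = simulate_case(noiseless_spec)
        sig = case.series.signal
        window = locate_bolus_window(case.reference, config)
        s0, _ = estimate_baseline(sig, window)
        mask = select_nonenhancing_voxels(sig, case.vois.brain, window, config)
        relax = np.full(sig.shape, np.nan)
        relax[mask], _ = signal_to_relaxivity(sig[mask], s0[mask], noiseless_spec.te_seconds)
        ref = build_reference_curve(relax, mask, noiseless_spec.tr_seconds)
        assert np.max(np.abs(ref.values - case.reference.values)) < 1e-6


class TestLocateBolusWindow:
    def test_noiseless_gamma_arrival_index(self, clean_reference, config):
        win = locate_bolus_window(clean_reference, config)
        assert abs(win.t0 - 20) <= 1
        assert win.baseline_end <= win.t0
        peak = int(np.argmax(clean_reference.values))
        assert win.t0 < peak < win.t1

    def test_symmetric_triangle_window_symmetric_about_peak(self, config):
        v = np.zeros(80)
        peak_idx = 40
        v[25:41] = np.linspace(0, 10, 16)
        v[40:56] = np.linspace(10, 0, 16)
        win = locate_bolus_window(ReferenceCurve(values=v, time_step=1.0), config)
        assert abs((peak_idx - win.t0) - (win.t1 - peak_idx)) <= 2

    def test_flat_curve_rejected(self, config):
        with pytest.raises(NumericalError):
            locate_bolus_window(ReferenceCurve(values=np.zeros(100), time_step=1.0), config)

    def test_short_tail_uses_post_bolus_points(self, config):
        """When fewer than the configured tail points remain after t1, all
        post-bolus points form the tail."""
        spec_curve = make_reference_curve(
            __import__("dscleak").PhantomSpec(
                n_timepoints=45,
                gamma_params=__import__("dscleak").GammaParams(
                    arrival_index=15, recirculation_fraction=0.0, steady_state_level=0.0
                ),
            )
        )
        win = locate_bolus_window(spec_curve, config)
        assert win.tail[0] == max(win.t1 + 1, 45 - config.tail_points)
        assert win.tail[-1] == 44
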