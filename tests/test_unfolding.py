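"""Worm-like chain evaluation and fitting, sawtooth peak detection,
contour-increment classification and trace acceptance."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from forcespec.simulate import (
    UnfoldingSimConfig,
    simulate_unfolding_population,
    simulate_unfolding_trace,
)
from forcespec.unfolding import (
    AcceptanceRules,
    ClassificationWindows,
    EdgeFitError,
    SawtoothModel,
    UnfoldingEvent,
    WLCParams,
    accept_trace,
    classify_event,
    detect_sawtooth_peaks,
    fit_edge_wlc,
    summarize_unfolding,
    wlc_force,
    wlc_inverse,
)


class TestWLC:
    def test_zero_extension_zero_force(self):
        assert wlc_force(0.0, 100.0, WLCParams()) == 0.0

    def test_half_extension_printed_value(self):
        # (kBT/p) * 1.25 with p = 0.4 nm at 298 K
        assert wlc_force(50.0, 100.0, WLCParams()) == pytest.approx(12.86, abs=0.01)

    @given(st.floats(min_value=0.01, max_value=0.98))
    def test_strictly_increasing(self, xi):
        p = WLCParams()
        assert wlc_force((xi + 0.01) * 100.0, 100.0, p) > wlc_force(xi * 100.0, 100.0, p)

    def test_divergence_near_contour_length(self):
        p = WLCParams()
        assert wlc_force(99.99, 100.0, p) > 1e4 * wlc_force(50.0, 100.0, p) / 13

    def test_domain_error_beyond_contour(self):
        with pytest.raises(ValueError):
            wlc_force(100.0, 100.0, WLCParams())

    def test_inverse_round_trip(self):
        p = WLCParams()
        for f in (1.0, 10.0, 100.0, 400.0):
            x = wlc_inverse(f, 60.0, p)
            assert wlc_force(x, 60.0, p) == pytest.approx(f, rel=1e-9)


class TestEdgeFit:
    def _edge(self, Lc, n=60, fmax_frac=0.93, noise=0.0, rng=None):
        p = WLCParams()
        x = np.linspace(0.05 * Lc, fmax_frac * Lc, n)
        f = wlc_force(x, Lc, p)
        if noise and rng is not None:
            f = f + rng.normal(0, noise, size=n)
        return x, f

    def test_noiseless_recovery(self):
        x, f = self._edge(88.2)
        Lc, rss = fit_edge_wlc(x, f, WLCParams())
        assert Lc == pytest.approx(88.2, rel=5e-3)
        assert rss < 1e-6

    def test_short_edge_discarded(self):
        x, f = self._edge(88.2, n=5)
        with pytest.raises(EdgeFitError):
            fit_edge_wlc(x, f, WLCParams())

    def test_resampling_invariance(self):
        x1, f1 = self._edge(70.0, n=40)
        x2, f2 = self._edge(70.0, n=80)
        Lc1, _ = fit_edge_wlc(x1, f1, WLCParams())
        Lc2, _ = fit_edge_wlc(x2, f2, WLCParams())
        assert Lc1 == pytest.approx(Lc2, rel=1e-3)

    def test_bracketed_fit_matches_grid_oracle(self, rng):
        # exhaustive 0.01 nm grid search as the independent oracle
        p = WLCParams()
        for _ in range(50):
            Lc_true = float(rng.uniform(40.0, 250.0))
            x, f = self._edge(Lc_true, n=50, noise=3.0, rng=rng)
            keep = f > 2.0
            x, f = x[keep], f[keep]
            if x.size < 8:
                continue
            Lc_fit, _ = fit_edge_wlc(x, f, p)
            grid = np.arange(x.max() * 1.000001, x.max() * 3.0, 0.01)
            scale = p.kbt_pn_nm / p.persistence_length_nm
            xi = x[None, :] / grid[:, None]
            rss = (((0.25 * (1 - xi) ** -2 - 0.25 + xi) * scale - f[None, :]) ** 2).sum(axis=1)
            Lc_grid = grid[np.argmin(rss)]
            assert abs(Lc_fit - Lc_grid) <= 0.02


class TestClassification:
    @pytest.mark.parametrize(
        "inc,label",
        [(30.4, "FLNA"), (27.3, "I27"), (28.85, "unclassified"), (40.0, "unclassified")],
    )
    def test_windows(self, inc, label):
        assert classify_event(inc) == label

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ClassificationWindows(flna_center=29.0, i27_center=27.3, half_width=1.5)


def _event(label, force, order, inc=None):
    inc = inc if inc is not None else (30.4 if label == "FLNA" else 27.3)
    return UnfoldingEvent(
        peak_force_pn=force,
        contour_length_nm=0.0,
        increment_nm=inc,
        extension_at_peak_nm=0.0,
        fit_rss=0.0,
        label=label,
        order_index=order,
    )


class TestAcceptance:
    def test_clean_trace_accepted(self):
        events = [_event("FLNA", 60.0, 0)] + [_event("I27", 250.0, i) for i in range(1, 8)]
        res = accept_trace(events)
        assert res.accepted
        assert res.events[0].order_index == 0

    def test_too_few_events_rejected(self):
        events = [_event("I27", 250.0, i) for i in range(2)]
        res = accept_trace(events)
        assert not res.accepted
        assert res.rejection_reason == "too_few_events"

    def test_ordering_violation_rejected(self):
        events = [_event("I27", 250.0, i) for i in range(4)] + [_event("FLNA", 60.0, 4)]
        res = accept_trace(events)
        assert not res.accepted
        assert res.rejection_reason == "ordering_violation"

    def test_rules_switchable(self):
        events = [_event("I27", 250.0, i) for i in range(2)]
        rules = AcceptanceRules(enforce_min_i27=False)
        assert accept_trace(events, rules).accepted


class TestDetection:
    def test_noiseless_trace_detects_all_domains(self, rng):
        cfg = UnfoldingSimConfig(n_traces=1, noise_sd_pn=0.0, seed=5)
        c = simulate_unfolding_trace(cfg, rng, "t")
        res = SawtoothModel(c).fit()
        assert len(res.events) == 8  # 3+1+4 domains; detachment excluded

    def test_flat_trace_empty(self):
        z = np.arange(0.0, 800.0, 0.4)
        peaks = detect_sawtooth_peaks(z, np.zeros_like(z), noise_sd_pn=1.0)
        assert peaks == []

    def test_noisy_detection_sensitivity_and_no_spurious(self):
        cfg = UnfoldingSimConfig(n_traces=100, noise_sd_pn=5.0, seed=8)
        curves, _ = simulate_unfolding_population(cfg)
        found, total, spurious = 0, 0, 0
        for c in curves:
            truth = json.loads(c.annotations["events_json"])
            res = SawtoothModel(c).fit()
            true_pos = [e["s_nm"] for e in truth]
            total += len(true_pos)
            matched = set()
            for ev in res.events:
                # event extension maps back to a pull distance near the rupture
                d = [abs(ev.extension_at_peak_nm + ev.peak_force_pn / 10.0 - s) for s in true_pos]
                j = int(np.argmin(d))
                if d[j] < 10.0 and j not in matched:
                    matched.add(j)
                    found += 1
                else:
                    spurious += 1
            assert len(res.events) <= len(true_pos)
        assert found / total >= 7 / 8
        assert spurious == 0

    def test_peak_forces_close_to_truth(self):
        cfg = UnfoldingSimConfig(n_traces=30, noise_sd_pn=5.0, seed=12)
        curves, _ = simulate_unfolding_population(cfg)
        errs = []
        for c in curves:
            truth = {round(e["Lc_after_nm"], 1): e["force_pN"] for e in json.loads(c.annotations["events_json"])}
            res = SawtoothModel(c).fit()
            for ev in res.events:
                key = min(truth, key=lambda k: abs(k - ev.contour_length_nm))
                if abs(key - ev.contour_length_nm) < 3.0:
                    errs.append(abs(ev.peak_force_pn - truth[key]))
        assert np.mean(errs) < 2 * cfg.noise_sd_pn


class TestSummaries:
    def test_rate_monotonicity_across_speeds(self):
        traces = []
        for speed in (400.0, 800.0, 1600.0):
            cfg = UnfoldingSimConfig(
                pulling_speed_nm_s=speed,
                sampling_rate_hz=4096.0 if speed >= 1000 else 1024.0,
                n_traces=40,
                seed=6,
                noise_sd_pn=5.0,
            )
            curves, _ = simulate_unfolding_population(cfg)
            traces.extend(SawtoothModel(c).fit() for c in curves)
        table = summarize_unfolding(traces)
        i27 = table[table["label"] == "I27"].sort_values("pulling_speed_nm_s")
        assert i27["force_mean_pN"].is_monotonic_increasing
        flna = table[table["label"] == "FLNA"].sort_values("pulling_speed_nm_s")
        assert flna["force_mean_pN"].is_monotonic_increasing

    def test_single_trace_counts(self, rng):
        cfg = UnfoldingSimConfig(n_traces=1, noise_sd_pn=0.0, seed=5)
        c = simulate_unfolding_trace(cfg, rng, "t")
        res = SawtoothModel(c).fit()
        table = summarize_unfolding([res], accepted_only=False)
        counts = dict(zip(table["label"], table["n"]))
        assert counts == {"FLNA": 1, "I27": 7}
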