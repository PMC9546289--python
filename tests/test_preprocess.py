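"""Baseline removal, contact-point detection and indentation-axis recovery
against simulator ground truth."""

import numpy as np
import pytest

from forcespec.curves import ForceCurve, Segment
from forcespec.preprocess import (
    Baseline,
    BaselineError,
    NoContactError,
    compute_indentation,
    estimate_baseline,
    find_contact_point,
    process_curve,
    qc_curve,
    QCThresholds,
)
from forcespec.simulate import IndentationSimConfig, simulate_indentation_curve


def _manual_curve(z, f, k=120.0):
    return ForceCurve(
        segments=[Segment("approach", np.asarray(z, float), np.asarray(f, float), 4096.0)],
        spring_constant=k,
        velocity=5000.0,
        temperature=310.0,
        mode="indentation",
        curve_id="manual",
    )


SAMPLE_NM = 5000.0 / 4096.0  # piezo spacing at the default speed and rate


class TestBaseline:
    def test_flat_zero_curve(self):
        z = np.linspace(5000, 0, 2000)
        c = _manual_curve(z, np.zeros_like(z))
        b = estimate_baseline(c)
        assert b.offset_pn == pytest.approx(0.0, abs=1e-12)
        assert b.tilt_pn_per_nm == pytest.approx(0.0, abs=1e-15)
        assert b.noise_sd_pn == pytest.approx(0.0, abs=1e-12)

    def test_recovers_injected_tilt_exactly_without_noise(self, rng):
        cfg = IndentationSimConfig(noise_sd_pn=0.0, baseline_tilt_range_pn_per_nm=0.05)
        c = simulate_indentation_curve(2.0, cfg, rng, "c")
        tilt_true = float(c.annotations["true_tilt_pN_per_nm"])
        b = estimate_baseline(c)
        assert b.tilt_pn_per_nm == pytest.approx(tilt_true, abs=1e-9)

    def test_noise_sd_recovered(self, rng):
        z = np.linspace(5000, 0, 2000)
        f = rng.normal(0.0, 5.0, size=z.size)
        b = estimate_baseline(_manual_curve(z, f))
        assert b.noise_sd_pn == pytest.approx(5.0, rel=0.15)

    def test_too_few_noncontact_samples(self):
        z = np.linspace(100, 0, 12)
        with pytest.raises(BaselineError, match="non-contact"):
            estimate_baseline(_manual_curve(z, np.zeros_like(z)), fraction_noncontact=0.2)


class TestContactPoint:
    def test_noiseless_recovery_within_one_sample(self, noiseless_indent_cfg, rng):
        for _ in range(5):
            c = simulate_indentation_curve(2.0, noiseless_indent_cfg, rng, "c")
            z0_true = float(c.annotations["true_contact_nm"])
            b = estimate_baseline(c)
            z0 = find_contact_point(c, b)
            assert abs(z0 - z0_true) <= SAMPLE_NM

    def test_noisy_recovery_within_20nm_for_95pct(self):
        cfg = IndentationSimConfig(noise_sd_pn=5.0, seed=21)
        rng = np.random.default_rng(cfg.seed)
        errors = []
        for i in range(200):
            c = simulate_indentation_curve(2.0, cfg, rng, f"c{i}")
            z0_true = float(c.annotations["true_contact_nm"])
            z0 = find_contact_point(c, estimate_baseline(c))
            errors.append(abs(z0 - z0_true))
        assert np.mean(np.array(errors) <= 20.0) >= 0.95

    def test_flat_curve_raises_no_contact(self):
        z = np.linspace(5000, 0, 2000)
        c = _manual_curve(z, np.zeros_like(z))
        with pytest.raises(NoContactError):
            find_contact_point(c, estimate_baseline(c))


class TestIndentation:
    def test_rigid_substrate_gives_zero_indentation(self):
        k = 120.0
        z = np.linspace(3000, 0, 2000)
        z0 = 1500.0
        f = np.where(z < z0, k * (z0 - z), 0.0)
        c = _manual_curve(z, f, k=k)
        p = compute_indentation(c, z0, Baseline(0.0, 0.0, 0.0))
        assert np.all(np.abs(p.indentation) < 1e-9)

    def test_deflection_correction_arithmetic(self):
        # delta = (z0 - z) - F/k = 600 - 100/120
        z0, z, F, k = 600.0, 0.0, 100.0, 120.0
        c = _manual_curve([700.0, z], [0.0, F], k=k)
        p = compute_indentation(c, z0, Baseline(0.0, 0.0, 0.0))
        assert p.indentation[-1] == pytest.approx(600.0 - 100.0 / 120.0, abs=1e-9)

    def test_noiseless_curve_satisfies_contact_law(self, noiseless_indent_cfg, rng):
        from forcespec.elasticity import hertz_sneddon_force

        cfg = noiseless_indent_cfg
        c = simulate_indentation_curve(2.0, cfg, rng, "c")
        p = process_curve(c)
        mask = p.indentation > 20.0  # contact-point rounding dominates below
        expected = hertz_sneddon_force(2.0, cfg.geometry, p.indentation[mask])
        np.testing.assert_allclose(p.post_contact_force[mask], expected, rtol=1e-3)

    def test_invalid_spring_constant(self):
        c = _manual_curve([700.0, 0.0], [0.0, 10.0])
        with pytest.raises(ValueError):
            compute_indentation(c, 600.0, Baseline(0.0, 0.0, 0.0), spring_constant=0.0)


class TestQC:
    def test_clean_curve_passes(self, rng):
        cfg = IndentationSimConfig(noise_sd_pn=5.0)
        c = simulate_indentation_curve(2.0, cfg, rng, "c")
        p = process_curve(c)
        assert p.qc.passed, p.qc.reasons

    def test_excessive_noise_flagged(self, rng):
        cfg = IndentationSimConfig(noise_sd_pn=250.0)
        c = simulate_indentation_curve(2.0, cfg, rng, "c")
        p = process_curve(c)
        assert not p.qc.passed
        assert "excessive_noise" in p.qc.reasons

    def test_flat_curve_flagged_no_contact(self):
        z = np.linspace(5000, 0, 2000)
        p = process_curve(_manual_curve(z, np.zeros_like(z)))
        assert not p.qc.passed
        assert "no_contact" in p.qc.reasons

    def test_drift_flagged(self):
        z = np.linspace(5000, 0, 2000)
        f = 1.0 * (5000.0 - z)  # 1 pN/nm tilt, far above the drift threshold
        f[z < 1000] += 0.002 * (1000 - z[z < 1000]) ** 2
        p = process_curve(_manual_curve(z, f))
        assert "drift" in p.qc.reasons

    def test_reasons_and_passed_consistent(self):
        z = np.linspace(5000, 0, 2000)
        p = process_curve(_manual_curve(z, np.zeros_like(z)))
        assert p.qc.passed == (not p.qc.reasons)


class TestEndToEnd:
    def test_precontact_mean_statistically_zero(self):
        cfg = IndentationSimConfig(noise_sd_pn=5.0, seed=31)
        rng = np.random.default_rng(cfg.seed)
        for i in range(20):
            c = simulate_indentation_curve(2.0, cfg, rng, f"c{i}")
            p = process_curve(c)
            pre = p.corrected_force[p.height > p.contact_point + 50.0]
            se = pre.std(ddof=1) / np.sqrt(pre.size)
            assert abs(pre.mean()) <= 2.5 * se + 1e-9

    def test_idempotence_of_baseline_correction(self, rng):
        cfg = IndentationSimConfig(noise_sd_pn=5.0)
        c = simulate_indentation_curve(2.0, cfg, rng, "c")
        p1 = process_curve(c)
        c2 = ForceCurve(
            segments=[Segment("approach", p1.height, p1.corrected_force, 4096.0)],
            spring_constant=c.spring_constant,
            velocity=c.velocity,
            temperature=c.temperature,
            mode="indentation",
            curve_id="reprocessed",
        )
        p2 = process_curve(c2)
        # second pass should change the corrected force by less than the noise
        diff = np.abs(p2.corrected_force - p1.corrected_force)
        assert diff.max() < p1.noise_sd_estimate
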