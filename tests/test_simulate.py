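"""Synthetic-generator ground truth: determinism, forward-model exactness,
lognormal population parameterization and kinetic Monte Carlo kinetics."""

import json
import math

import numpy as np
import pytest

from forcespec.constants import kbt
from forcespec.elasticity import hertz_sneddon_force
from forcespec.simulate import (
    AdhesionSimConfig,
    BellEvansParams,
    FLNA_INCREMENT_NM,
    I27_BELL_EVANS,
    I27_INCREMENT_NM,
    IndentationSimConfig,
    UnfoldingSimConfig,
    bell_evans_most_probable_force,
    bell_evans_wlc_force,
    default_domain_layout,
    lognormal_mu_for_mode,
    simulate_adhesion_curve,
    simulate_indentation_curve,
    simulate_indentation_population,
    simulate_unfolding_trace,
    simulate_unfolding_population,
    true_event_frame,
)
from forcespec.stats import summarize
from forcespec.unfolding import WLCParams


class TestIndentationSim:
    def test_forward_model_matches_contact_law(self, geometry20):
        # direct evaluation of the pyramidal contact law at 500 nm
        assert hertz_sneddon_force(2.0, geometry20, 500.0) == pytest.approx(171.6, abs=0.1)

    def test_precontact_force_identically_zero_when_noiseless(self, noiseless_indent_cfg, rng):
        c = simulate_indentation_curve(2.0, noiseless_indent_cfg, rng, "c")
        z0 = float(c.annotations["true_contact_nm"])
        pre = c.approach.force[c.approach.height > z0]
        assert np.all(pre == 0.0)

    def test_post_contact_follows_contact_law_in_indentation(self, noiseless_indent_cfg, rng):
        cfg = noiseless_indent_cfg
        c = simulate_indentation_curve(3.0, cfg, rng, "c")
        z0 = float(c.annotations["true_contact_nm"])
        z, f = c.approach.height, c.approach.force
        post = f > 0
        delta = (z0 - z[post]) - f[post] / cfg.spring_constant_pn_nm
        expected = hertz_sneddon_force(3.0, cfg.geometry, delta)
        np.testing.assert_allclose(f[post], expected, rtol=1e-9)

    def test_same_seed_identical_curve(self):
        cfg = IndentationSimConfig(seed=7)
        a = simulate_indentation_curve(2.0, cfg, np.random.default_rng(7), "a")
        b = simulate_indentation_curve(2.0, cfg, np.random.default_rng(7), "b")
        np.testing.assert_array_equal(a.approach.force, b.approach.force)
        np.testing.assert_array_equal(a.approach.height, b.approach.height)

    def test_population_counts_and_degenerate_sigma(self):
        cfg = IndentationSimConfig(n_cells=50, curves_per_cell=10, modulus_sigma=1e-12, seed=1)
        curves, truth = simulate_indentation_population(cfg)
        assert len(curves) == 500
        assert len(truth) == 50
        np.testing.assert_allclose(truth["true_E_kPa"], cfg.modulus_mode_kpa, rtol=1e-6)

    def test_lognormal_mode_parameterization(self):
        # Monte Carlo vs the closed-form mode exp(mu - sigma^2)
        mode, sigma = 1.88, 0.5
        rng = np.random.default_rng(0)
        draws = np.exp(rng.normal(lognormal_mu_for_mode(mode, sigma), sigma, size=100_000))
        fitted = summarize(draws).lognormal.mode
        assert fitted == pytest.approx(mode, rel=0.03)


class TestAdhesionSim:
    def test_triangular_work_matches_target(self, rng):
        cfg = AdhesionSimConfig(noise_sd_pn=0.0, work_target_fj=1.0)
        c = simulate_adhesion_curve(cfg, rng, "a")
        assert float(c.annotations["true_work_fJ"]) == pytest.approx(1.0, rel=1e-3)

    def test_zero_work_gives_flat_retract(self, rng):
        cfg = AdhesionSimConfig(noise_sd_pn=0.0, work_target_fj=0.0)
        c = simulate_adhesion_curve(cfg, rng, "a")
        z = c.retract.height
        tail = c.retract.force[z > 600.0]  # past the contact unload
        assert np.all(tail == 0.0)

    def test_multi_rupture_has_sign_restoring_steps(self, rng):
        cfg = AdhesionSimConfig(profile="multi_rupture", rupture_count=3, noise_sd_pn=0.0)
        c = simulate_adhesion_curve(cfg, rng, "a")
        f = c.retract.force
        steps = np.diff(f)
        big_up = np.sum(steps > 30.0)
        assert big_up == 3
        assert float(c.annotations["true_work_fJ"]) == pytest.approx(
            cfg.work_target_fj, rel=1e-3
        )


class TestBellEvans:
    def test_most_probable_force_value(self):
        # direct evaluation at kBT = 4.114 pN nm
        p = BellEvansParams(k0_per_s=1e-4, delta_x_nm=0.25)
        f = bell_evans_most_probable_force(p, 1e4, 298.0)
        assert f == pytest.approx(257.0, abs=0.5)

    def test_rate_times_e_shifts_by_kbt_over_dx(self):
        p = BellEvansParams(k0_per_s=1e-3, delta_x_nm=0.3)
        f1 = bell_evans_most_probable_force(p, 5e3, 298.0)
        f2 = bell_evans_most_probable_force(p, 5e3 * math.e, 298.0)
        assert f2 - f1 == pytest.approx(kbt(298.0) / 0.3, rel=1e-9)

    def test_strictly_increasing_in_rate(self):
        p = BellEvansParams(k0_per_s=1e-3, delta_x_nm=0.3)
        forces = [bell_evans_most_probable_force(p, r, 298.0) for r in (1e2, 1e3, 1e4)]
        assert forces[0] < forces[1] < forces[2]

    def test_subthreshold_rate_raises(self):
        p = BellEvansParams(k0_per_s=1e6, delta_x_nm=0.1)
        with pytest.raises(ValueError):
            bell_evans_most_probable_force(p, 1.0, 298.0)


class TestUnfoldingSim:
    def test_flna_unfolds_first_in_nearly_all_traces(self):
        cfg = UnfoldingSimConfig(n_traces=100, seed=2, noise_sd_pn=0.0)
        curves, _ = simulate_unfolding_population(cfg)
        first = [json.loads(c.annotations["events_json"])[0]["domain"] for c in curves]
        assert np.mean([d == "FLNA" for d in first]) >= 0.95

    def test_doubling_speed_raises_mean_unfolding_force(self):
        means = {}
        for speed in (800.0, 1600.0):
            cfg = UnfoldingSimConfig(
                pulling_speed_nm_s=speed, n_traces=150, seed=5, noise_sd_pn=0.0
            )
            curves, _ = simulate_unfolding_population(cfg)
            ev = true_event_frame(curves)
            means[speed] = ev.groupby("domain")["force_pN"].mean()
        for domain in ("FLNA", "I27"):
            assert means[1600.0][domain] > means[800.0][domain]

    def test_inert_domain_never_unfolds(self, rng):
        dead = BellEvansParams(k0_per_s=1e-30, delta_x_nm=0.05)
        layout = [("I27", I27_INCREMENT_NM, I27_BELL_EVANS)] * 3 + [
            ("DEAD", 30.0, dead)
        ]
        cfg = UnfoldingSimConfig(domain_layout=layout, n_traces=1, seed=3, noise_sd_pn=0.0)
        c = simulate_unfolding_trace(cfg, rng)
        events = json.loads(c.annotations["events_json"])
        assert all(e["domain"] != "DEAD" for e in events)

    def test_seed_determinism_is_byte_identical(self, tmp_path):
        from forcespec.io import write_curve

        cfg = UnfoldingSimConfig(n_traces=1, seed=9)
        a = simulate_unfolding_trace(cfg, np.random.default_rng(9), "t")
        b = simulate_unfolding_trace(cfg, np.random.default_rng(9), "t")
        pa, pb = tmp_path / "a", tmp_path / "b"
        write_curve(a, pa)
        write_curve(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_kmc_matches_bell_evans_in_stiff_spring_limit(self):
        # single domain, stiff cantilever: mean simulated unfolding force vs
        # the self-consistent most-probable-force at the local loading rate
        be = BellEvansParams(k0_per_s=1e-3, delta_x_nm=0.2)
        cfg = UnfoldingSimConfig(
            domain_layout=[("X", 28.0, be)],
            spring_constant_pn_nm=1000.0,
            n_traces=2000,
            seed=4,
            noise_sd_pn=0.0,
            curve_length_nm=400.0,
        )
        curves, _ = simulate_unfolding_population(cfg)
        forces = true_event_frame(curves)["force_pN"].to_numpy()
        f_star = bell_evans_wlc_force(
            be,
            cfg.pulling_speed_nm_s,
            cfg.spring_constant_pn_nm,
            cfg.initial_contour_nm,
            WLCParams(cfg.persistence_length_nm, cfg.temperature_k),
        )
        assert forces.mean() == pytest.approx(f_star, rel=0.10)

    def test_default_layout_composition(self):
        layout = default_domain_layout()
        labels = [l for l, _, _ in layout]
        assert labels == ["I27"] * 3 + ["FLNA"] + ["I27"] * 4
        incs = {l: inc for l, inc, _ in layout}
        assert incs == {"I27": I27_INCREMENT_NM, "FLNA": FLNA_INCREMENT_NM}
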