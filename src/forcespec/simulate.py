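"""Synthetic force-curve generators with recorded ground truth.

Three curve classes replace the instrument:

* **Indentation** approach curves from cell populations whose Young's moduli
  are lognormally distributed (parameterized by the *mode*, the "most
  probable value", with mu = ln(mode) + sigma^2), forward-modelled through
  the Hertz-Sneddon pyramidal contact law with a drawn contact point,
  baseline tilt and additive Gaussian force noise.
* **Adhesion** retract curves whose negative-force region integrates, noise
  free, to a prescribed work of adhesion (triangular or multi-rupture
  profiles), with the detachment point recorded.
* **Unfolding** sawtooth traces of a polyprotein (default 3xI27 +
  FLNA repeat 22 + 4xI27) pulled at constant velocity: the instantaneous
  force solves the serial-WLC + cantilever force balance at the current
  released contour length, and each folded domain unfolds stochastically
  with the Bell-Evans rate k(F) = k0 * exp(F*dx/kBT) integrated over the
  trajectory (kinetic Monte Carlo).

Every generator records its ground truth in the curve annotations, making
parameter recovery testable end to end. Identical config + seed gives
byte-identical curves.

The Bell-Evans parameters of the default domain layouts are calibration
choices (k0 and dx are not measurable from mean forces alone): they were
chosen, via the self-consistent most-probable-force relation
F* = (kBT/dx) * ln(r(F*) dx / (k0 kBT)) with r(F) the local WLC+cantilever
loading rate, so that simulated unfolding-force distributions land near the
experimentally reported ranges (I27 ~215/250 pN and FLNA repeat 22 in the
tens of pN at 400/1600 nm/s).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import PN_NM_TO_FJ, kbt
from .curves import ForceCurve, Segment
from .elasticity import IndenterGeometry
from .unfolding import WLCParams, wlc_inverse, wlc_stiffness


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def lognormal_mu_for_mode(mode: float, sigma: float) -> float:
    """Location parameter of a lognormal with the given mode: mu = ln(mode) + sigma^2."""
    if mode <= 0:
        raise ValueError("mode must be positive")
    return math.log(mode) + sigma**2


# ---------------------------------------------------------------------------
# indentation


@dataclass
class IndentationSimConfig:
    """Cell-population indentation study settings.

    Defaults mirror the experimental design: >= 50 cells x 10 curves per
    cell, 5 um/s approach at 4096 Hz over a 7.5 um curve, 1 nN maximum
    force, 0.12 N/m cantilever at 310 K.
    """

    modulus_mode_kpa: float = 1.88
    modulus_sigma: float = 0.5
    n_cells: int = 50
    curves_per_cell: int = 10
    geometry: IndenterGeometry = field(default_factory=IndenterGeometry)
    contact_offset_range_nm: tuple[float, float] = (2800.0, 3800.0)
    baseline_tilt_range_pn_per_nm: float = 0.02
    noise_sd_pn: float = 5.0
    max_force_pn: float = 1000.0
    curve_length_nm: float = 7500.0
    sampling_rate_hz: float = 4096.0
    velocity_nm_s: float = 5000.0
    spring_constant_pn_nm: float = 120.0
    temperature_k: float = 310.0
    group_label: str = ""
    seed: int = 0

    def validate(self) -> None:
        if self.modulus_mode_kpa <= 0 or self.modulus_sigma < 0:
            raise ValueError("modulus mode must be positive, sigma non-negative")
        if self.n_cells < 1 or self.curves_per_cell < 1:
            raise ValueError("n_cells and curves_per_cell must be >= 1")
        if self.noise_sd_pn < 0 or self.max_force_pn <= 0:
            raise ValueError("noise_sd must be >= 0, max_force > 0")


def simulate_indentation_curve(
    E_kpa: float,
    config: IndentationSimConfig,
    rng,
    curve_id: str = "indent-0",
    cell_id: str = "",
) -> ForceCurve:
    """One approach curve at modulus E with drawn contact point and tilt."""
    if E_kpa <= 0:
        raise ValueError("E must be positive")
    config.validate()
    rng = _rng(rng)
    dz = config.velocity_nm_s / config.sampling_rate_hz
    z = np.arange(config.curve_length_nm, -dz / 2, -dz)
    z0 = float(rng.uniform(*config.contact_offset_range_nm))
    tilt = float(rng.uniform(-1, 1) * config.baseline_tilt_range_pn_per_nm)
    k = config.spring_constant_pn_nm
    c = E_kpa * config.geometry.prefactor_per_kpa  # pN/nm^2
    s = np.clip(z0 - z, 0.0, None)  # piezo travel past contact
    # delta solves c*delta^2/k + delta = s  (deflection-corrected contact)
    delta = (np.sqrt(1.0 + 4.0 * c * s / k) - 1.0) * k / (2.0 * c)
    force = c * delta**2
    # truncate at max force, keeping the first sample at/above it
    over = np.nonzero(force >= config.max_force_pn)[0]
    end = int(over[0]) + 1 if over.size else len(z)
    z, force = z[:end], force[:end]
    force = force + tilt * (z - z0)
    if config.noise_sd_pn > 0:
        force = force + rng.normal(0.0, config.noise_sd_pn, size=force.shape)
    curve = ForceCurve(
        segments=[Segment("approach", z, force, config.sampling_rate_hz)],
        spring_constant=k,
        velocity=config.velocity_nm_s,
        temperature=config.temperature_k,
        mode="indentation",
        curve_id=curve_id,
        cell_id=cell_id,
        group_label=config.group_label,
        annotations={
            "true_E_kPa": repr(float(E_kpa)),
            "true_contact_nm": repr(z0),
            "true_tilt_pN_per_nm": repr(tilt),
            "noise_sd_pN": repr(float(config.noise_sd_pn)),
            "face_angle_deg": repr(config.geometry.face_angle_deg),
        },
    )
    return curve


def simulate_indentation_population(
    config: IndentationSimConfig,
) -> tuple[list[ForceCurve], pd.DataFrame]:
    """Draw one modulus per cell from the configured lognormal, then
    ``curves_per_cell`` curves per cell. Returns curves and a truth table."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    mu = lognormal_mu_for_mode(config.modulus_mode_kpa, config.modulus_sigma)
    cell_E = np.exp(rng.normal(mu, config.modulus_sigma, size=config.n_cells))
    curves: list[ForceCurve] = []
    rows = []
    tag = config.group_label or "pop"
    for i, E in enumerate(cell_E):
        cell_id = f"{tag}-cell-{i:03d}"
        rows.append({"cell_id": cell_id, "true_E_kPa": float(E)})
        for j in range(config.curves_per_cell):
            curves.append(
                simulate_indentation_curve(
                    float(E),
                    config,
                    rng,
                    curve_id=f"{tag}-c{i:03d}-r{j:02d}",
                    cell_id=cell_id,
                )
            )
    return curves, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# adhesion


@dataclass
class AdhesionSimConfig:
    """Cell-fibronectin adhesion retract settings.

    The retract covers 100 um at 5 um/s and 2048 Hz after a 2 nN contact
    and a 1 s constant-height pause, as in single-cell force spectroscopy
    with an extended-range piezo module.
    """

    profile: str = "triangular"  # or "multi_rupture"
    work_target_fj: float = 1.0
    rupture_count: int = 3
    detachment_range_nm: tuple[float, float] = (20000.0, 40000.0)
    noise_sd_pn: float = 5.0
    contact_force_pn: float = 2000.0
    unload_slope_pn_per_nm: float = 4.0
    retract_length_nm: float = 100000.0
    sampling_rate_hz: float = 2048.0
    velocity_nm_s: float = 5000.0
    spring_constant_pn_nm: float = 120.0
    temperature_k: float = 310.0
    pause_s: float = 1.0
    group_label: str = ""
    seed: int = 0

    def validate(self) -> None:
        if self.profile not in ("triangular", "multi_rupture"):
            raise ValueError(f"unknown adhesion profile {self.profile!r}")
        if self.work_target_fj < 0:
            raise ValueError("work_target must be >= 0")
        if self.profile == "multi_rupture" and self.rupture_count < 1:
            raise ValueError("multi_rupture needs rupture_count >= 1")


def _adhesion_profile(z: np.ndarray, z_zf: float, z_det: float, cfg: AdhesionSimConfig) -> np.ndarray:
    """Noise-free adhesive force (negative dip) between zero-force and detachment."""
    w_pn_nm = cfg.work_target_fj / PN_NM_TO_FJ
    f = np.zeros_like(z)
    if w_pn_nm <= 0 or z_det <= z_zf:
        return f
    if cfg.profile == "triangular":
        width = z_det - z_zf
        depth = 2.0 * w_pn_nm / width
        mid = 0.5 * (z_zf + z_det)
        in_dip = (z >= z_zf) & (z <= z_det)
        frac = np.where(z[in_dip] <= mid, (z[in_dip] - z_zf) / (mid - z_zf),
                        (z_det - z[in_dip]) / (z_det - mid))
        f[in_dip] = -depth * frac
        return f
    # multi_rupture: equal-area sawtooth dips, each ending in a step back to 0
    n = cfg.rupture_count
    bounds = np.linspace(z_zf, z_det, n + 1)
    for a, b in zip(bounds[:-1], bounds[1:]):
        depth = 2.0 * (w_pn_nm / n) / (b - a)
        in_dip = (z >= a) & (z < b)
        f[in_dip] = -depth * (z[in_dip] - a) / (b - a)
    return f


def simulate_adhesion_curve(
    config: AdhesionSimConfig, rng, curve_id: str = "adh-0", cell_id: str = ""
) -> ForceCurve:
    """Pause + retract curve whose noise-free adhesive work equals the target."""
    config.validate()
    rng = _rng(rng)
    dz = config.velocity_nm_s / config.sampling_rate_hz
    z = np.arange(0.0, config.retract_length_nm, dz)
    z_zf = config.contact_force_pn / config.unload_slope_pn_per_nm
    z_det = float(rng.uniform(*config.detachment_range_nm))
    force = np.maximum(config.contact_force_pn - config.unload_slope_pn_per_nm * z, 0.0)
    force = force + _adhesion_profile(z, z_zf, z_det, config)
    true_work = float(
        np.trapezoid(np.clip(-force, 0.0, None), z) * PN_NM_TO_FJ
    )
    if config.noise_sd_pn > 0:
        force = force + rng.normal(0.0, config.noise_sd_pn, size=force.shape)
    n_pause = max(int(round(config.pause_s * config.sampling_rate_hz)), 2)
    pause_h = np.full(n_pause, 0.0)
    pause_f = np.full(n_pause, config.contact_force_pn)
    if config.noise_sd_pn > 0:
        pause_f = pause_f + rng.normal(0.0, config.noise_sd_pn, size=n_pause)
    # pause heights must be stored; keep them constant at the contact height
    segments = [
        Segment("pause", pause_h, pause_f, config.sampling_rate_hz),
        Segment("retract", z, force, config.sampling_rate_hz),
    ]
    n_rupture = config.rupture_count if config.profile == "multi_rupture" else 0
    if config.work_target_fj <= 0:
        n_rupture = 0
    return ForceCurve(
        segments=segments,
        spring_constant=config.spring_constant_pn_nm,
        velocity=config.velocity_nm_s,
        temperature=config.temperature_k,
        mode="adhesion",
        curve_id=curve_id,
        cell_id=cell_id,
        group_label=config.group_label,
        annotations={
            "true_work_fJ": repr(true_work),
            "target_work_fJ": repr(float(config.work_target_fj)),
            "true_detachment_nm": repr(z_det if config.work_target_fj > 0 else z_zf),
            "true_zero_force_nm": repr(z_zf),
            "true_rupture_count": repr(n_rupture),
            "noise_sd_pN": repr(float(config.noise_sd_pn)),
        },
    )


def simulate_adhesion_population(
    config: AdhesionSimConfig,
    n_curves: int,
    work_sigma: float = 0.5,
) -> tuple[list[ForceCurve], pd.DataFrame]:
    """n adhesion curves with per-curve work drawn from a lognormal whose
    *median* is ``config.work_target_fj`` (median = exp(mu) is the natural
    centre for ratio comparisons)."""
    rng = np.random.default_rng(config.seed)
    mu = math.log(config.work_target_fj) if config.work_target_fj > 0 else None
    curves, rows = [], []
    tag = config.group_label or "adh"
    for i in range(n_curves):
        if mu is None:
            w = 0.0
        else:
            w = float(np.exp(rng.normal(mu, work_sigma)))
        cfg_i = replace(config, work_target_fj=w)
        c = simulate_adhesion_curve(cfg_i, rng, curve_id=f"{tag}-{i:04d}")
        curves.append(c)
        rows.append({"curve_id": c.curve_id, "true_work_fJ": float(c.annotations["true_work_fJ"])})
    return curves, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bell-Evans + kinetic Monte Carlo unfolding


@dataclass(frozen=True)
class BellEvansParams:
    """Intrinsic unfolding rate k0 (1/s) and transition-state distance dx (nm)."""

    k0_per_s: float
    delta_x_nm: float

    def __post_init__(self) -> None:
        if self.k0_per_s <= 0 or self.delta_x_nm <= 0:
            raise ValueError("k0 and delta_x must be positive")

    def rate(self, force_pn, temperature_K: float):
        return self.k0_per_s * np.exp(
            np.asarray(force_pn, dtype=float) * self.delta_x_nm / kbt(temperature_K)
        )


#: calibration defaults (see module docstring): titin I27 and the two FLNA
#: repeat-22 variants (unedited Q, edited R). Calibrated so the *peak* of
#: the measured unfolding-force distribution (detected, accepted events at
#: 5 pN noise — the same kind of quantity the experiments report) lands
#: near the reported values: I27 215/250 pN, Q 35.4/61.4 pN, R 43.7/82.0 pN
#: at 400/1600 nm/s. For the R variant part of the 400 nm/s population
#: unfolds below the ~20 pN detection floor (its printed speed dependence
#: implies a steep force-vs-log-rate slope); those events are invisible to
#: the detector, exactly as they would be to the instrument.
I27_BELL_EVANS = BellEvansParams(k0_per_s=3.09e-3, delta_x_nm=0.172)
FLNA_Q_BELL_EVANS = BellEvansParams(k0_per_s=5.0, delta_x_nm=0.33)
FLNA_R_BELL_EVANS = BellEvansParams(k0_per_s=7.0, delta_x_nm=0.215)

I27_INCREMENT_NM = 27.3
FLNA_INCREMENT_NM = 30.4


def default_domain_layout(flna: BellEvansParams = FLNA_Q_BELL_EVANS):
    """3x I27 + FLNA repeat 22 + 4x I27, N- to C-terminus."""
    i27 = [("I27", I27_INCREMENT_NM, I27_BELL_EVANS)] * 3
    i27b = [("I27", I27_INCREMENT_NM, I27_BELL_EVANS)] * 4
    return i27 + [("FLNA", FLNA_INCREMENT_NM, flna)] + i27b


def bell_evans_most_probable_force(
    params: BellEvansParams, loading_rate_pn_s: float, temperature_K: float
) -> float:
    """Analytic most probable rupture force at a constant loading rate.

    F* = (kBT/dx) * ln(r * dx / (k0 * kBT)). Raises ValueError when the
    logarithm's argument is <= 1 (the most probable force is then zero:
    spontaneous unfolding outruns the ramp).
    """
    kt = kbt(temperature_K)
    arg = loading_rate_pn_s * params.delta_x_nm / (params.k0_per_s * kt)
    if arg <= 1.0:
        raise ValueError(
            f"loading rate too low for a finite most probable force (arg={arg:.3g})"
        )
    return kt / params.delta_x_nm * math.log(arg)


def bell_evans_wlc_force(
    params: BellEvansParams,
    pulling_speed_nm_s: float,
    spring_constant_pn_nm: float,
    Lc_nm: float,
    wlc: WLCParams,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> float:
    """Self-consistent most probable force with the local WLC loading rate.

    Iterates F* = (kBT/dx) ln(r(F*) dx/(k0 kBT)) where r(F) = k_eff(F) * v
    and k_eff is the series stiffness of cantilever and WLC at force F.
    """
    F = 50.0
    for _ in range(max_iter):
        x = wlc_inverse(F, Lc_nm, wlc)
        k_wlc = wlc_stiffness(x, Lc_nm, wlc)
        k_eff = 1.0 / (1.0 / spring_constant_pn_nm + 1.0 / k_wlc)
        r = k_eff * pulling_speed_nm_s
        F_new = bell_evans_most_probable_force(params, r, wlc.temperature_K)
        if abs(F_new - F) < tol:
            return F_new
        F = 0.5 * (F + F_new)
    return F


@dataclass
class UnfoldingSimConfig:
    """Constant-velocity polyprotein pulling settings.

    Defaults follow the single-molecule protocol: 800 nm curve at 400 or
    1600 nm/s, a 0.01 N/m cantilever, fixed 0.4 nm persistence length.
    ``initial_contour_nm`` is the folded-backbone contour (folded domains +
    linkers) before any unfolding.
    """

    domain_layout: list[tuple[str, float, BellEvansParams]] = field(
        default_factory=default_domain_layout
    )
    persistence_length_nm: float = 0.4
    pulling_speed_nm_s: float = 1600.0
    spring_constant_pn_nm: float = 10.0
    temperature_k: float = 298.0
    noise_sd_pn: float = 5.0
    n_traces: int = 100
    curve_length_nm: float = 800.0
    sampling_rate_hz: float = 4096.0
    initial_contour_nm: float = 30.0
    detachment_force_pn: float = 500.0
    group_label: str = ""
    seed: int = 0

    def validate(self) -> None:
        if not self.domain_layout:
            raise ValueError("domain layout must be non-empty")
        if self.persistence_length_nm <= 0:
            raise ValueError("persistence length must be positive")
        if self.pulling_speed_nm_s <= 0 or self.spring_constant_pn_nm <= 0:
            raise ValueError("speed and spring constant must be positive")

    @property
    def wlc(self) -> WLCParams:
        return WLCParams(self.persistence_length_nm, self.temperature_k)


class _Trajectory:
    """Deterministic force-vs-pull-distance curve at fixed contour length.

    Parameterized on a uniform force grid (so force increments per step are
    exactly dF): s(F) = x_wlc(F) + F/k. Carries the cumulative Bell-Evans
    hazard for each distinct parameter set in the layout.
    """

    def __init__(self, Lc: float, cfg: UnfoldingSimConfig, classes: list[BellEvansParams], dF: float = 0.25):
        f_grid = np.arange(0.0, cfg.detachment_force_pn + dF, dF)
        x = wlc_inverse(f_grid, Lc, cfg.wlc)
        self.s = x + f_grid / cfg.spring_constant_pn_nm
        self.f = f_grid
        self.Lc = Lc
        v = cfg.pulling_speed_nm_s
        self.hazards = []
        ds = np.diff(self.s)
        for be in classes:
            rate = be.rate(f_grid, cfg.temperature_k)
            cum = np.concatenate([[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * ds / v)])
            self.hazards.append(cum)

    def force_at(self, s):
        return np.interp(s, self.s, self.f)

    def hazard_at(self, class_idx: int, s) -> float:
        return float(np.interp(s, self.s, self.hazards[class_idx]))

    def s_where_hazard(self, class_idx: int, target: float) -> float:
        cum = self.hazards[class_idx]
        if target >= cum[-1]:
            return math.inf
        return float(np.interp(target, cum, self.s))

    @property
    def s_detach(self) -> float:
        return float(self.s[-1])


class UnfoldingSimulator:
    """Kinetic-Monte-Carlo sawtooth generator with cached force trajectories."""

    def __init__(self, config: UnfoldingSimConfig):
        config.validate()
        self.config = config
        self._classes: list[BellEvansParams] = []
        self._class_of: list[int] = []
        for _, _, be in config.domain_layout:
            if be not in self._classes:
                self._classes.append(be)
            self._class_of.append(self._classes.index(be))
        self._traj_cache: dict[float, _Trajectory] = {}

    def _traj(self, Lc: float) -> _Trajectory:
        key = round(Lc, 6)
        if key not in self._traj_cache:
            self._traj_cache[key] = _Trajectory(Lc, self.config, self._classes)
        return self._traj_cache[key]

    def simulate(self, rng, curve_id: str = "unfold-0") -> ForceCurve:
        cfg = self.config
        rng = _rng(rng)
        n_dom = len(cfg.domain_layout)
        budgets = rng.exponential(1.0, size=n_dom)  # Exp(1) hazard thresholds
        spent = np.zeros(n_dom)
        folded = np.ones(n_dom, dtype=bool)
        Lc = cfg.initial_contour_nm
        s_now = 0.0
        events = []
        # (s_start, s_end, Lc) pieces for rendering
        pieces: list[tuple[float, float, float]] = []
        detach_s = None
        while True:
            traj = self._traj(Lc)
            h_now = [traj.hazard_at(c, s_now) for c in range(len(self._classes))]
            best_s, best_i = math.inf, -1
            for i in range(n_dom):
                if not folded[i]:
                    continue
                c = self._class_of[i]
                s_i = traj.s_where_hazard(c, h_now[c] + (budgets[i] - spent[i]))
                if s_i < best_s:
                    best_s, best_i = s_i, i
            s_end_options = [traj.s_detach, cfg.curve_length_nm]
            s_limit = min(s_end_options)
            if best_i < 0 or best_s >= s_limit:
                # detachment (or truncation at curve end) before next unfolding
                if traj.s_detach <= cfg.curve_length_nm:
                    detach_s = traj.s_detach
                    pieces.append((s_now, detach_s, Lc))
                else:
                    pieces.append((s_now, cfg.curve_length_nm, Lc))
                break
            # commit the unfolding event at best_s
            label, inc, _ = cfg.domain_layout[best_i]
            f_event = float(traj.force_at(best_s))
            events.append(
                {
                    "domain": label,
                    "index": int(best_i),
                    "force_pN": f_event,
                    "s_nm": float(best_s),
                    "time_s": float(best_s / cfg.pulling_speed_nm_s),
                    "Lc_before_nm": float(Lc),
                    "Lc_after_nm": float(Lc + inc),
                }
            )
            for i in range(n_dom):
                if folded[i]:
                    c = self._class_of[i]
                    spent[i] += traj.hazard_at(c, best_s) - h_now[c]
            folded[best_i] = False
            pieces.append((s_now, best_s, Lc))
            Lc += inc
            s_now = best_s
        # render at the sampling rate
        dz = cfg.pulling_speed_nm_s / cfg.sampling_rate_hz
        s_grid = np.arange(0.0, cfg.curve_length_nm, dz)
        force = np.zeros_like(s_grid)
        for s_a, s_b, piece_lc in pieces:
            m = (s_grid >= s_a) & (s_grid < s_b)
            if m.any():
                force[m] = self._traj(piece_lc).force_at(s_grid[m])
        if cfg.noise_sd_pn > 0:
            force = force + rng.normal(0.0, cfg.noise_sd_pn, size=force.shape)
        return ForceCurve(
            segments=[Segment("retract", s_grid, force, cfg.sampling_rate_hz)],
            spring_constant=cfg.spring_constant_pn_nm,
            velocity=cfg.pulling_speed_nm_s,
            temperature=cfg.temperature_k,
            mode="unfolding",
            curve_id=curve_id,
            group_label=cfg.group_label,
            annotations={
                "events_json": json.dumps(events),
                "detachment_s_nm": repr(detach_s if detach_s is not None else float("nan")),
                "initial_contour_nm": repr(float(cfg.initial_contour_nm)),
                "noise_sd_pN": repr(float(cfg.noise_sd_pn)),
            },
        )


def simulate_unfolding_trace(config: UnfoldingSimConfig, rng, curve_id: str = "unfold-0") -> ForceCurve:
    """One sawtooth trace; see :class:`UnfoldingSimulator` for the mechanics."""
    return UnfoldingSimulator(config).simulate(rng, curve_id)


def simulate_unfolding_population(
    config: UnfoldingSimConfig,
) -> tuple[list[ForceCurve], pd.DataFrame]:
    """n_traces sawtooth traces plus a truth table of per-trace event lists."""
    sim = UnfoldingSimulator(config)
    rng = np.random.default_rng(config.seed)
    tag = config.group_label or "unfold"
    curves, rows = [], []
    for i in range(config.n_traces):
        c = sim.simulate(rng, curve_id=f"{tag}-{i:04d}")
        curves.append(c)
        rows.append(
            {
                "curve_id": c.curve_id,
                "pulling_speed_nm_s": config.pulling_speed_nm_s,
                "events_json": c.annotations["events_json"],
            }
        )
    return curves, pd.DataFrame(rows)


def true_event_frame(curves: list[ForceCurve]) -> pd.DataFrame:
    """Flatten the simulator's ground-truth event lists into a table."""
    rows = []
    for c in curves:
        for order, ev in enumerate(json.loads(c.annotations["events_json"])):
            rows.append(
                {
                    "curve_id": c.curve_id,
                    "order_index": order,
                    "domain": ev["domain"],
                    "force_pN": ev["force_pN"],
                    "Lc_before_nm": ev["Lc_before_nm"],
                    "increment_nm": ev["Lc_after_nm"] - ev["Lc_before_nm"],
                    "pulling_speed_nm_s": c.velocity,
                }
            )
    return pd.DataFrame(rows)
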