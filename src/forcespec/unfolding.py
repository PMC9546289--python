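"""Sawtooth (polyprotein unfolding) trace analysis.

The entropic elasticity of an unfolded polypeptide segment is the
interpolated worm-like chain (WLC),

    F(x) = (kB*T / p) * [ 1/4 * (1 - x/Lc)^-2 - 1/4 + x/Lc ],

with persistence length p fixed at 0.4 nm (the scale of a single amino
acid) and contour length Lc the only fitted parameter per rising edge.

A retract trace is analysed as: peak detection (local maxima over a noise
threshold followed by a large force drop), per-edge WLC fits on the
deflection-corrected extension axis x = z - F/k, contour-length-increment
classification of events into FLNA repeat-22 (~30.4 nm) versus titin I27
(~27.3 nm), rule-based trace acceptance, and per-(label, speed) summaries.

Event bookkeeping: the contour length attributed to an unfolding peak is
the fitted Lc of the rising edge *following* it — the length the rupture
released — so the increment of event i is Lc(edge i+1) - Lc(edge i). The
final peak (tip-surface detachment) has no following edge and is excluded
from domain counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .constants import kbt
from .curves import ForceCurve

EVENT_LABELS = ("FLNA", "I27", "unclassified")


@dataclass(frozen=True)
class WLCParams:
    """Worm-like chain parameters: persistence length (nm) and temperature (K)."""

    persistence_length_nm: float = 0.4
    temperature_K: float = 298.0

    def __post_init__(self) -> None:
        if self.persistence_length_nm <= 0:
            raise ValueError("persistence length must be positive")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kbt_pn_nm(self) -> float:
        return kbt(self.temperature_K)


def wlc_force(x_nm, Lc_nm: float, params: WLCParams):
    """Interpolated WLC force (pN) at extension x for contour length Lc."""
    x = np.asarray(x_nm, dtype=float)
    if Lc_nm <= 0:
        raise ValueError("contour length must be positive")
    if np.any(x < 0) or np.any(x >= Lc_nm):
        raise ValueError("extension must satisfy 0 <= x < Lc")
    xi = x / Lc_nm
    scale = params.kbt_pn_nm / params.persistence_length_nm
    out = scale * (0.25 * (1.0 - xi) ** -2 - 0.25 + xi)
    return out if out.ndim else float(out)


def wlc_stiffness(x_nm: float, Lc_nm: float, params: WLCParams) -> float:
    """dF/dx (pN/nm) of the interpolated WLC."""
    xi = x_nm / Lc_nm
    scale = params.kbt_pn_nm / params.persistence_length_nm
    return scale * (0.5 * (1.0 - xi) ** -3 + 1.0) / Lc_nm


def wlc_inverse(force_pn, Lc_nm: float, params: WLCParams):
    """Extension x (nm) at which the WLC reaches ``force_pn`` (vectorized).

    Solved by bisection on the fractional extension; exact at F = 0.
    """
    f = np.atleast_1d(np.asarray(force_pn, dtype=float))
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    scale = params.kbt_pn_nm / params.persistence_length_nm
    target = f / scale
    lo = np.zeros_like(target)
    hi = np.full_like(target, 1.0 - 1e-12)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        val = 0.25 * (1.0 - mid) ** -2 - 0.25 + mid
        high = val > target
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    xi = 0.5 * (lo + hi)
    out = xi * Lc_nm
    return out if np.asarray(force_pn).ndim else float(out[0])


# ---------------------------------------------------------------------------
# peak detection


@dataclass
class SawtoothPeak:
    """A detected peak with its preceding rising edge (sample index range)."""

    peak_index: int
    edge_start: int
    peak_force_pn: float
    peak_position_nm: float


def detect_sawtooth_peaks(
    height_nm: np.ndarray,
    force_pn: np.ndarray,
    noise_sd_pn: float,
    min_force_pn: float = 20.0,
    min_spacing_nm: float = 5.0,
    drop_fraction: float = 0.3,
    threshold_sigmas: float = 4.0,
) -> list[SawtoothPeak]:
    """Local maxima above max(min_force, threshold*noise) followed by a drop.

    A candidate maximum qualifies when the force falls by more than
    ``drop_fraction`` of the peak value before the next retained candidate
    (a genuine rupture, not a noise bump); each peak is paired with its
    rising edge, starting at the valley after the previous peak (trace
    start for the first).
    """
    from scipy.signal import find_peaks

    f = np.asarray(force_pn, dtype=float)
    z = np.asarray(height_nm, dtype=float)
    n = len(f)
    thr = max(min_force_pn, threshold_sigmas * noise_sd_pn)
    dz = float(np.median(np.abs(np.diff(z)))) if n > 1 else 1.0
    min_gap = max(int(round(min_spacing_nm / max(dz, 1e-9))), 1)
    cand, _ = find_peaks(f, height=thr, distance=min_gap)
    # a maximum at the very end of the trace has no detectable drop; allow it
    retained: list[int] = []
    min_drop = 6.0 * noise_sd_pn  # a genuine rupture, not a noise dip
    for idx, c in enumerate(cand):
        nxt = cand[idx + 1] if idx + 1 < len(cand) else n
        tail_min = float(f[c:nxt].min())
        if f[c] - tail_min >= max(drop_fraction * f[c], min_drop):
            retained.append(int(c))
    # merge candidates sharing a rising edge: keep the highest between drops
    peaks: list[SawtoothPeak] = []
    prev_peak = 0
    for c in retained:
        lo = prev_peak
        valley = lo + int(np.argmin(f[lo : c + 1])) if c > lo else lo
        peaks.append(
            SawtoothPeak(
                peak_index=c,
                edge_start=valley,
                peak_force_pn=float(f[c]),
                peak_position_nm=float(z[c]),
            )
        )
        prev_peak = c
    return peaks


# ---------------------------------------------------------------------------
# WLC edge fitting


class EdgeFitError(ValueError):
    pass


def fit_edge_wlc(
    x_nm: np.ndarray,
    force_pn: np.ndarray,
    params: WLCParams,
    min_samples: int = 8,
    min_force_pn: float = 2.0,
) -> tuple[float, float]:
    """Fit Lc (nm) to one rising edge by 1-D bounded least squares.

    Only samples with force above ``min_force_pn`` and positive extension
    enter the fit; Lc is searched on (max extension, 10x max extension).
    Returns ``(Lc, rss)``.
    """
    x = np.asarray(x_nm, dtype=float)
    f = np.asarray(force_pn, dtype=float)
    keep = (f > min_force_pn) & (x > 0)
    x, f = x[keep], f[keep]
    if x.size < min_samples:
        raise EdgeFitError(f"edge has {x.size} usable samples (need >= {min_samples})")
    xmax = float(x.max())
    lo, hi = xmax * (1.0 + 1e-6), xmax * 10.0
    scale = params.kbt_pn_nm / params.persistence_length_nm

    def rss(Lc: float) -> float:
        xi = x / Lc
        model = scale * (0.25 * (1.0 - xi) ** -2 - 0.25 + xi)
        r = f - model
        return float(np.dot(r, r))

    res = minimize_scalar(rss, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4})
    if not res.success:
        raise EdgeFitError(f"WLC fit did not converge: {res.message}")
    return float(res.x), float(res.fun)


# ---------------------------------------------------------------------------
# classification and acceptance


@dataclass(frozen=True)
class ClassificationWindows:
    """Contour-length-increment windows for domain assignment (nm)."""

    flna_center: float = 30.4
    i27_center: float = 27.3
    half_width: float = 1.5

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("window half-width must be positive")
        if abs(self.flna_center - self.i27_center) < 2 * self.half_width:
            raise ValueError("classification windows overlap")


def classify_event(increment_nm: float, windows: ClassificationWindows | None = None) -> str:
    """Label one contour-length increment as FLNA, I27 or unclassified."""
    w = windows or ClassificationWindows()
    if abs(increment_nm - w.flna_center) <= w.half_width:
        return "FLNA"
    if abs(increment_nm - w.i27_center) <= w.half_width:
        return "I27"
    return "unclassified"


@dataclass
class UnfoldingEvent:
    peak_force_pn: float
    contour_length_nm: float  # Lc of the edge following the peak
    increment_nm: float
    extension_at_peak_nm: float
    fit_rss: float
    label: str
    order_index: int


@dataclass
class AcceptanceRules:
    """Trace-level acceptance rules; each individually switchable."""

    min_i27: int = 4
    max_flna: int = 1
    require_weak_before_strong: bool = True
    enforce_min_i27: bool = True
    enforce_max_flna: bool = True


@dataclass
class TraceResult:
    curve_id: str
    pulling_speed_nm_s: float
    events: list[UnfoldingEvent]
    detachment_force_pn: float | None
    accepted: bool = False
    rejection_reason: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "curve_id": self.curve_id,
                "order_index": e.order_index,
                "label": e.label,
                "peak_force_pN": e.peak_force_pn,
                "Lc_nm": e.contour_length_nm,
                "dLc_nm": e.increment_nm,
                "extension_nm": e.extension_at_peak_nm,
                "rss": e.fit_rss,
                "pulling_speed_nm_s": self.pulling_speed_nm_s,
                "accepted": self.accepted,
            }
            for e in self.events
        ]
        return pd.DataFrame(rows)


def accept_trace(
    events: list[UnfoldingEvent],
    rules: AcceptanceRules | None = None,
    curve_id: str = "",
    pulling_speed_nm_s: float = 0.0,
    detachment_force_pn: float | None = None,
) -> TraceResult:
    """Apply the acceptance rule set; rejection is a result, not an error."""
    r = rules or AcceptanceRules()
    result = TraceResult(
        curve_id=curve_id,
        pulling_speed_nm_s=pulling_speed_nm_s,
        events=events,
        detachment_force_pn=detachment_force_pn,
    )
    i27 = [e for e in events if e.label == "I27"]
    flna = [e for e in events if e.label == "FLNA"]
    if r.enforce_min_i27 and len(i27) < r.min_i27:
        result.rejection_reason = "too_few_events"
        return result
    if r.enforce_max_flna and len(flna) > r.max_flna:
        result.rejection_reason = "too_many_flna"
        return result
    if r.require_weak_before_strong and flna:
        e_flna = flna[0]
        for e in i27:
            if e.peak_force_pn > e_flna.peak_force_pn and e.order_index < e_flna.order_index:
                result.rejection_reason = "ordering_violation"
                return result
    result.accepted = True
    return result


# ---------------------------------------------------------------------------
# trace-level model object


@dataclass
class SawtoothConfig:
    wlc: WLCParams = field(default_factory=WLCParams)
    windows: ClassificationWindows = field(default_factory=ClassificationWindows)
    rules: AcceptanceRules = field(default_factory=AcceptanceRules)
    min_force_pn: float = 20.0
    drop_fraction: float = 0.3
    threshold_sigmas: float = 4.0
    baseline_tail_fraction: float = 0.1
    smooth_window: int = 5  # light boxcar for detection/peak readout


def _tail_baseline(force: np.ndarray, fraction: float) -> tuple[float, float]:
    n = max(int(len(force) * fraction), 10)
    tail = force[-n:]
    return float(np.median(tail)), float(tail.std(ddof=1))


class SawtoothModel:
    """Analysis model for one unfolding retract trace.

    ``fit()`` runs baseline removal (post-detachment tail), peak detection on
    a lightly smoothed trace, per-edge WLC fits, increment classification and
    acceptance, returning a :class:`TraceResult`.
    """

    def __init__(self, curve: ForceCurve, config: SawtoothConfig | None = None):
        if curve.retract is None:
            raise ValueError("unfolding analysis needs a retract segment")
        self.curve = curve
        self.config = config or SawtoothConfig()

    def fit(self) -> TraceResult:
        cfg = self.config
        seg = self.curve.retract
        z = seg.height
        offset, noise_sd = _tail_baseline(seg.force, cfg.baseline_tail_fraction)
        f = seg.force - offset
        w = cfg.smooth_window
        if w > 1:
            pad = w // 2
            fs = np.convolve(np.pad(f, pad, mode="edge"), np.ones(w) / w, mode="valid")
            noise_eff = noise_sd / np.sqrt(w)
        else:
            fs, noise_eff = f, noise_sd
        peaks = detect_sawtooth_peaks(
            z,
            fs,
            noise_eff,
            min_force_pn=cfg.min_force_pn,
            drop_fraction=cfg.drop_fraction,
            threshold_sigmas=cfg.threshold_sigmas,
        )
        # refine each peak to the raw sample just before the rupture step:
        # the smoothed maximum is pulled low by post-drop samples in the
        # boxcar, while the raw pre-rupture sample is unbiased up to noise
        refined: list[int] = []
        for p in peaks:
            lo = max(p.peak_index - w, 0)
            hi = min(p.peak_index + w + 1, len(f) - 1)
            d = np.diff(f[lo : hi + 1])
            i = lo + int(np.argmin(d)) if len(d) else p.peak_index
            refined.append(i)
            p.peak_force_pn = float(f[i])
            p.peak_position_nm = float(z[i])
        # fit every rising edge on the deflection-corrected extension axis
        k = self.curve.spring_constant
        x_axis = z - z[0] - f / k
        edge_fits: list[tuple[float, float] | None] = []
        for p in peaks:
            sl = slice(p.edge_start, p.peak_index + 1)
            try:
                edge_fits.append(fit_edge_wlc(x_axis[sl], f[sl], cfg.wlc))
            except EdgeFitError:
                edge_fits.append(None)
        events: list[UnfoldingEvent] = []
        detachment_force = peaks[-1].peak_force_pn if peaks else None
        order = 0
        for i in range(len(peaks) - 1):  # last peak = detachment, excluded
            this_fit, next_fit = edge_fits[i], edge_fits[i + 1]
            if this_fit is None or next_fit is None:
                continue
            inc = next_fit[0] - this_fit[0]
            events.append(
                UnfoldingEvent(
                    peak_force_pn=peaks[i].peak_force_pn,
                    contour_length_nm=next_fit[0],
                    increment_nm=inc,
                    extension_at_peak_nm=float(x_axis[refined[i]]),
                    fit_rss=next_fit[1],
                    label=classify_event(inc, cfg.windows),
                    order_index=order,
                )
            )
            order += 1
        return accept_trace(
            events,
            cfg.rules,
            curve_id=self.curve.curve_id,
            pulling_speed_nm_s=self.curve.velocity,
            detachment_force_pn=detachment_force,
        )


def analyze_trace(curve: ForceCurve, config: SawtoothConfig | None = None) -> TraceResult:
    """Functional form of :class:`SawtoothModel` for pipeline use."""
    return SawtoothModel(curve, config).fit()


def summarize_unfolding(
    traces: list[TraceResult], accepted_only: bool = True
) -> pd.DataFrame:
    """Per-(label, pulling speed) force/contour statistics.

    Returns a table with n, mean +/- SE of peak force and of the
    contour-length increment. Empty groups are simply absent.
    """
    frames = [
        t.to_frame()
        for t in traces
        if t.events and (t.accepted or not accepted_only)
    ]
    if not frames:
        return pd.DataFrame(
            columns=[
                "label",
                "pulling_speed_nm_s",
                "n",
                "force_mean_pN",
                "force_se_pN",
                "dLc_mean_nm",
                "dLc_se_nm",
            ]
        )
    df = pd.concat(frames, ignore_index=True)
    df = df[df["label"] != "unclassified"]
    rows = []
    for (label, speed), grp in df.groupby(["label", "pulling_speed_nm_s"]):
        n = len(grp)
        rows.append(
            {
                "label": label,
                "pulling_speed_nm_s": speed,
                "n": n,
                "force_mean_pN": grp["peak_force_pN"].mean(),
                "force_se_pN": grp["peak_force_pN"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "dLc_mean_nm": grp["dLc_nm"].mean(),
                "dLc_se_nm": grp["dLc_nm"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values(["label", "pulling_speed_nm_s"]).reset_index(drop=True)
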