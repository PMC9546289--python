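"""Work of adhesion from retract curves.

The work of adhesion is the area under the adhesive (negative-force) part
of the baseline-corrected retract,

    W_adh = integral of -F(z) dz  between the retract zero-force point
            and the detachment point,

reported in fJ (1 pN*nm = 1e-6 fJ). The baseline is estimated from the
post-detachment tail (the farthest fraction of the retract, the only
guaranteed force-free region); the detachment point is the last position
where the force returns permanently to within a noise threshold of zero,
refined by a piecewise-linear kink fit (linear approach to zero before the
detachment, zero after). Only negative-force samples contribute to the
integral; positive excursions between ruptures contribute nothing. The
constant-height pause segment is never integrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import PN_NM_TO_FJ
from .curves import ForceCurve
from .preprocess import QCRecord


@dataclass
class AdhesionConfig:
    baseline_tail_fraction: float = 0.2
    threshold_sigmas: float = 3.0
    min_noise_pn: float = 0.05
    refine_window_nm: float = 500.0
    rupture_threshold_pn: float | None = None  # default max(6*noise, 30 pN)
    signed_integration: bool = False  # integrate signed F between the bounds


@dataclass
class AdhesionResult:
    curve_id: str
    work_fj: float
    zero_force_point_nm: float
    detachment_point_nm: float
    max_adhesion_force_pn: float
    rupture_count: int
    noise_sd_pn: float
    qc: QCRecord = field(default_factory=QCRecord)

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "curve_id": self.curve_id,
                "work_fJ": self.work_fj,
                "zero_force_nm": self.zero_force_point_nm,
                "detachment_nm": self.detachment_point_nm,
                "max_adhesion_pN": self.max_adhesion_force_pn,
                "rupture_count": self.rupture_count,
                "qc_passed": self.qc.passed,
            }
        )


def _tail_baseline(z: np.ndarray, f: np.ndarray, fraction: float) -> tuple[np.ndarray, float]:
    """Linear baseline from the farthest ``fraction`` of the retract."""
    n = max(int(len(z) * fraction), 10)
    zt, ft = z[-n:], f[-n:]
    coeffs = np.polyfit(zt, ft, 1)
    corrected = f - np.polyval(coeffs, z)
    resid = ft - np.polyval(coeffs, zt)
    return corrected, float(resid.std(ddof=2))


def find_detachment_point(
    z: np.ndarray,
    corrected_force: np.ndarray,
    noise_sd: float,
    threshold_sigmas: float = 3.0,
    min_noise_pn: float = 0.05,
    refine_window_nm: float = 500.0,
    smooth_window: int = 51,
    detect_sigmas: float = 5.0,
) -> float:
    """Last position where the force returns permanently to (noise-level) zero.

    Candidate: last sample of the smoothed trace below the noise threshold
    (smoothing suppresses isolated noise outliers in the force-free tail,
    which would otherwise drag the bound far past the true detachment).
    Refinement: a sharp final rupture (single-sample step back to zero) is
    taken at the step; a gradual return is refined by scanning a piecewise
    model (linear ramp meeting zero at z_d, zero after) over a window around
    the candidate, returning the RSS-minimizing kink.
    """
    f = corrected_force
    n = len(f)
    w = min(smooth_window, max(n // 10, 1))
    if w > 1:
        pad = w // 2
        fs = np.convolve(np.pad(f, pad, mode="edge"), np.ones(w) / w, mode="valid")
        sm_noise = noise_sd / np.sqrt(w)
    else:
        fs, sm_noise = f, noise_sd
    # a long force-free tail offers many chances for a spurious excursion;
    # detect on the smoothed trace at a conservative multiple of its noise
    thr_sm = detect_sigmas * max(sm_noise, min_noise_pn)
    adhesive = np.nonzero(fs < -thr_sm)[0]
    if adhesive.size == 0:
        return float(z[0])
    cand = int(adhesive[-1])
    # sharp final rupture: unsmoothed force steps from adhesive to zero
    step_thr = max(6.0 * noise_sd, 5.0 * max(min_noise_pn, noise_sd), 1.0)
    lo_s = max(cand - w, 0)
    hi_s = min(cand + w, n - 1)
    if hi_s > lo_s:
        jumps = np.diff(f[lo_s : hi_s + 1])
        j_best = int(np.argmax(jumps))
        if jumps[j_best] > step_thr and f[lo_s + j_best] < -step_thr / 2.0:
            i = lo_s + j_best
            return float(0.5 * (z[i] + z[i + 1]))
    dz = float(np.median(np.abs(np.diff(z))))
    win = max(int(round(refine_window_nm / dz)), 3)
    lo = max(cand - win, 0)
    hi = min(cand + win, len(z) - 1)
    zs = z[lo : hi + 1]
    fs = corrected_force[lo : hi + 1]
    best_rss, best_zd = np.inf, float(z[min(cand + 1, len(z) - 1)])
    # least-squares slope of the pre-kink ramp is closed form per candidate
    for j in range(1, len(zs)):
        zd = zs[j]
        u = zs[:j] - zd  # negative
        fpre = fs[:j]
        denom = float(np.dot(u, u))
        if denom == 0:
            continue
        m = float(np.dot(fpre, u)) / denom
        if m < 0:
            m = 0.0  # adhesive ramp must approach zero from below
        r_pre = fpre - m * u
        r_post = fs[j:]
        rss = float(np.dot(r_pre, r_pre) + np.dot(r_post, r_post))
        if rss < best_rss:
            best_rss, best_zd = rss, float(zd)
    return best_zd


def work_of_adhesion(
    z: np.ndarray,
    corrected_force: np.ndarray,
    zero_force_point_nm: float,
    detachment_point_nm: float,
    signed: bool = False,
) -> float:
    """Trapezoidal integral of the adhesive force over z between the bounds, fJ.

    ``signed=False`` (default) clips to negative-force samples; ``signed=True``
    integrates -F as is, so positive excursions subtract.
    """
    if detachment_point_nm < zero_force_point_nm:
        raise ValueError("detachment point must not precede zero-force point")
    if zero_force_point_nm < z[0] - 1e-9 or detachment_point_nm > z[-1] + 1e-9:
        raise ValueError("integration bounds outside the retract segment")
    m = (z >= zero_force_point_nm) & (z <= detachment_point_nm)
    if m.sum() < 2:
        return 0.0
    integrand = -corrected_force[m]
    if not signed:
        integrand = np.clip(integrand, 0.0, None)
    return float(np.trapezoid(integrand, z[m]) * PN_NM_TO_FJ)


def count_ruptures(
    z: np.ndarray,
    corrected_force: np.ndarray,
    noise_sd: float,
    zero_force_point_nm: float,
    detachment_point_nm: float,
    rupture_threshold_pn: float | None = None,
) -> int:
    """Discrete adhesive ruptures: single-sample force steps upward larger
    than the threshold, starting from an adhesive level."""
    thr = rupture_threshold_pn if rupture_threshold_pn is not None else max(6.0 * noise_sd, 30.0)
    dz = float(np.median(np.abs(np.diff(z)))) if len(z) > 1 else 0.0
    # include one sample past the detachment bound so the final step counts
    m = (z >= zero_force_point_nm) & (z <= detachment_point_nm + dz + 1e-9)
    f = corrected_force[m]
    if f.size < 2:
        return 0
    steps = np.diff(f)
    adhesive_before = f[:-1] < -thr / 2.0
    return int(np.sum((steps > thr) & adhesive_before))


def analyze_adhesion(curve: ForceCurve, config: AdhesionConfig | None = None) -> AdhesionResult:
    """Full adhesion chain: tail baseline, detachment detection, integration."""
    cfg = config or AdhesionConfig()
    if curve.mode != "adhesion":
        raise ValueError(f"curve {curve.curve_id} has mode {curve.mode!r}, not adhesion")
    seg = curve.retract
    if seg is None:
        raise ValueError("adhesion analysis needs a retract segment")
    z, f_raw = seg.height, seg.force
    corrected, noise_sd = _tail_baseline(z, f_raw, cfg.baseline_tail_fraction)
    thr = cfg.threshold_sigmas * max(noise_sd, cfg.min_noise_pn)
    # zero-force point: first crossing out of the positive contact region
    positive = corrected > thr
    if positive[0]:
        below = np.nonzero(~positive)[0]
        z_zf = float(z[below[0]]) if below.size else float(z[-1])
    else:
        z_zf = float(z[0])
    z_det = find_detachment_point(
        z,
        corrected,
        noise_sd,
        threshold_sigmas=cfg.threshold_sigmas,
        min_noise_pn=cfg.min_noise_pn,
        refine_window_nm=cfg.refine_window_nm,
    )
    z_det = max(z_det, z_zf)
    work = work_of_adhesion(z, corrected, z_zf, z_det, signed=cfg.signed_integration)
    adhesive = corrected[(z >= z_zf) & (z <= z_det)]
    max_adh = float(-adhesive.min()) if adhesive.size and adhesive.min() < 0 else 0.0
    ruptures = count_ruptures(
        z, corrected, noise_sd, z_zf, z_det, cfg.rupture_threshold_pn
    )
    result = AdhesionResult(
        curve_id=curve.curve_id,
        work_fj=work,
        zero_force_point_nm=z_zf,
        detachment_point_nm=z_det,
        max_adhesion_force_pn=max_adh,
        rupture_count=ruptures,
        noise_sd_pn=noise_sd,
    )
    if noise_sd > 50.0:
        result.qc.fail("excessive_noise")
    return result


class AdhesionModel:
    """Model object over one adhesion retract curve; fit() -> AdhesionResult."""

    def __init__(self, curve: ForceCurve, config: AdhesionConfig | None = None):
        self.curve = curve
        self.config = config or AdhesionConfig()

    def fit(self) -> AdhesionResult:
        return analyze_adhesion(self.curve, self.config)
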