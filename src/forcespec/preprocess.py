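"""Raw-curve conditioning: baseline/tilt removal, contact-point detection,
indentation axis construction and automated quality control.

The processing chain for an indentation curve is

1. robust linear baseline over the non-contact fraction of the approach
   (offset, tilt and a residual noise SD estimate),
2. two-stage contact-point detection: a noise-threshold candidate followed
   by a piecewise least-squares refinement (zero force before the contact
   point z0, quadratic-in-indentation force after it),
3. indentation axis delta = (z0 - z) - F/k on the post-contact approach,
   i.e. piezo travel past contact minus cantilever deflection,
4. QC flags replacing manual outlier screening with explicit thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import ForceCurve, Segment

QC_REASONS = ("excessive_noise", "no_contact", "non_monotone", "saturated", "drift")


class BaselineError(ValueError):
    pass


class NoContactError(ValueError):
    """No threshold crossing found on the approach."""


@dataclass
class QCRecord:
    passed: bool = True
    reasons: list[str] = field(default_factory=list)

    def fail(self, reason: str) -> None:
        if reason not in QC_REASONS:
            raise ValueError(f"unknown QC reason {reason!r}")
        if reason not in self.reasons:
            self.reasons.append(reason)
        self.passed = False


@dataclass
class Baseline:
    offset_pn: float  # baseline force at z = 0
    tilt_pn_per_nm: float  # slope of baseline vs z
    noise_sd_pn: float

    def evaluate(self, z):
        return self.offset_pn + self.tilt_pn_per_nm * np.asarray(z, dtype=float)


@dataclass
class ProcessedCurve:
    """Baseline-corrected approach with contact point and indentation axis."""

    source: ForceCurve
    height: np.ndarray  # approach heights, time order (descending z)
    corrected_force: np.ndarray  # full approach, baseline removed
    contact_point: float  # z0, piezo coordinate (nm)
    indentation: np.ndarray  # delta per post-contact sample (nm)
    post_contact_force: np.ndarray  # corrected force on the same samples
    tilt_slope: float
    baseline_offset: float
    noise_sd_estimate: float
    qc: QCRecord = field(default_factory=QCRecord)


def estimate_baseline(
    curve: ForceCurve,
    fraction_noncontact: float = 0.5,
    clip_sigmas: float = 3.0,
    above_z: float | None = None,
) -> Baseline:
    """Robust linear fit over the non-contact part of the approach.

    The region is either the leading ``fraction_noncontact`` of the samples
    (first pass, contact point unknown) or, when ``above_z`` is given, every
    sample with z above it (zero-slope refinement once the contact point is
    known). Least squares with one round of residual clipping at
    ``clip_sigmas`` standard deviations; returns the intercept (pN at z=0),
    tilt (pN/nm vs z) and residual SD.
    """
    seg = curve.approach
    if seg is None:
        raise BaselineError("curve has no approach segment")
    if not 0 < fraction_noncontact < 1:
        raise BaselineError("fraction_noncontact must be in (0, 1)")
    if above_z is None:
        n = max(int(round(seg.n_samples * fraction_noncontact)), 0)
        z = seg.height[:n]
        f = seg.force[:n]
    else:
        mask = seg.height > above_z
        z = seg.height[mask]
        f = seg.force[mask]
        n = int(mask.sum())
    if n < 10:
        raise BaselineError(f"only {n} samples in non-contact region (need >= 10)")
    coeffs = np.polyfit(z, f, 1)
    resid = f - np.polyval(coeffs, z)
    sd = float(resid.std(ddof=2)) if n > 2 else 0.0
    if sd > 0:
        keep = np.abs(resid) <= clip_sigmas * sd
        if keep.sum() >= 10 and keep.sum() < n:
            coeffs = np.polyfit(z[keep], f[keep], 1)
            resid = f[keep] - np.polyval(coeffs, z[keep])
            sd = float(resid.std(ddof=2))
    tilt, offset = float(coeffs[0]), float(coeffs[1])
    # guard against exactly-zero synthetic noise leaving tiny negative values
    return Baseline(offset_pn=offset, tilt_pn_per_nm=tilt, noise_sd_pn=max(sd, 0.0))


def _piecewise_rss_scan(
    z: np.ndarray, f: np.ndarray, a: np.ndarray, lo: int, hi: int, window: int
) -> tuple[np.ndarray, np.ndarray]:
    """RSS of the piecewise model for every candidate contact index in [lo, hi).

    For candidate index j (contact at z[j]) the model is zero force before j
    and c * delta^2 after, with delta = (z0 + a_i) and a_i = -z_i - F_i/k
    precomputed. All candidates are scored over the *same* fixed sample range
    [lo - window, hi + window) so their RSS values are comparable; all sums
    are prefix-sum differences, so the scan is O(n) overall.
    """
    n = len(z)
    L = max(lo - window, 0)
    R = min(hi + window, n)

    def cs(x):
        return np.concatenate([[0.0], np.cumsum(x)])

    F2 = cs(f * f)
    # powers needed for sum(F * delta^2) and sum(delta^4)
    S_f = cs(f)
    S_fa = cs(f * a)
    S_fa2 = cs(f * a * a)
    S_1 = np.arange(n + 1, dtype=float)
    S_a = cs(a)
    S_a2 = cs(a * a)
    S_a3 = cs(a * a * a)
    S_a4 = cs(a * a * a * a)

    js = np.arange(lo, hi)
    z0 = z[js]

    def rng(S):
        return S[R] - S[js]

    # sum F*delta^2 = z0^2*sum(F) + 2 z0 * sum(F a) + sum(F a^2)
    sfd2 = z0**2 * rng(S_f) + 2 * z0 * rng(S_fa) + rng(S_fa2)
    # sum delta^4 = sum (z0 + a)^4 expanded in powers of a
    sd4 = (
        z0**4 * rng(S_1)
        + 4 * z0**3 * rng(S_a)
        + 6 * z0**2 * rng(S_a2)
        + 4 * z0 * rng(S_a3)
        + rng(S_a4)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(sd4 > 0, sfd2 / sd4, 0.0)
    c = np.maximum(c, 0.0)  # repulsive contact only
    rss_post = (F2[R] - F2[js]) - 2 * c * sfd2 + c**2 * sd4
    rss_pre = F2[js] - F2[L]
    return js, rss_pre + rss_post


def find_contact_point(
    curve: ForceCurve,
    baseline: Baseline,
    threshold_sigmas: float = 3.0,
    window_nm: float = 250.0,
    min_noise_pn: float = 0.05,
) -> float:
    """Two-stage contact-point detector on the baseline-corrected approach.

    Candidate: start of the final run of samples whose corrected force stays
    above ``threshold_sigmas * noise_sd``. Refinement: minimize the summed
    squared residuals of a piecewise model (zero before z0, quadratic in
    indentation after) over a window around the candidate, with parabolic
    sub-sample interpolation of the RSS minimum.
    """
    seg = curve.approach
    if seg is None:
        raise NoContactError("curve has no approach segment")
    z = seg.height
    f = seg.force - baseline.evaluate(z)
    thr = threshold_sigmas * max(baseline.noise_sd_pn, min_noise_pn)
    above = f > thr
    if not above[-1]:
        raise NoContactError("corrected force never stays above threshold")
    # start index of the trailing run of True
    below_idx = np.nonzero(~above)[0]
    start = int(below_idx[-1]) + 1 if below_idx.size else 0
    if start == 0:
        raise NoContactError("no pre-contact region below threshold")

    dz = float(np.median(np.abs(np.diff(z))))
    win = max(int(round(window_nm / dz)), 5)
    lo = max(start - win, 1)
    hi = min(start + win, len(z) - 5)
    if hi <= lo:
        return float(z[start])
    a = -z - f / curve.spring_constant
    js, rss = _piecewise_rss_scan(z, f, a, lo, hi, window=win)
    k = int(np.argmin(rss))
    j = int(js[k])
    z0 = float(z[j])
    # parabolic refinement on the RSS around the best grid point
    if 0 < k < len(js) - 1:
        r0, r1, r2 = rss[k - 1], rss[k], rss[k + 1]
        denom = r0 - 2 * r1 + r2
        if denom > 0:
            shift = 0.5 * (r0 - r2) / denom
            shift = float(np.clip(shift, -1.0, 1.0))
            # z decreases with index on the approach
            z0 = float(z[j] + shift * (z[min(j + 1, len(z) - 1)] - z[j]))
    return z0


def compute_indentation(
    curve: ForceCurve, z0: float, baseline: Baseline, spring_constant: float | None = None
) -> ProcessedCurve:
    """Build the indentation axis delta = (z0 - z) - F/k for post-contact samples."""
    k = curve.spring_constant if spring_constant is None else spring_constant
    if k <= 0:
        raise ValueError("spring constant must be positive")
    seg = curve.approach
    if seg is None:
        raise ValueError("curve has no approach segment")
    z = seg.height
    f = seg.force - baseline.evaluate(z)
    post = z <= z0
    delta = (z0 - z[post]) - f[post] / k
    force_post = f[post]
    keep = delta >= 0
    return ProcessedCurve(
        source=curve,
        height=z,
        corrected_force=f,
        contact_point=float(z0),
        indentation=delta[keep],
        post_contact_force=force_post[keep],
        tilt_slope=baseline.tilt_pn_per_nm,
        baseline_offset=baseline.offset_pn,
        noise_sd_estimate=baseline.noise_sd_pn,
    )


@dataclass
class QCThresholds:
    max_noise_sd_pn: float = 25.0
    saturation_force_pn: float = 5000.0
    max_drift_pn_per_nm: float = 0.5
    monotone_window: int = 51
    monotone_tolerance_pn: float = 0.0  # extra slack on top of noise


def qc_curve(processed: ProcessedCurve, thresholds: QCThresholds | None = None) -> QCRecord:
    """Automated surrogate for manual outlier screening; deterministic flags."""
    t = thresholds or QCThresholds()
    qc = QCRecord()
    if processed.noise_sd_estimate > t.max_noise_sd_pn:
        qc.fail("excessive_noise")
    if processed.indentation.size < 2:
        qc.fail("no_contact")
    if abs(processed.tilt_slope) > t.max_drift_pn_per_nm:
        qc.fail("drift")
    f = processed.post_contact_force
    if f.size:
        if f.max() >= t.saturation_force_pn:
            qc.fail("saturated")
        # post-contact force should rise on a smoothed scale
        w = min(t.monotone_window, max(f.size // 4 * 2 + 1, 3))
        if f.size > 3 * w:
            sm = np.convolve(f, np.ones(w) / w, mode="valid")
            drop = sm[: -w] - sm[w:]
            slack = 4.0 * processed.noise_sd_estimate + t.monotone_tolerance_pn
            if np.any(drop > slack + 1e-9):
                qc.fail("non_monotone")
    processed.qc = qc
    return qc


def process_curve(
    curve: ForceCurve,
    fraction_noncontact: float = 0.5,
    threshold_sigmas: float = 3.0,
    qc_thresholds: QCThresholds | None = None,
) -> ProcessedCurve:
    """Full conditioning chain; QC failures are recorded, not raised.

    Two-pass baseline: a first fit over the leading non-contact fraction
    locates the contact point, then the baseline (offset and zero-slope tilt)
    is refit over the entire pre-contact region and the contact point is
    re-refined, eliminating extrapolation error in the correction.
    """
    baseline = estimate_baseline(curve, fraction_noncontact)
    try:
        z0 = find_contact_point(curve, baseline, threshold_sigmas)
        try:
            baseline = estimate_baseline(curve, above_z=z0 + 20.0)
            z0 = find_contact_point(curve, baseline, threshold_sigmas)
        except BaselineError:
            pass  # contact very early in the ramp; keep the first-pass fit
    except NoContactError:
        seg = curve.approach
        processed = ProcessedCurve(
            source=curve,
            height=seg.height,
            corrected_force=seg.force - baseline.evaluate(seg.height),
            contact_point=float("nan"),
            indentation=np.empty(0),
            post_contact_force=np.empty(0),
            tilt_slope=baseline.tilt_pn_per_nm,
            baseline_offset=baseline.offset_pn,
            noise_sd_estimate=baseline.noise_sd_pn,
        )
        processed.qc.fail("no_contact")
        return processed
    processed = compute_indentation(curve, z0, baseline)
    qc_curve(processed, qc_thresholds)
    return processed
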