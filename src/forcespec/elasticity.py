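"""Hertz-Sneddon elasticity for four-sided pyramidal indenters.

The contact model is

    F = E / (1 - nu^2) * (tan(alpha) / sqrt(2)) * delta^2

with F the force (pN), E the Young's modulus, nu the Poisson ratio (0.5 for
cells treated as incompressible), alpha the pyramid face angle and delta the
indentation (nm). E is the single free parameter of the fit, so the
least-squares estimate over the fitted depth range is closed form: a linear
regression of F on delta^2 through the origin.

The per-curve headline numbers are E fitted over delta in [0, 500] nm and
the indentation reached at a load of 1 nN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import KPA_TO_PN_PER_NM2
from .preprocess import ProcessedCurve


class ShallowCurveError(ValueError):
    """Post-contact depth does not reach the requested fit depth."""


class MaxForceNotReachedError(ValueError):
    """The corrected approach force never reaches the target force."""


@dataclass(frozen=True)
class IndenterGeometry:
    """Four-sided pyramidal tip geometry.

    face_angle_deg is the pyramid face angle alpha of the contact model;
    the default of 18 degrees is a configurable choice (sharp silicon
    nitride probes), as the probe's exact angle is instrument-specific.
    """

    face_angle_deg: float = 18.0
    poisson_ratio: float = 0.5
    shape: str = "four_sided_pyramid"

    def __post_init__(self) -> None:
        if not 0 < self.face_angle_deg < 90:
            raise ValueError("face angle must be in (0, 90) degrees")
        if not 0 <= self.poisson_ratio <= 0.5:
            raise ValueError("Poisson ratio must be in [0, 0.5]")

    @property
    def prefactor_per_kpa(self) -> float:
        """F/delta^2 in pN/nm^2 for E = 1 kPa."""
        alpha = math.radians(self.face_angle_deg)
        return (
            KPA_TO_PN_PER_NM2
            / (1.0 - self.poisson_ratio**2)
            * math.tan(alpha)
            / math.sqrt(2.0)
        )


def hertz_sneddon_force(E_kpa: float, geometry: IndenterGeometry, delta_nm):
    """Force (pN) at indentation delta (nm) for Young's modulus E (kPa)."""
    delta = np.asarray(delta_nm, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation must be non-negative")
    return E_kpa * geometry.prefactor_per_kpa * delta**2


def invert_hertz_sneddon(E_kpa: float, geometry: IndenterGeometry, force_pn: float) -> float:
    """Indentation (nm) at which the model reaches ``force_pn``."""
    if force_pn < 0:
        raise ValueError("force must be non-negative")
    return math.sqrt(force_pn / (E_kpa * geometry.prefactor_per_kpa))


@dataclass
class ElasticFit:
    """Result of fitting the contact model to one processed curve."""

    youngs_modulus_kpa: float
    youngs_modulus_se_kpa: float
    contact_point_nm: float
    fit_depth_nm: float
    rss_pn2: float
    n_points: int
    indentation_at_1nN_nm: float | None = None

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "E_kPa": self.youngs_modulus_kpa,
                "E_se_kPa": self.youngs_modulus_se_kpa,
                "contact_point_nm": self.contact_point_nm,
                "fit_depth_nm": self.fit_depth_nm,
                "rss_pN2": self.rss_pn2,
                "n_points": self.n_points,
                "delta_at_1nN_nm": self.indentation_at_1nN_nm,
            }
        )


def fit_modulus(
    processed: ProcessedCurve,
    geometry: IndenterGeometry,
    fit_depth_nm: float = 500.0,
    min_points: int = 20,
) -> ElasticFit:
    """Least-squares Young's modulus over delta in [0, fit_depth_nm].

    E is the only free parameter; the fit is the closed-form regression of
    force on delta^2 through the origin. Raises :class:`ShallowCurveError`
    when the curve does not indent to the requested depth.
    """
    delta = processed.indentation
    force = processed.post_contact_force
    if delta.size == 0 or delta.max() < fit_depth_nm:
        raise ShallowCurveError(
            f"curve {processed.source.curve_id}: max indentation "
            f"{0.0 if delta.size == 0 else delta.max():.1f} nm < fit depth {fit_depth_nm} nm"
        )
    mask = delta <= fit_depth_nm
    if mask.sum() < min_points:
        raise ShallowCurveError(
            f"curve {processed.source.curve_id}: only {int(mask.sum())} samples "
            f"within fit depth (need >= {min_points})"
        )
    d2 = delta[mask] ** 2
    f = force[mask]
    denom = float(np.dot(d2, d2))
    c = float(np.dot(f, d2)) / denom  # pN/nm^2
    resid = f - c * d2
    rss = float(np.dot(resid, resid))
    n = int(mask.sum())
    # SE of the regression slope, propagated to E
    sigma2 = rss / max(n - 1, 1)
    c_se = math.sqrt(sigma2 / denom)
    pref = geometry.prefactor_per_kpa
    return ElasticFit(
        youngs_modulus_kpa=c / pref,
        youngs_modulus_se_kpa=c_se / pref,
        contact_point_nm=processed.contact_point,
        fit_depth_nm=fit_depth_nm,
        rss_pn2=rss,
        n_points=n,
    )


def indentation_at_force(processed: ProcessedCurve, target_force_pn: float = 1000.0) -> float:
    """Indentation (nm) at the first crossing of ``target_force_pn``.

    Linear interpolation between the bracketing post-contact samples; raises
    :class:`MaxForceNotReachedError` when the force never reaches the target.
    """
    delta = processed.indentation
    force = processed.post_contact_force
    above = np.nonzero(force >= target_force_pn)[0]
    if delta.size == 0 or above.size == 0:
        raise MaxForceNotReachedError(
            f"curve {processed.source.curve_id}: force never reaches "
            f"{target_force_pn} pN"
        )
    i = int(above[0])
    if i == 0:
        return float(delta[0])
    f0, f1 = force[i - 1], force[i]
    d0, d1 = delta[i - 1], delta[i]
    if f1 == f0:
        return float(d1)
    t = (target_force_pn - f0) / (f1 - f0)
    return float(d0 + t * (d1 - d0))


class HertzSneddonModel:
    """Model object tying a processed indentation curve to the contact model.

    ``fit()`` returns a :class:`HertzSneddonResults` carrying the modulus,
    its standard error and the indentation at 1 nN where reachable.
    """

    def __init__(
        self,
        processed: ProcessedCurve,
        geometry: IndenterGeometry | None = None,
        fit_depth_nm: float = 500.0,
    ):
        self.processed = processed
        self.geometry = geometry or IndenterGeometry()
        self.fit_depth_nm = fit_depth_nm

    def fit(self, target_force_pn: float = 1000.0) -> "HertzSneddonResults":
        elastic = fit_modulus(self.processed, self.geometry, self.fit_depth_nm)
        try:
            elastic.indentation_at_1nN_nm = indentation_at_force(
                self.processed, target_force_pn
            )
        except MaxForceNotReachedError:
            elastic.indentation_at_1nN_nm = None
        return HertzSneddonResults(self, elastic)


class HertzSneddonResults:
    def __init__(self, model: HertzSneddonModel, fit: ElasticFit):
        self.model = model
        self.elastic_fit = fit

    @property
    def youngs_modulus_kpa(self) -> float:
        return self.elastic_fit.youngs_modulus_kpa

    def predict(self, delta_nm):
        return hertz_sneddon_force(
            self.youngs_modulus_kpa, self.model.geometry, delta_nm
        )

    def summary(self) -> pd.Series:
        s = self.elastic_fit.summary()
        s["curve_id"] = self.model.processed.source.curve_id
        return s

    def plot(self, ax=None):
        """Corrected force vs indentation with the fitted model overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        p = self.model.processed
        ax.plot(p.indentation, p.post_contact_force, ".", ms=2, label="data")
        grid = np.linspace(0, self.elastic_fit.fit_depth_nm, 200)
        ax.plot(grid, self.predict(grid), "r-", label=f"fit E={self.youngs_modulus_kpa:.2f} kPa")
        ax.set_xlabel("indentation (nm)")
        ax.set_ylabel("force (pN)")
        ax.legend()
        return ax
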