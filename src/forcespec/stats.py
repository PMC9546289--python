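"""Population description and two-group comparison.

AFM population metrics (moduli, works of adhesion, unfolding forces) are
typically right-skewed and well described by lognormal distributions; the
headline statistic is the *most probable value*, the analytic mode
exp(mu - sigma^2) of the lognormal fitted by maximum likelihood on the log
values. Summaries also carry mean/median/SD/SE, 10/25/75/90th percentiles
(type-7, linear interpolation of order statistics), an R^2 of the fitted
density against a Freedman-Diaconis histogram, and a Gaussian KDE with
Silverman bandwidth. Two-group significance uses the two-sided
Mann-Whitney U test: full enumeration of all C(n_a+n_b, n_a) labelings for
small samples (midranks, so ties are handled), a tie-corrected normal
approximation otherwise. Stars follow *P<0.05, **P<0.01, ***P<0.001 with
strict inequalities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass
class LognormalFit:
    mu: float
    sigma: float
    mode: float
    r2: float | None = None


@dataclass
class PopulationSummary:
    n: int
    mean: float
    median: float
    sd: float
    se: float
    p10: float
    p25: float
    p75: float
    p90: float
    lognormal: LognormalFit
    kde_grid: np.ndarray = field(repr=False, default=None)
    kde_density: np.ndarray = field(repr=False, default=None)
    kde_peak: float = float("nan")
    n_nonpositive_excluded: int = 0
    normality_p: float = float("nan")
    distribution_route: str = "lognormal"  # or "normal"

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "median": self.median,
            "sd": self.sd,
            "se": self.se,
            "p10": self.p10,
            "p25": self.p25,
            "p75": self.p75,
            "p90": self.p90,
            "lognormal": {
                "mu": self.lognormal.mu,
                "sigma": self.lognormal.sigma,
                "mode": self.lognormal.mode,
                "r2": self.lognormal.r2,
            },
            "kde_peak": self.kde_peak,
            "normality_p": self.normality_p,
            "distribution_route": self.distribution_route,
        }


def _hist_r2(values: np.ndarray, mu: float, sigma: float) -> float | None:
    """R^2 of the lognormal density against a density-normalized
    Freedman-Diaconis histogram."""
    if sigma <= 0:
        return None
    try:
        hist, edges = np.histogram(values, bins="fd", density=True)
    except (ValueError, MemoryError):
        return None
    if len(hist) < 3:
        return None
    centers = 0.5 * (edges[:-1] + edges[1:])
    pdf = sps.lognorm.pdf(centers, s=sigma, scale=math.exp(mu))
    ss_res = float(np.sum((hist - pdf) ** 2))
    ss_tot = float(np.sum((hist - hist.mean()) ** 2))
    if ss_tot == 0:
        return None
    return 1.0 - ss_res / ss_tot


def summarize(values, kde_points: int = 256) -> PopulationSummary:
    """Moments, percentiles, lognormal MLE fit and KDE for one sample.

    Non-positive values are excluded from the lognormal fit (count is
    reported); n >= 3 finite values are required.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise StatsError(f"need at least 3 values, got {x.size}")
    pos = x[x > 0]
    n_excluded = int(x.size - pos.size)
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    se = sd / math.sqrt(x.size)
    p10, p25, med, p75, p90 = (
        float(v) for v in np.quantile(x, [0.10, 0.25, 0.50, 0.75, 0.90])
    )
    if pos.size >= 3:
        logs = np.log(pos)
        mu = float(logs.mean())
        sigma = float(logs.std(ddof=0))  # MLE
        mode = math.exp(mu - sigma**2)
        r2 = _hist_r2(pos, mu, sigma)
    else:
        mu, sigma, mode, r2 = float("nan"), float("nan"), float("nan"), None
    # normality screen routes the description; reported, never silent
    try:
        if x.size <= 5000:
            norm_p = float(sps.shapiro(x).pvalue)
        else:
            norm_p = float(sps.normaltest(x).pvalue)
    except ValueError:
        norm_p = float("nan")
    route = "normal" if norm_p > 0.05 else "lognormal"
    summary = PopulationSummary(
        n=int(x.size),
        mean=mean,
        median=med,
        sd=sd,
        se=se,
        p10=p10,
        p25=p25,
        p75=p75,
        p90=p90,
        lognormal=LognormalFit(mu=mu, sigma=sigma, mode=mode, r2=r2),
        n_nonpositive_excluded=n_excluded,
        normality_p=norm_p,
        distribution_route=route,
    )
    if sd > 0:
        kde = sps.gaussian_kde(x, bw_method="silverman")
        bw = kde.factor * sd
        grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, kde_points)
        dens = kde(grid)
        summary.kde_grid = grid
        summary.kde_density = dens
        summary.kde_peak = float(grid[int(np.argmax(dens))])
    return summary


# ---------------------------------------------------------------------------
# Mann-Whitney


@dataclass
class ComparisonResult:
    u_statistic: float
    p_value: float
    method: str  # "exact_enumeration" | "normal_approximation"
    stars: str
    group_summaries: dict[str, PopulationSummary] = field(default_factory=dict)
    deltas_pct: dict[str, float] = field(default_factory=dict)
    metric: str = ""
    group_labels: tuple[str, str] = ("a", "b")

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "groups": [
                dict(label=label, **self.group_summaries[label].to_dict())
                for label in self.group_labels
                if label in self.group_summaries
            ],
            "u": self.u_statistic,
            "p": self.p_value,
            "method": self.method,
            "stars": self.stars,
            "deltas": self.deltas_pct,
        }

    def summary(self) -> pd.DataFrame:
        rows = []
        for label in self.group_labels:
            s = self.group_summaries.get(label)
            if s is None:
                continue
            rows.append(
                {
                    "group": label,
                    "n": s.n,
                    "mean": s.mean,
                    "median": s.median,
                    "sd": s.sd,
                    "se": s.se,
                    "lognormal_mode": s.lognormal.mode,
                }
            )
        df = pd.DataFrame(rows)
        df.attrs["u"] = self.u_statistic
        df.attrs["p"] = self.p_value
        df.attrs["stars"] = self.stars
        return df


def stars(p_value: float) -> str:
    """Significance stars at strict 0.05/0.01/0.001 thresholds."""
    if not 0 <= p_value <= 1:
        raise StatsError(f"p-value out of range: {p_value}")
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


_null_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _exact_u_distribution(ranks: np.ndarray, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of U_a over all C(n, n_a) labelings of the pooled sample.

    Cached by (n_a, midrank multiset): for tie-free data the midranks are
    always 1..n, so repeated calls at the same sizes reuse one enumeration.
    """
    key = (n_a, tuple(np.sort(ranks)))
    if key in _null_cache:
        return _null_cache[key]
    n = len(ranks)
    idx = np.fromiter(
        (i for comb in combinations(range(n), n_a) for i in comb), dtype=np.intp
    ).reshape(-1, n_a)
    ranksums = ranks[idx].sum(axis=1)
    u_vals = ranksums - n_a * (n_a + 1) / 2.0
    uniq, counts = np.unique(u_vals, return_counts=True)
    out = (uniq, counts / counts.sum())
    _null_cache[key] = out
    return out


def mann_whitney(a, b, mode: str = "auto", max_exact_total: int = 20) -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    ``mode``: 'auto' enumerates exactly when n_a + n_b <= ``max_exact_total``,
    'exact' forces enumeration, 'approx' forces the tie-corrected normal
    approximation (delegated to scipy). U is reported as min(U_a, U_b).
    The exact two-sided p is P(min(U_a, U_b) <= observed min) under random
    labeling.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
    u_b = n_a * n_b - u_a
    u_min = min(u_a, u_b)
    use_exact = mode == "exact" or (mode == "auto" and n_a + n_b <= max_exact_total)
    if mode not in ("auto", "exact", "approx"):
        raise StatsError(f"unknown mode {mode!r}")
    if use_exact:
        uniq, probs = _exact_u_distribution(ranks, n_a)
        u_mirror = n_a * n_b - uniq
        mins = np.minimum(uniq, u_mirror)
        p = float(probs[mins <= u_min + 1e-9].sum())
        method = "exact_enumeration"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "normal_approximation"
    p = min(p, 1.0)
    return ComparisonResult(
        u_statistic=u_min, p_value=p, method=method, stars=stars(p)
    )


def compare_groups(
    values_by_group: dict[str, np.ndarray], metric_name: str = "", mode: str = "auto"
) -> ComparisonResult:
    """Summaries + Mann-Whitney + percentage deltas for exactly two groups.

    Deltas are (g2 - g1)/g1 * 100 for mean, median and lognormal mode, in
    the insertion order of ``values_by_group``.
    """
    if len(values_by_group) != 2:
        raise StatsError(
            f"compare_groups takes exactly two groups, got {len(values_by_group)}; "
            "run pairwise comparisons for more"
        )
    (label1, g1), (label2, g2) = values_by_group.items()
    s1, s2 = summarize(g1), summarize(g2)
    result = mann_whitney(g1, g2, mode=mode)
    result.metric = metric_name
    result.group_labels = (label1, label2)
    result.group_summaries = {label1: s1, label2: s2}

    def pct(x2: float, x1: float) -> float:
        return (x2 - x1) / x1 * 100.0 if x1 != 0 else float("nan")

    result.deltas_pct = {
        "mean_pct": pct(s2.mean, s1.mean),
        "median_pct": pct(s2.median, s1.median),
        "mode_pct": pct(s2.lognormal.mode, s1.lognormal.mode),
    }
    return result
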