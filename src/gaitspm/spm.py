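"""1D statistical parametric mapping (SPM) for gait waveform comparison.

Gait waveforms sampled on a common 0-100 % cycle grid are compared
node-wise with a two-sample t statistic. Because neighbouring nodes are
strongly correlated, the family-wise error across the whole curve is
controlled with random field theory (RFT): the smoothness of the
residual field is estimated as a FWHM in grid nodes, and the critical
threshold u solves

    E[EC(u)] = (1 - F_t(u; df)) + R * rho_1(u) = alpha_tail

where R = (Q - 1) / FWHM is the resel count of the 1D field and rho_1 is
the 1D Euler-characteristic density of a t field,

    rho_1(u) = sqrt(4 ln 2) / (2 pi) * (1 + u^2 / df) ** (-(df - 1) / 2).

Supra-threshold clusters of |t| receive extent-based p-values using the
standard exponential approximation to the cluster-extent distribution.
The module also provides the scalar statistics used alongside the
waveform tests: Cohen's d from summary statistics, a priori sample size
from noncentral-t power, and normality-gated two-group scalar tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

_SQRT_4LN2 = math.sqrt(4.0 * math.log(2.0))


@dataclass
class Cluster:
    """One supra-threshold cluster of the t curve."""

    start: int  # first node index
    end: int  # last node index (inclusive)
    p_value: float
    mean_d: float  # mean Cohen's d over the cluster nodes

    @property
    def extent(self) -> int:
        return self.end - self.start + 1


@dataclass
class SpmResult:
    t_curve: np.ndarray
    df: int
    fwhm: float
    t_crit: float
    clusters: list[Cluster] = field(default_factory=list)
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return len(self.clusters) > 0


@dataclass
class EffectSize:
    d: float


def estimate_fwhm(residuals: np.ndarray) -> float:
    """Field smoothness (FWHM, in nodes) from normalized residual gradients.

    Uses the standard estimator based on the variance of the gradient of
    the variance-normalized residual field; larger FWHM means a smoother
    field and fewer resolution elements.
    """
    r = np.asarray(residuals, dtype=float)
    ssq = (r**2).sum(axis=0)
    grad = np.gradient(r, axis=1)
    v = (grad**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = v / ssq
    v = v[np.isfinite(v)]
    if v.size == 0 or np.all(v == 0):
        return float("inf")
    resels_per_node = np.sqrt(v / (4.0 * math.log(2.0)))
    rpn = resels_per_node.mean()
    return float(1.0 / rpn) if rpn > 0 else float("inf")


def _ec_density_1d(u: float, df: int) -> float:
    """1D Euler-characteristic density of a t field at height u."""
    return _SQRT_4LN2 / (2.0 * math.pi) * (1.0 + u**2 / df) ** (-(df - 1) / 2.0)


def expected_ec(u: float, df: int, resels: float) -> float:
    """Expected Euler characteristic of a thresholded 1D t field."""
    return stats.t.sf(u, df) + resels * _ec_density_1d(u, df)


def rft_threshold(
    df: int, n_nodes: int, fwhm: float, alpha: float = 0.05, tails: int = 2
) -> float:
    """Critical t threshold controlling family-wise error over the field.

    Solves ``E[EC(u)] = alpha / tails`` for u. As the field becomes
    infinitely smooth (resels -> 0) the threshold converges to the
    ordinary t quantile; it decreases monotonically with FWHM.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if df < 1:
        raise ValueError("df must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    target = alpha / tails
    resels = (n_nodes - 1) / fwhm
    f = lambda u: expected_ec(u, df, resels) - target
    lo, hi = 1e-6, 50.0
    if f(hi) > 0:
        raise ValueError("no root in (0, 50]: field too rough for this alpha")
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def cluster_pvalue(
    extent: float, t_crit: float, df: int, fwhm: float, n_nodes: int
) -> float:
    """RFT cluster-extent p-value (exponential approximation).

    The expected number of clusters above the threshold is the resel term
    of the EC expansion; cluster extents are taken exponentially
    distributed with mean equal to expected supra-threshold volume per
    cluster. The p-value is the probability that a null field produces at
    least one cluster at least this large.
    """
    if extent <= 0:
        return 1.0
    resels = (n_nodes - 1) / fwhm
    e_clusters = resels * _ec_density_1d(t_crit, df)
    e_nodes = n_nodes * stats.t.sf(t_crit, df)
    if e_clusters <= 0:
        return 0.0
    mean_extent = e_nodes / e_clusters
    p_extent = math.exp(-extent / mean_extent)
    return float(min(1.0, 1.0 - math.exp(-e_clusters * p_extent)))


def spm_ttest2(
    group_a: np.ndarray,
    group_b: np.ndarray,
    alpha: float = 0.05,
    tails: int = 2,
) -> SpmResult:
    """Two-sample SPM t-test over a common waveform grid.

    ``group_a`` and ``group_b`` are ``(subjects, nodes)`` matrices. The
    pointwise pooled-variance t statistic (df = nA + nB - 2) is
    thresholded at the RFT critical value; maximal supra-threshold runs
    of |t| become clusters with extent p-values and the mean pointwise
    Cohen's d over their nodes. Nodes with zero pooled variance are
    masked (t = 0) with a warning.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 subjects per group")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the waveform grid")
    q = a.shape[1]
    df = na + nb - 2
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / df
    sp = np.sqrt(sp2)
    se = sp * math.sqrt(1.0 / na + 1.0 / nb)
    dead = se == 0
    if np.any(dead):
        warnings.warn(f"{int(dead.sum())} nodes with zero pooled variance masked")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(dead, 0.0, (ma - mb) / np.where(dead, 1.0, se))
        d_curve = np.where(dead, 0.0, (ma - mb) / np.where(dead, 1.0, sp))
    residuals = np.vstack([a - ma, b - mb])
    if np.allclose(residuals, 0):
        # identical subjects: flat null field, nothing can be significant
        fwhm = float("inf")
        t_crit = float(stats.t.isf(alpha / tails, df))
        return SpmResult(t_curve=t, df=df, fwhm=fwhm, t_crit=t_crit, alpha=alpha)
    fwhm = estimate_fwhm(residuals)
    if math.isinf(fwhm):
        t_crit = float(stats.t.isf(alpha / tails, df))
    else:
        try:
            t_crit = rft_threshold(df, q, fwhm, alpha=alpha, tails=tails)
        except ValueError:
            # residual field too rough for any attainable threshold: the
            # family-wise criterion cannot be met anywhere
            warnings.warn(
                "residual field too rough for RFT inference; no threshold "
                "attainable, reporting no clusters"
            )
            t_crit = float("inf")
    clusters: list[Cluster] = []
    supra = np.abs(t) > t_crit
    padded = np.concatenate(([False], supra, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for i in range(0, edges.size, 2):
        start, stop = int(edges[i]), int(edges[i + 1])  # [start, stop)
        extent = stop - start
        p = (
            cluster_pvalue(extent, t_crit, df, fwhm, q)
            if math.isfinite(fwhm)
            else alpha  # flat-field limit: crossing the quantile is the event
        )
        mean_d = float(np.abs(d_curve[start:stop].mean()))
        clusters.append(Cluster(start=start, end=stop - 1, p_value=p, mean_d=mean_d))
    return SpmResult(
        t_curve=t, df=df, fwhm=fwhm, t_crit=t_crit, clusters=clusters, alpha=alpha
    )


def cohens_d_scalar(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> EffectSize:
    """Cohen's d from summary statistics with pooled standard deviation."""
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 in each group")
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    if sp2 == 0:
        raise ZeroDivisionError("zero pooled standard deviation")
    return EffectSize(d=float((mean_a - mean_b) / math.sqrt(sp2)))


def power_n_per_group(
    d: float, alpha: float = 0.05, power: float = 0.8, tails: int = 1
) -> int:
    """Smallest per-group n for a two-sample t-test to reach target power.

    Power is computed from the noncentral t distribution with
    ``ncp = d * sqrt(n / 2)`` and ``df = 2n - 2``; the one-tailed mode
    reproduces the conventional a priori computation at d = 1.03,
    alpha = 0.05, power = 0.80 (n = 13), the two-tailed mode gives 16.
    """
    if d <= 0:
        raise ValueError("effect size must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    for n in range(2, 10**6 + 1):
        df = 2 * n - 2
        ncp = d * math.sqrt(n / 2.0)
        t_crit = stats.t.isf(alpha / tails, df)
        if stats.nct.sf(t_crit, df, ncp) >= power:
            return n
    raise ValueError("target power unreachable within n <= 10^6")


def compare_scalar(
    group_a, group_b, kind: str = "auto"
) -> tuple[float, float, str]:
    """Two-group scalar comparison with a Shapiro-Wilk normality gate.

    kind="auto" runs an independent-samples t-test when both groups pass
    Shapiro-Wilk at 0.05, otherwise a Wilcoxon rank-sum test. kind="chi2"
    expects ``(successes, n)`` pairs and applies the continuity-corrected
    chi-squared test on the implied 2x2 table. Returns
    ``(statistic, p, kind_used)``.
    """
    if kind == "chi2":
        (k1, n1), (k2, n2) = group_a, group_b
        table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
        res = stats.chi2_contingency(table, correction=True)
        return float(res[0]), float(res[1]), "chi2"
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if kind == "auto":
        normal = all(
            v.size >= 3 and np.ptp(v) > 0 and stats.shapiro(v).pvalue > 0.05
            for v in (a, b)
        )
        kind = "t" if normal else "ranksum"
    if kind == "t":
        res = stats.ttest_ind(a, b)
        return float(res.statistic), float(res.pvalue), "t"
    if kind == "ranksum":
        res = stats.ranksums(a, b)
        return float(res.statistic), float(res.pvalue), "ranksum"
    raise ValueError(f"unknown kind {kind!r}")
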