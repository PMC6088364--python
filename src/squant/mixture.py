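"""Objective small/large event separation via cumulative-normal mixture fits.

The empirical cumulative distribution of a cell's event amplitudes is fitted
by least squares with one or two cumulative normal components,

    F_k(x) = sum_i w_i * Phi((x - mu_i) / sigma_i),      sum w_i = 1,

the two fits are compared with a nested-model F test,

    F = [(RSS_1 - RSS_2) / (p_2 - p_1)] / [RSS_2 / (n - p_2)],

and, when two components fit significantly better, the amplitude threshold
A_th for "large" events is the abscissa at which the fitted two-component
CDF reaches the cumulative level where the first component ends.

This module follows a model/results layout: build an
:class:`AmplitudeMixtureModel` from amplitudes, call :meth:`fit`, and work
with the returned :class:`MixtureFitResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .detection import EventTable

__all__ = [
    "AmplitudeMixtureModel",
    "MixtureFitResults",
    "FTestResult",
    "ThresholdResult",
    "fit_cumulative_mixture",
    "compare_fits",
    "amplitude_threshold",
    "split_by_threshold",
]


def _ecdf(amplitudes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted amplitudes with Hazen plotting positions (i - 0.5)/n."""
    x = np.sort(np.asarray(amplitudes, dtype=float))
    n = len(x)
    return x, (np.arange(1, n + 1) - 0.5) / n


@dataclass
class FTestResult:
    """Nested-model F test between the one- and two-component CDF fits."""

    f_value: float
    df_num: int
    df_den: int
    p_value: float
    degenerate: bool = False  # RSS_2 == 0 (perfect two-component fit)

    def __str__(self) -> str:
        return (
            f"F({self.df_num}, {self.df_den}) = {self.f_value:.4g}, "
            f"p = {self.p_value:.3g}"
        )


@dataclass
class ThresholdResult:
    """Amplitude threshold A_th (pA) separating small from large events.

    ``y_break`` is the cumulative probability at which the first component
    ends (its weight attained at mu1 + 3*sigma1); ``a_th`` is the abscissa
    where the fitted two-component CDF crosses that level.
    """

    a_th: float
    y_break: float
    low_separation: bool = False


class MixtureFitResults:
    """Fitted cumulative-normal mixture (one or two components).

    Attributes
    ----------
    k : int
        Number of components.
    weights, means, sds : ndarray
        Component parameters (pA); for ``k == 2``, ``means[0] < means[1]``.
    rss : float
        Residual sum of squares of the CDF fit.
    p_params : int
        Free-parameter count (2 for k=1; 5 for k=2: w1 is free, w2 = 1-w1).
    n_points : int
        Number of fitted CDF points.
    """

    def __init__(self, model, k, weights, means, sds, rss):
        self.model = model
        self.k = k
        self.weights = np.asarray(weights, dtype=float)
        self.means = np.asarray(means, dtype=float)
        self.sds = np.asarray(sds, dtype=float)
        self.rss = float(rss)
        self.p_params = 2 if k == 1 else 5
        self.n_points = model.nobs

    def cdf(self, x) -> np.ndarray:
        """Fitted mixture CDF evaluated at ``x``."""
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x, dtype=float)
        for w, m, s in zip(self.weights, self.means, self.sds):
            out += w * stats.norm.cdf(x, m, s)
        return out

    def compare_to(self, other: "MixtureFitResults") -> FTestResult:
        """F test of this (k=1) fit against ``other`` (k=2); see :func:`compare_fits`."""
        return compare_fits(self, other)

    def amplitude_threshold(self) -> ThresholdResult:
        """A_th for this two-component fit; see :func:`amplitude_threshold`."""
        return amplitude_threshold(self)

    def summary(self) -> str:
        lines = [
            f"Cumulative-normal mixture fit (k={self.k}, n={self.n_points} points)",
            f"  RSS = {self.rss:.6g}  (free parameters: {self.p_params})",
        ]
        for i, (w, m, s) in enumerate(zip(self.weights, self.means, self.sds), 1):
            lines.append(
                f"  component {i}: w = {w:.3f}, mu = {m:.2f} pA, sigma = {s:.2f} pA"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        if self.k == 1:
            return {"mu": self.means[0], "sigma": self.sds[0], "rss": self.rss}
        return {
            "w1": self.weights[0],
            "mu1": self.means[0],
            "sigma1": self.sds[0],
            "mu2": self.means[1],
            "sigma2": self.sds[1],
            "rss": self.rss,
        }


class AmplitudeMixtureModel:
    """Least-squares cumulative-normal mixture model of event amplitudes.

    The fitting target is the empirical CDF evaluated at every sorted
    amplitude (Hazen plotting positions), mirroring the plotted-and-fitted
    cumulative distribution procedure.
    """

    def __init__(self, amplitudes):
        amplitudes = np.asarray(amplitudes, dtype=float)
        if amplitudes.ndim != 1 or len(amplitudes) < 2:
            raise ValueError("need a 1-d array of at least 2 amplitudes")
        if len(amplitudes) < 50:
            warnings.warn(
                f"only {len(amplitudes)} amplitudes; mixture fit may be unstable"
            )
        self.x, self.y = _ecdf(amplitudes)
        self.nobs = len(self.x)

    @classmethod
    def from_event_table(cls, table: EventTable) -> "AmplitudeMixtureModel":
        return cls(table.amplitudes)

    # ------------------------------------------------------------------ fit
    def fit(self, k: int = 2) -> MixtureFitResults:
        """Fit a ``k``-component cumulative-normal mixture (k in {1, 2}).

        k=2 uses 5 multistarts (median split plus alternate quantile splits
        with quartile-based sigma guesses) and keeps the lowest-RSS solution.
        Raises ``RuntimeError`` with best-so-far diagnostics if no start
        converges.
        """
        if k == 1:
            return self._fit1()
        if k == 2:
            return self._fit2()
        raise ValueError("k must be 1 or 2")

    def _fit1(self) -> MixtureFitResults:
        x, y = self.x, self.y
        mu0, s0 = float(np.mean(x)), float(np.std(x, ddof=1))

        def resid(theta):
            mu, ls = theta
            return stats.norm.cdf(x, mu, np.exp(ls)) - y

        sol = optimize.least_squares(resid, [mu0, np.log(max(s0, 1e-6))])
        mu, sigma = sol.x[0], float(np.exp(sol.x[1]))
        rss = float(np.sum(sol.fun**2))
        return MixtureFitResults(self, 1, [1.0], [mu], [sigma], rss)

    def _starts2(self) -> list[np.ndarray]:
        x = self.x
        starts = []
        for q in (0.5, 0.65, 0.75, 0.85, 0.35):
            split = np.quantile(x, q)
            lo, hi = x[x <= split], x[x > split]
            if len(lo) < 2 or len(hi) < 2:
                continue
            w1 = len(lo) / len(x)
            starts.append(
                np.array(
                    [
                        w1,
                        np.mean(lo),
                        max(np.std(lo, ddof=1), 1e-3),
                        np.mean(hi),
                        max(np.std(hi, ddof=1), 1e-3),
                    ]
                )
            )
        if not starts:  # pathological: nearly constant data
            m = float(np.mean(x))
            s = max(float(np.std(x)), 1e-3)
            starts = [np.array([0.5, m - s, s, m + s, s])]
        return starts

    def _fit2(self) -> MixtureFitResults:
        x, y = self.x, self.y

        def resid(theta):
            w1, m1, s1, m2, s2 = theta
            return (
                w1 * stats.norm.cdf(x, m1, s1)
                + (1 - w1) * stats.norm.cdf(x, m2, s2)
                - y
            )

        span = x[-1] - x[0]
        lb = [1e-4, x[0] - span, 1e-6, x[0] - span, 1e-6]
        ub = [1 - 1e-4, x[-1] + span, 10 * span + 1, x[-1] + span, 10 * span + 1]

        best = None
        diagnostics = []
        for theta0 in self._starts2():
            theta0 = np.clip(theta0, lb, ub)
            try:
                sol = optimize.least_squares(resid, theta0, bounds=(lb, ub))
            except Exception as exc:  # pragma: no cover - optimizer failure path
                diagnostics.append(str(exc))
                continue
            rss = float(np.sum(sol.fun**2))
            diagnostics.append(f"start {theta0.round(3)} -> rss {rss:.3g}")
            if sol.success and (best is None or rss < best[0]):
                best = (rss, sol.x)
        if best is None:
            raise RuntimeError(
                "two-component mixture fit failed to converge; diagnostics: "
                + "; ".join(diagnostics)
            )
        rss, (w1, m1, s1, m2, s2) = best
        if m1 > m2:  # enforce mu1 < mu2 by relabelling
            w1, m1, s1, m2, s2 = 1 - w1, m2, s2, m1, s1
        return MixtureFitResults(self, 2, [w1, 1 - w1], [m1, m2], [s1, s2], rss)


# --------------------------------------------------------------------------
# functional surface
# --------------------------------------------------------------------------

def fit_cumulative_mixture(amplitudes, k: int) -> MixtureFitResults:
    """Fit the empirical amplitude CDF with ``k`` cumulative normals."""
    return AmplitudeMixtureModel(amplitudes).fit(k)


def compare_fits(fit1: MixtureFitResults, fit2: MixtureFitResults) -> FTestResult:
    """Nested-model F test: does the two-component fit improve significantly?

    F = [(RSS1 - RSS2)/(p2 - p1)] / [RSS2/(n - p2)], with p from the F
    distribution on (p2 - p1, n - p2) degrees of freedom.  A perfect
    two-component fit (RSS2 == 0) is reported as p = 0 with a degeneracy flag.
    """
    if fit1.n_points != fit2.n_points:
        raise ValueError("fits must be computed on the same points")
    n = fit1.n_points
    p1, p2 = fit1.p_params, fit2.p_params
    df_num, df_den = p2 - p1, n - p2
    if fit2.rss == 0:
        return FTestResult(np.inf, df_num, df_den, 0.0, degenerate=True)
    f = ((fit1.rss - fit2.rss) / df_num) / (fit2.rss / df_den)
    p = float(stats.f.sf(f, df_num, df_den)) if f >= 0 else 1.0
    return FTestResult(float(f), df_num, df_den, p)


def amplitude_threshold(fit2: MixtureFitResults) -> ThresholdResult:
    """Amplitude threshold where the first fitted distribution ends.

    The first component is taken to "end" at q = mu1 + 3*sigma1 (99.87% of
    component 1 lies below), so the break level is
    y_break = w1 * Phi((q - mu1)/sigma1) ~= w1; A_th solves
    F_2(A_th) = y_break on the fitted two-component CDF.
    """
    if fit2.k != 2:
        raise ValueError("amplitude_threshold requires a two-component fit")
    w1, (m1, m2), (s1, s2) = fit2.weights[0], fit2.means, fit2.sds
    if abs(m2 - m1) < s1 + s2:
        warnings.warn(
            "mixture components overlap heavily (|mu2-mu1| < sigma1+sigma2); "
            "threshold is poorly separated"
        )
        low_sep = True
    else:
        low_sep = False
    q = m1 + 3 * s1
    y_break = float(w1 * stats.norm.cdf(3.0))

    lo = min(m1 - 10 * s1, m2 - 10 * s2)
    hi = max(m1 + 10 * s1, m2 + 10 * s2)
    a_th = float(optimize.brentq(lambda x: fit2.cdf(x) - y_break, lo, hi))
    return ThresholdResult(a_th=a_th, y_break=y_break, low_separation=low_sep)


def split_by_threshold(table: EventTable, a_th: float) -> EventTable:
    """Label events: amplitude > ``a_th`` -> 'large', otherwise 'small'."""
    if a_th <= 0:
        raise ValueError("a_th must be positive")
    classes = ["large" if a > a_th else "small" for a in table.amplitudes]
    return table.with_classes(classes)
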