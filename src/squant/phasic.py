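"""Threshold-free phasic-charge measurement and E/I ratio estimation.

For a 15-s segment of raw recording an all-point histogram (1 pA bins) is
built and smoothed (Savitzky–Golay, order 2, window 17).  The histogram is
skewed toward the polarity of the synaptic events; the non-skewed side is
fitted with a Gaussian from its far end to the point past the peak where
the smoothed counts fall to 95% of the peak.  The fitted mean is the
holding current; mirroring the Gaussian onto the skewed side and summing
the positive excess of the histogram over the mirror, weighted by distance
from the holding current, gives the phasic charge in pC without any event
detection threshold.

E/I ratios are formed from m excitatory and n inhibitory segment charges as
(7·E)/(6·I), equalizing the ~60 vs ~70 mV driving forces of sEPSC (−60 mV)
and sIPSC (0 mV) recordings; m = n = 10 segments yield 100 ratios per cell.
The fractional deviation t_{0.975,N-1}·sigma/(mu·sqrt(N)) quantifies how
close the mean of N ratios is to the population value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.signal import savgol_filter

from .trace import Trace

__all__ = [
    "AllPointHistogram",
    "BaselineFit",
    "PhasicMeasure",
    "EIMatrix",
    "sample_segments",
    "all_point_histogram",
    "fit_baseline",
    "phasic_charge",
    "measure_segment",
    "ei_matrix",
    "fractional_deviation",
    "sample_size_curve",
    "ptx_sigma_check",
]

DRIVING_FORCE_E_MV = 60.0
DRIVING_FORCE_I_MV = 70.0


# --------------------------------------------------------------------------
# segment sampling
# --------------------------------------------------------------------------

def sample_segments(
    trace: Trace,
    m: int,
    duration: float = 15.0,
    rng: np.random.Generator | None = None,
    max_retries: int = 10_000,
) -> list[tuple[float, float]]:
    """Randomly place ``m`` disjoint ``duration``-s windows on the trace.

    Start times are drawn as integer seconds; a draw overlapping an
    already-accepted window or a seal-test exclusion window is regenerated.
    Sequential placement can paint itself into a corner at high packing
    fractions, so after ``max_retries // 100`` consecutive rejections the
    placement restarts from scratch; ``max_retries`` rejections in total
    raise an error stating the capacity problem.
    """
    if rng is None:
        rng = np.random.default_rng()
    t_max = int(np.floor(trace.duration - duration))
    if t_max < 0:
        raise ValueError("trace shorter than one segment")
    accepted: list[tuple[float, float]] = []
    retries = 0
    stuck = 0
    restart_after = max(max_retries // 100, 10)
    while len(accepted) < m:
        start = float(rng.integers(0, t_max + 1))
        window = (start, start + duration)
        bad = any(window[0] < hi and lo < window[1] for lo, hi in accepted)
        bad = bad or any(
            window[0] < hi and lo < window[1] for lo, hi in trace.exclusion_windows
        )
        if bad:
            retries += 1
            stuck += 1
            if retries > max_retries:
                raise RuntimeError(
                    f"could not place {m} disjoint {duration:g}-s segments on a "
                    f"{trace.duration:g}-s trace after {max_retries} rejections "
                    f"({len(accepted)} placed)"
                )
            if stuck >= restart_after:  # likely deadlocked: start over
                accepted.clear()
                stuck = 0
            continue
        accepted.append(window)
        stuck = 0
    return sorted(accepted)


def extract_segment(trace: Trace, window: tuple[float, float]) -> np.ndarray:
    """Samples of ``trace`` inside ``window`` (s)."""
    i0 = int(round(window[0] * trace.fs))
    i1 = int(round(window[1] * trace.fs))
    return trace.samples[i0:i1]


# --------------------------------------------------------------------------
# all-point histogram
# --------------------------------------------------------------------------

@dataclass
class AllPointHistogram:
    """All-point histogram of a segment at exactly 1 pA bin width."""

    bin_edges: np.ndarray  # len nbins+1, 1 pA spacing
    counts: np.ndarray
    smoothed_counts: np.ndarray
    peak_bin: int
    skew_side: str  # 'left' or 'right'
    smoothed: bool = True

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())


def all_point_histogram(segment: np.ndarray) -> AllPointHistogram:
    """Histogram every sample of ``segment`` into 1 pA bins and smooth.

    The peak is taken from the smoothed counts (2nd-order, 17-point
    Savitzky–Golay); ``skew_side`` is the side of the peak carrying the
    excess event mass, determined by the sign of mean − median of the
    samples (splitting raw counts at the peak bin is fragile when the
    baseline mean sits near a 1 pA bin edge).  Histograms narrower than
    17 bins are returned unsmoothed with a warning.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size < 1000:
        raise ValueError("segment too short (< 1000 samples)")
    lo = np.floor(segment.min())
    hi = np.ceil(segment.max())
    if hi == lo:
        hi = lo + 1
    edges = np.arange(lo, hi + 1.0)  # exact 1 pA bins
    counts, _ = np.histogram(segment, bins=edges)
    if len(counts) >= 17:
        smoothed = np.clip(savgol_filter(counts.astype(float), 17, 2), 0, None)
        did_smooth = True
    else:
        warnings.warn("histogram narrower than 17 bins; smoothing skipped")
        smoothed = counts.astype(float)
        did_smooth = False
    peak = int(np.argmax(smoothed))
    side = "right" if float(np.mean(segment)) >= float(np.median(segment)) else "left"
    return AllPointHistogram(edges, counts, smoothed, peak, side, did_smooth)


@dataclass
class BaselineFit:
    """Gaussian baseline of the all-point histogram.

    ``i_hold`` (pA) is the fitted mean — the mean holding current;
    ``sigma_b`` its SD (the quantity compared before/after PTX);
    ``amplitude`` the fitted peak height in counts.
    """

    i_hold: float
    sigma_b: float
    amplitude: float
    fit_range: tuple[float, float]
    fallback: bool = False

    def gaussian(self, x: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-((x - self.i_hold) ** 2) / (2 * self.sigma_b**2))


def fit_baseline(hist: AllPointHistogram) -> BaselineFit:
    """Least-squares Gaussian on the non-skewed side of the histogram.

    The fit range runs from the far end of the non-skewed side, through the
    peak, to the first bin on the skewed side where the smoothed counts drop
    to 95% of the peak value.  The smoothed counts locate the peak and fix
    the range; the Gaussian itself is fitted to the raw counts, whose shape
    the 17-point smoothing would otherwise broaden.  On optimizer failure a
    flagged fallback uses the mode and the half-width at exp(-1/2) of the
    peak.
    """
    y = hist.smoothed_counts
    x = hist.centers
    peak = hist.peak_bin
    peak_val = y[peak]
    level = 0.95 * peak_val
    if hist.skew_side == "right":
        j = peak
        while j + 1 < len(y) and y[j + 1] >= level:
            j += 1
        sl = slice(0, j + 1)
    else:
        j = peak
        while j - 1 >= 0 and y[j - 1] >= level:
            j -= 1
        sl = slice(j, len(y))
    xs, ys = x[sl], hist.counts[sl].astype(float)
    fit_range = (float(xs[0]), float(xs[-1]))

    # moment-based initial guess on the fitted range
    w = np.clip(ys, 0, None)
    mu0 = float(np.average(xs, weights=w)) if w.sum() else float(x[peak])
    s0 = float(np.sqrt(np.average((xs - mu0) ** 2, weights=w))) if w.sum() else 1.0
    s0 = max(s0, 0.5)
    try:
        popt, _ = optimize.curve_fit(
            lambda xx, a, m, s: a * np.exp(-((xx - m) ** 2) / (2 * s**2)),
            xs,
            ys,
            p0=[peak_val, x[peak], s0],
            maxfev=10_000,
        )
        a, m, s = popt
        if not (np.isfinite([a, m, s]).all() and s != 0 and a > 0):
            raise RuntimeError("non-finite Gaussian fit")
        return BaselineFit(float(m), abs(float(s)), float(a), fit_range)
    except Exception:
        # fallback: mode and half-width at exp(-1/2) of the peak
        half = peak_val * np.exp(-0.5)
        below = np.flatnonzero(y < half)
        lo_idx = below[below < peak].max() if np.any(below < peak) else 0
        hi_idx = below[below > peak].min() if np.any(below > peak) else len(y) - 1
        sigma = max((x[hi_idx] - x[lo_idx]) / 2.0, 0.5)
        warnings.warn("Gaussian baseline fit diverged; using mode/half-width fallback")
        return BaselineFit(float(x[peak]), float(sigma), float(peak_val), fit_range, True)


# --------------------------------------------------------------------------
# phasic charge
# --------------------------------------------------------------------------

@dataclass
class PhasicMeasure:
    """Phasic charge of one segment.

    ``charge`` is in pC: excess histogram mass over the mirrored Gaussian on
    the skewed side, weighted by |i - i_hold| and scaled by the sample
    interval (pA·s = pC).  ``charge_per_sample`` is the per-point-normalized
    variant (pC per excess point); the E/I ratio is identical under either
    normalization.
    """

    segment_id: int
    charge: float
    i_hold: float
    sigma_b: float
    duration: float
    charge_per_sample: float = float("nan")
    clipped: bool = False
    start_s: float = float("nan")


def phasic_charge(
    segment: np.ndarray,
    fit: BaselineFit,
    hist: AllPointHistogram,
    fs: float,
    segment_id: int = 0,
) -> PhasicMeasure:
    """Mirror-Gaussian phasic charge of a segment (pC).

    excess(i) = max(counts(i) - mirrored Gaussian(i), 0) over bins on the
    skewed side of the fitted mean; charge = sum(excess · |i - i_hold|)/fs.
    Negative total excess (over-fitted baseline) is clipped to 0 and flagged.
    """
    x = hist.centers
    mirror = fit.gaussian(x)
    raw_excess = hist.counts - mirror
    if hist.skew_side == "right":
        side = x > fit.i_hold
    else:
        side = x < fit.i_hold
    excess = np.where(side, raw_excess, 0.0)
    clipped = bool(np.any(excess < 0))
    excess = np.clip(excess, 0.0, None)
    weights = np.abs(x - fit.i_hold)
    charge = float(np.sum(excess * weights) / fs)  # pA * s = pC
    n_excess = float(np.sum(excess))
    per_sample = charge / n_excess if n_excess > 0 else 0.0
    if charge < 0:  # pragma: no cover - clip above prevents this
        charge = 0.0
    return PhasicMeasure(
        segment_id=segment_id,
        charge=charge,
        i_hold=fit.i_hold,
        sigma_b=fit.sigma_b,
        duration=len(segment) / fs,
        charge_per_sample=per_sample,
        clipped=clipped,
    )


def measure_segment(
    trace: Trace, window: tuple[float, float], segment_id: int = 0
) -> PhasicMeasure:
    """All-point histogram → baseline Gaussian → phasic charge for one window."""
    seg = extract_segment(trace, window)
    hist = all_point_histogram(seg)
    fit = fit_baseline(hist)
    pm = phasic_charge(seg, fit, hist, trace.fs, segment_id)
    pm.start_s = window[0]
    return pm


# --------------------------------------------------------------------------
# E/I ratios
# --------------------------------------------------------------------------

@dataclass
class EIMatrix:
    """Driving-force-corrected E/I ratio matrix.

    ``ratios[j, k] = (7 · E_j) / (6 · I_k)`` over m excitatory and n
    inhibitory segment charges; the 7/6 factor equalizes the ~70 vs ~60 mV
    driving forces of the inhibitory and excitatory recordings.
    """

    e_values: np.ndarray
    i_values: np.ndarray
    ratios: np.ndarray
    df_correction: tuple[float, float] = (7.0, 6.0)
    missing_columns: list[int] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.ratios))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.ratios, ddof=1))

    @property
    def flat(self) -> np.ndarray:
        r = self.ratios.ravel()
        return r[np.isfinite(r)]


def ei_matrix(e_measures, i_measures) -> EIMatrix:
    """All m×n driving-force-corrected ratios of E over I phasic charges.

    Accepts :class:`PhasicMeasure` lists or plain charge arrays.  A zero
    inhibitory charge makes that column undefined (NaN, reported missing).
    """
    def charges(ms):
        return np.array(
            [m.charge if isinstance(m, PhasicMeasure) else float(m) for m in ms]
        )

    e = charges(e_measures)
    i = charges(i_measures)
    if e.size < 1 or i.size < 1:
        raise ValueError("need at least one E and one I charge")
    if np.any(e < 0) or np.any(i < 0):
        raise ValueError("charges must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = (7.0 * e[:, None]) / (6.0 * i[None, :])
    missing = [int(k) for k in np.flatnonzero(i == 0)]
    ratios[:, i == 0] = np.nan
    if missing:
        warnings.warn(f"zero inhibitory charge in columns {missing}; reported missing")
    return EIMatrix(e, i, ratios, missing_columns=missing)


# --------------------------------------------------------------------------
# sample-size analysis (fractional deviation)
# --------------------------------------------------------------------------

def fractional_deviation(ratios, n: int) -> float:
    """t_{0.975, N-1} · sigma / (mu · sqrt(N)) for a sample of E/I ratios.

    The relative half-width of the 95% confidence interval of the mean of N
    ratios: how far (as a fraction) the sample mean may sit from the
    population mean.  Strictly decreasing in N and ~1/sqrt(N) for large N.
    """
    ratios = np.asarray(ratios, dtype=float)
    ratios = ratios[np.isfinite(ratios)]
    if n < 2:
        raise ValueError("N must be >= 2")
    mu = float(np.mean(ratios))
    if mu <= 0:
        raise ValueError("fractional deviation undefined for non-positive mean")
    sigma = float(np.std(ratios, ddof=1))
    t = float(stats.t.ppf(0.975, n - 1))
    return t * sigma / (mu * np.sqrt(n))


def sample_size_curve(ratios, n_values=None) -> "np.recarray":
    """Fractional-deviation curve over candidate sample sizes (default 10..100)."""
    if n_values is None:
        n_values = np.arange(10, 101, 10)
    ratios = np.asarray(ratios, dtype=float)
    rows = []
    for n in n_values:
        rows.append(
            (
                int(n),
                fractional_deviation(ratios, int(n)),
                float(stats.t.ppf(0.975, int(n) - 1)),
                float(np.mean(ratios)),
                float(np.std(ratios, ddof=1)),
            )
        )
    return np.array(
        rows,
        dtype=[
            ("n", int),
            ("fractional_deviation", float),
            ("t_quantile", float),
            ("mu", float),
            ("sigma", float),
        ],
    ).view(np.recarray)


# --------------------------------------------------------------------------
# PTX contamination check
# --------------------------------------------------------------------------

def ptx_sigma_check(sigma_pre, sigma_post) -> dict:
    """Paired Wilcoxon test of baseline sigma before vs after PTX wash-in.

    A significant *decrease* of the Gaussian baseline SD after blocking
    GABA_A receptors indicates that small outward sIPSCs were contaminating
    the sEPSC recording.  Requires per-cell pairing; >= 3 pairs for a
    meaningful test.
    """
    pre = np.asarray(sigma_pre, dtype=float)
    post = np.asarray(sigma_post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("sigma_pre and sigma_post must be paired (equal length)")
    if pre.size < 3:
        warnings.warn("fewer than 3 pairs; PTX check has little power")
    diffs = post - pre
    if np.all(diffs == 0):
        return {
            "statistic": 0.0,
            "p_value": 1.0,
            "decrease": False,
            "contamination": False,
            "note": "identical pre/post sigmas",
        }
    res = stats.wilcoxon(pre, post, zero_method="wilcox")
    decrease = bool(np.median(diffs) < 0)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "decrease": decrease,
        "contamination": bool(res.pvalue < 0.05 and decrease),
        "note": "",
    }
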