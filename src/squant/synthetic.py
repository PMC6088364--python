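"""Synthetic voltage-clamp trace generator with known ground truth.

Emulates whole-cell recordings of spontaneous postsynaptic currents:
Gaussian baseline noise around a holding current, PSC events with
bi-exponential kinetics placed by a configurable inter-event-interval (IEI)
point process, amplitudes drawn from a two-component normal mixture, inward
events at negative holding voltages and outward events at 0 mV, 1.5 kHz
low-pass filtering at a 10 kHz sampling rate, and optional seal-test
exclusion windows.  Every trace is returned together with its
:class:`GroundTruth` so downstream detection, mixture, temporal and phasic
analyses can be validated against known event times, amplitudes and charge.

The default simulation parameters are matched to the wild-type-like sIPSC
statistics of the study conditions: a two-component amplitude mixture with
small events near 28 pA and large events near 95 pA (4:1 weight), event
rates in the 6–11 Hz range, 10 kHz sampling and 1.5 kHz low-pass filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .trace import Trace

__all__ = [
    "IEIProcessSpec",
    "AmplitudeMixtureSpec",
    "KernelSpec",
    "SimConfig",
    "GroundTruth",
    "ConfigurationError",
    "generate_iei_sequence",
    "generate_amplitudes",
    "biexp_kernel",
    "synthesize_trace",
]


class ConfigurationError(ValueError):
    """A simulation spec field is invalid; the message names the field."""


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

_IEI_KINDS = ("exponential", "gamma", "lognormal", "constant", "ar1_copula")


@dataclass(frozen=True)
class IEIProcessSpec:
    """Inter-event-interval point process.

    ``kind`` selects the marginal/process: ``exponential`` (Poisson train),
    ``gamma`` / ``lognormal`` (renewal with tunable regularity), ``constant``
    (perfectly regular), or ``ar1_copula`` (gamma marginal driven through a
    latent Gaussian AR(1), giving tunable lag-1 Spearman memory with an
    exact marginal).  ``rate`` is events/s; ``shape`` is the gamma shape or
    the lognormal sigma; ``lag1_target`` (only for ``ar1_copula``) is the
    desired lag-1 Spearman autocorrelation in (−1, 1).
    """

    kind: str = "exponential"
    rate: float = 10.0
    shape: float = 1.0
    lag1_target: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _IEI_KINDS:
            raise ConfigurationError(f"kind: unknown IEI process {self.kind!r}")
        if not self.rate > 0:
            raise ConfigurationError("rate: must be > 0")
        if self.kind in ("gamma", "ar1_copula") and not self.shape > 0:
            raise ConfigurationError("shape: gamma shape must be > 0")
        if self.kind == "lognormal" and not self.shape > 0:
            raise ConfigurationError("shape: lognormal sigma must be > 0")
        if self.kind == "ar1_copula":
            if self.lag1_target is None or not (-1 < self.lag1_target < 1):
                raise ConfigurationError(
                    "lag1_target: required in (-1, 1) for ar1_copula"
                )
        elif self.lag1_target is not None:
            raise ConfigurationError("lag1_target: only valid for ar1_copula")


@dataclass(frozen=True)
class AmplitudeMixtureSpec:
    """Two-component normal amplitude mixture (pA), truncated at 0.

    ``w1`` weights the small component; means must satisfy ``mu1 < mu2``.
    Defaults are the wild-type-like sIPSC values (small ≈28 pA, large ≈95 pA,
    4:1 small:large).
    """

    w1: float = 0.8
    mu1: float = 28.0
    sigma1: float = 8.0
    mu2: float = 95.0
    sigma2: float = 25.0

    def __post_init__(self) -> None:
        if not (0 < self.w1 <= 1):
            raise ConfigurationError("w1: must be in (0, 1]")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ConfigurationError("sigma: all component SDs must be > 0")
        if self.w1 < 1 and not self.mu1 < self.mu2:
            raise ConfigurationError("mu1: must be < mu2")

    def cdf(self, x: np.ndarray | float) -> np.ndarray:
        """Untruncated mixture CDF (truncation at 0 is negligible for pA-scale means)."""
        return self.w1 * stats.norm.cdf(x, self.mu1, self.sigma1) + (
            1 - self.w1
        ) * stats.norm.cdf(x, self.mu2, self.sigma2)

    @property
    def mean(self) -> float:
        return self.w1 * self.mu1 + (1 - self.w1) * self.mu2


@dataclass(frozen=True)
class KernelSpec:
    """Bi-exponential PSC waveform, peak-normalized to 1.

    ``k(t) = exp(-t/tau_decay) - exp(-t/tau_rise)``, scaled so the peak is 1
    and a drawn amplitude is reproduced exactly.  Times are in ms.
    """

    tau_rise: float = 0.5
    tau_decay: float = 6.0
    polarity: str = "outward"

    def __post_init__(self) -> None:
        if not (0 < self.tau_rise < self.tau_decay):
            raise ConfigurationError("tau_rise: need 0 < tau_rise < tau_decay")
        if self.polarity not in ("inward", "outward"):
            raise ConfigurationError("polarity: must be 'inward' or 'outward'")

    @property
    def t_peak_ms(self) -> float:
        """Time of the kernel peak (ms)."""
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * np.log(td / tr)

    @property
    def peak_value(self) -> float:
        """Unnormalized peak of exp(-t/td) - exp(-t/tr)."""
        tp = self.t_peak_ms
        return np.exp(-tp / self.tau_decay) - np.exp(-tp / self.tau_rise)

    @property
    def unit_charge_s(self) -> float:
        """Integral of the peak-normalized kernel in seconds (so that
        event charge in pC = amplitude_pA * unit_charge_s)."""
        return (self.tau_decay - self.tau_rise) / self.peak_value * 1e-3

    def sample(self, fs: float, tol: float = 1e-4) -> np.ndarray:
        """Peak-normalized kernel sampled at ``fs`` until it decays to ``tol``."""
        n = int(np.ceil(-self.tau_decay * np.log(tol) * 1e-3 * fs)) + 1
        t_ms = np.arange(n) / fs * 1e3
        k = np.exp(-t_ms / self.tau_decay) - np.exp(-t_ms / self.tau_rise)
        return k / self.peak_value


@dataclass(frozen=True)
class SimConfig:
    """Full simulation configuration for one trace."""

    duration: float = 60.0
    fs: float = 10_000.0
    lowpass_hz: float = 1_500.0
    hold_current: float = 0.0
    noise_sigma: float = 7.0  # pre-filter; gives ~3.9 pA baseline SD after 1.5 kHz
    iei: IEIProcessSpec = field(default_factory=IEIProcessSpec)
    amps: AmplitudeMixtureSpec = field(default_factory=AmplitudeMixtureSpec)
    kernel: KernelSpec = field(default_factory=KernelSpec)
    seal_test_windows: tuple[tuple[float, float], ...] = ()
    v_hold: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ConfigurationError("duration: must be > 0")
        if not self.fs > 2 * self.lowpass_hz:
            raise ConfigurationError("fs: must exceed 2 * lowpass_hz")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma: must be >= 0")


@dataclass
class GroundTruth:
    """True event placements backing a synthetic trace.

    ``total_event_charge`` is the summed per-event charge (pC) actually
    deposited inside the trace window, i.e. amplitude × kernel integral with
    analytic truncation at the window end.
    """

    event_times: np.ndarray
    event_amplitudes: np.ndarray
    total_event_charge: float

    @property
    def n_events(self) -> int:
        return len(self.event_times)


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def generate_iei_sequence(
    spec: IEIProcessSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` positive inter-event intervals (s) from ``spec``.

    All marginals have mean ``1/rate``.  For ``ar1_copula`` a latent Gaussian
    AR(1) is pushed through the gamma marginal's quantile function; the latent
    Pearson coefficient is chosen so the Spearman lag-1 autocorrelation
    converges to ``lag1_target`` (rho = 2 sin(pi * rho_S / 6)).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    mean = 1.0 / spec.rate
    if spec.kind == "constant":
        return np.full(n, mean)
    if spec.kind == "exponential":
        return rng.exponential(mean, size=n)
    if spec.kind == "gamma":
        return rng.gamma(spec.shape, mean / spec.shape, size=n)
    if spec.kind == "lognormal":
        # mean of lognormal(mu, s) is exp(mu + s^2/2); pin the mean at 1/rate
        s = spec.shape
        return rng.lognormal(np.log(mean) - s**2 / 2, s, size=n)
    # ar1_copula
    rho_s = spec.lag1_target
    rho = 2.0 * np.sin(np.pi * rho_s / 6.0)
    z = np.empty(n)
    z[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * np.sqrt(1 - rho**2)
    for i in range(1, n):
        z[i] = rho * z[i - 1] + innov[i - 1]
    u = stats.norm.cdf(z)
    return stats.gamma.ppf(u, spec.shape, scale=mean / spec.shape)


def generate_amplitudes(
    spec: AmplitudeMixtureSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` positive amplitudes (pA) from the two-component mixture.

    Non-positive draws are redrawn (truncation by rejection), preserving the
    mixture shape above zero.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = np.empty(n)
    remaining = np.arange(n)
    while remaining.size:
        m = remaining.size
        comp = rng.random(m) < spec.w1
        draws = np.where(
            comp,
            rng.normal(spec.mu1, spec.sigma1, m),
            rng.normal(spec.mu2, spec.sigma2, m),
        )
        out[remaining] = draws
        remaining = remaining[draws <= 0]
    return out


def biexp_kernel(spec: KernelSpec, fs: float) -> np.ndarray:
    """Convenience alias for :meth:`KernelSpec.sample`."""
    return spec.sample(fs)


def synthesize_trace(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[Trace, GroundTruth]:
    """Render one voltage-clamp trace and its ground truth.

    Events are placed at cumulative IEI times, scaled by mixture-drawn
    amplitudes with the kernel's polarity (inward events deflect the current
    negative, outward positive), summed linearly, offset by the holding
    current, then Gaussian noise of ``noise_sigma`` is added and the whole
    trace is low-pass filtered (4th-order Butterworth, zero-phase).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_samples = int(round(cfg.duration * cfg.fs))
    clean = np.zeros(n_samples)

    # draw enough IEIs to cover the window, then truncate
    mean_iei = 1.0 / cfg.iei.rate
    n_guess = max(int(cfg.duration / mean_iei * 1.5) + 20, 2)
    ieis = generate_iei_sequence(cfg.iei, n_guess, rng)
    times = np.cumsum(ieis)
    while times[-1] < cfg.duration:
        more = generate_iei_sequence(cfg.iei, n_guess, rng)
        times = np.concatenate([times, times[-1] + np.cumsum(more)])
    times = times[times < cfg.duration]

    amps = generate_amplitudes(cfg.amps, len(times), rng) if len(times) else np.empty(0)
    kernel = cfg.kernel.sample(cfg.fs)
    sign = -1.0 if cfg.kernel.polarity == "inward" else 1.0

    # warn in the summation regime: expected event occupancy above 50%
    # (an event "occupies" samples while the kernel exceeds 5% of its peak)
    occupancy = cfg.iei.rate * len(cfg.kernel.sample(cfg.fs, tol=0.05)) / cfg.fs
    if occupancy > 0.5:
        warnings.warn(
            f"event rate {cfg.iei.rate:g} Hz puts ~{occupancy:.0%} of samples inside "
            "events; overlapping-event summation will dominate",
            stacklevel=2,
        )

    total_charge = 0.0
    unit_charge = cfg.kernel.unit_charge_s  # s, peak-normalized integral
    td_s = cfg.kernel.tau_decay * 1e-3
    tr_s = cfg.kernel.tau_rise * 1e-3
    peak = cfg.kernel.peak_value
    for t, a in zip(times, amps):
        i0 = int(round(t * cfg.fs))
        seg = kernel[: n_samples - i0]
        clean[i0 : i0 + len(seg)] += sign * a * seg
        # analytic kernel integral truncated at the window end
        rem = cfg.duration - t
        trunc = (
            td_s * (1 - np.exp(-rem / td_s)) - tr_s * (1 - np.exp(-rem / tr_s))
        ) / peak
        total_charge += a * min(trunc, unit_charge)

    noisy = clean + cfg.hold_current + rng.normal(0.0, cfg.noise_sigma, n_samples)
    if cfg.noise_sigma > 0 or len(times):
        b, a_f = signal.butter(4, cfg.lowpass_hz / (cfg.fs / 2))
        noisy = signal.filtfilt(b, a_f, noisy)

    trace = Trace(
        samples=noisy,
        fs=cfg.fs,
        v_hold=cfg.v_hold,
        exclusion_windows=[tuple(w) for w in cfg.seal_test_windows],
    )
    truth = GroundTruth(
        event_times=times,
        event_amplitudes=amps,
        total_event_charge=total_charge,
    )
    return trace, truth
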