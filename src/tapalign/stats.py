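"""Tapping-performance statistics.

Beyond the mean and SD of the tap-stimulus asynchrony, this module offers
three standard alternative measures from the sensorimotor-synchronization
literature:

* the mean resultant vector length of tap phases (circular statistics),
* a method-of-moments fit of the Vorberg-Wing linear phase-correction
  model, decomposing tapping variability into timekeeper noise sigma_T,
  motor noise sigma_M and an error-correction gain alpha,
* lag-1 autocorrelations of the asynchrony and the inter-tap interval.

Vorberg-Wing model
------------------
With A_n the asynchrony on tap n, T_n ~ N(0, sigma_T^2) the timekeeper
noise and M_n ~ N(0, sigma_M^2) the motor delay, the centered asynchronies
follow

    A_{n+1} = (1 - alpha) A_n + T_n + M_{n+1} - M_n .

Writing beta = 1 - alpha and gamma(k) for the lag-k autocovariance of the
stationary series, the model implies gamma(2) = beta * gamma(1),
sigma_M^2 = beta*gamma(0) - gamma(1) and
sigma_T^2 = (1 - beta^2)*gamma(0) - 2*(1 - beta)*sigma_M^2, which yields a
closed-form estimator from the sample autocovariances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SMSMetrics",
    "asynchrony_stats",
    "vector_length",
    "fit_vorberg_wing",
    "lag1_autocorrelation",
    "compute_metrics",
    "summarize_trials",
]


@dataclass(frozen=True)
class SMSMetrics:
    """Per-trial tapping-performance summary. NaN marks undefined values."""

    mean_async: float
    sd_async: float
    vector_length: float
    vw_alpha: float
    vw_sigma_t: float
    vw_sigma_m: float
    lag1_async: float
    lag1_iti: float
    n_matched: int
    flags: tuple = ()

    def to_dict(self) -> dict:
        d = {k: (None if isinstance(v, float) and np.isnan(v) else v)
             for k, v in self.__dict__.items() if k != "flags"}
        d["flags"] = list(self.flags)
        return d


def asynchrony_stats(asynchronies: np.ndarray) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of the asynchronies.

    SD is NaN for fewer than two values. A negative mean indicates
    anticipation — the typical human tendency to tap a few tens of
    milliseconds ahead of the beat.
    """
    a = np.asarray(asynchronies, dtype=np.float64)
    if a.size == 0:
        return float("nan"), float("nan")
    mean = float(np.mean(a))
    sd = float(np.std(a, ddof=1)) if a.size >= 2 else float("nan")
    return mean, sd


def vector_length(asynchronies: np.ndarray, local_iois: np.ndarray) -> float:
    """Mean resultant vector length R of tap phases, in [0, 1].

    Each asynchrony is converted to a phase angle theta_n = 2*pi*A_n/IOI_n
    relative to its local inter-onset interval; R is the modulus of the mean
    unit phasor. R = 1 for perfectly concentrated phases, R = 0 for phases
    spread uniformly around the circle.
    """
    a = np.asarray(asynchronies, dtype=np.float64)
    iois = np.asarray(local_iois, dtype=np.float64)
    if a.size == 0:
        return float("nan")
    if a.size != iois.size:
        raise ValueError("asynchronies and local_iois must have equal length")
    if np.any(iois <= 0):
        raise ValueError("all local IOIs must be positive")
    theta = 2 * np.pi * a / iois
    return float(np.abs(np.mean(np.exp(1j * theta))))


def _autocovariance(x: np.ndarray, lag: int) -> float:
    """Biased (1/n) sample autocovariance at the given lag."""
    x = x - x.mean()
    n = x.size
    return float(np.dot(x[: n - lag], x[lag:]) / n)


def fit_vorberg_wing(asynchronies: np.ndarray
                     ) -> tuple[float, float, float, tuple]:
    """Method-of-moments fit of the linear phase-correction model.

    Returns ``(alpha, sigma_t, sigma_m, flags)`` where sigmas are in the
    unit of the input (ms). Negative variance estimates are clipped to 0
    and flagged ``"vw_clipped"``; a near-zero lag-1 autocovariance makes
    the ratio gamma(2)/gamma(1) unstable and is flagged ``"vw_degenerate"``
    (alpha is then reported as 1, the white-noise limit).
    """
    a = np.asarray(asynchronies, dtype=np.float64)
    flags: list = []
    if a.size < 5:
        return float("nan"), float("nan"), float("nan"), ("vw_too_short",)
    g0 = _autocovariance(a, 0)
    g1 = _autocovariance(a, 1)
    g2 = _autocovariance(a, 2)
    # |g1| below its own sampling noise (~g0/sqrt(n)) makes g2/g1 meaningless;
    # report the white-noise limit (full correction, no motor component)
    if g0 <= 0 or abs(g1) < 2.0 * g0 / np.sqrt(a.size):
        return 1.0, float(np.sqrt(max(g0, 0.0))), 0.0, ("vw_degenerate",)
    beta = g2 / g1
    if not (-1 < beta < 1):
        flags.append("vw_unstable_beta")
        beta = float(np.clip(beta, -0.999, 0.999))
    var_m = beta * g0 - g1
    if var_m < 0:
        flags.append("vw_clipped")
        var_m = 0.0
    var_t = (1 - beta ** 2) * g0 - 2 * (1 - beta) * var_m
    if var_t < 0:
        flags.append("vw_clipped")
        var_t = 0.0
    alpha = 1.0 - beta
    return float(alpha), float(np.sqrt(var_t)), float(np.sqrt(var_m)), tuple(flags)


def lag1_autocorrelation(series: np.ndarray) -> float:
    """Sample lag-1 autocorrelation; NaN for constant or too-short series.

    For inter-tap intervals built from i.i.d. tap-time jitter on an
    isochronous grid this tends to -0.5 (the Wing-Kristofferson limit with
    no error correction); alternating series approach -1, trends +1.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.size < 3:
        return float("nan")
    g0 = _autocovariance(x, 0)
    if g0 <= 0:
        return float("nan")
    return _autocovariance(x, 1) / g0


def compute_metrics(asynchronies: np.ndarray, tap_onsets: np.ndarray,
                    local_iois: np.ndarray) -> SMSMetrics:
    """Assemble the full per-trial metric set from matched pairs."""
    a = np.asarray(asynchronies, dtype=np.float64)
    mean_a, sd_a = asynchrony_stats(a)
    r = vector_length(a, local_iois) if a.size else float("nan")
    alpha, sig_t, sig_m, flags = fit_vorberg_wing(a)
    itis = np.diff(np.asarray(tap_onsets, dtype=np.float64))
    return SMSMetrics(
        mean_async=mean_a, sd_async=sd_a, vector_length=r,
        vw_alpha=alpha, vw_sigma_t=sig_t, vw_sigma_m=sig_m,
        lag1_async=lag1_autocorrelation(a),
        lag1_iti=lag1_autocorrelation(itis),
        n_matched=int(a.size), flags=flags,
    )


def summarize_trials(trial_metrics: list[SMSMetrics]) -> dict:
    """Average per-trial metrics into a participant-level score.

    Per-trial values are averaged with equal weight (NaNs ignored); the SD
    of asynchrony is aggregated as the mean of per-trial SDs.
    """
    fields = ["mean_async", "sd_async", "vector_length", "vw_alpha",
              "vw_sigma_t", "vw_sigma_m", "lag1_async", "lag1_iti"]
    out = {}
    for f in fields:
        vals = np.array([getattr(m, f) for m in trial_metrics], dtype=np.float64)
        vals = vals[np.isfinite(vals)]
        out[f] = float(vals.mean()) if vals.size else float("nan")
    out["n_trials"] = len(trial_metrics)
    return out
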